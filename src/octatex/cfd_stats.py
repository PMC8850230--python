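"""Group statistics for sector-wise capillary flow density (CFD).

CFD is the percentage of a macular sector's area occupied by vessel lumens
(the device also reports a choroidal ``thickness`` sector in um).  This
module reproduces the case/control machinery applied to such tables:
per-cell descriptive summaries, two-sample t-tests computed either from raw
per-subject values or directly from printed (mean, SD, n) summaries,
Pearson chi-squared tests of category tables, and Cohen's kappa for
intra-observer agreement.

The t-test is offered in both classical flavours: ``t_pooled`` (equal
variances, df = n1 + n2 - 2) and ``t_welch`` (per-group variances,
Satterthwaite df).  P-values are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reference_tables

VALID_SECTORS = set(reference_tables.SECTORS)

SUMMARY_COLUMNS = [
    "sector",
    "mean_case",
    "sd_case",
    "n_case",
    "mean_control",
    "sd_control",
    "n_control",
]


@dataclass
class TestResult:
    method: str  # t_pooled | t_welch | chi_squared
    statistic: float
    df: float
    p_two_sided: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_two_sided <= 1.0
        assert self.df > 0


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per group x sector descriptive summary of a long CFD table.

    Input columns: ``subject_id, group, layer, sector, value``.  Returns
    mean, sample SD (n-1), median, IQR (linear-interpolation quartiles)
    and n per cell; cells with fewer than two records are flagged
    (``usable = False``) and should be excluded from testing.
    """
    required = {"group", "sector", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")

    def _cell(v: pd.Series) -> pd.Series:
        v = v.astype(float)
        q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
        return pd.Series(
            {
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                "median": v.median(),
                "iqr": q3 - q1,
                "n": len(v),
                "usable": len(v) >= 2,
            }
        )

    keys = ["group", "sector"] + (["layer"] if "layer" in records.columns else [])
    out = records.groupby(keys)["value"].apply(_cell).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    out["usable"] = out["usable"].astype(bool)
    return out


def t_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    method: str = "t_pooled",
) -> TestResult:
    """Two-sample t-test from printed summary statistics.

    pooled: t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2)),
            s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2),
            df = n1 + n2 - 2.
    welch:  per-group variances with Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("standard deviations must be >= 0 and not both zero")
    v1, v2 = sd1**2, sd2**2
    if method == "t_pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif method == "t_welch":
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = np.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    t = (mean1 - mean2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(method=method, statistic=float(t), df=float(df), p_two_sided=float(p))


def t_test_from_samples(
    x: Sequence[float], y: Sequence[float], method: str = "t_pooled"
) -> TestResult:
    """Same test from raw samples; defined as the summary test applied to
    the samples' own mean/SD/n, so the two paths agree exactly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    return t_test_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), method
    )


def chi_squared_test(table: np.ndarray) -> TestResult:
    """Pearson chi-squared test of independence on a counts table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2D table with at least 2 rows and 2 columns")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError(
            "zero expected count (empty row or column margin); "
            "collapse sparse categories before testing"
        )
    statistic = ((table - expected) ** 2 / expected).sum()
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = stats.chi2.sf(statistic, df)
    return TestResult(
        method="chi_squared", statistic=float(statistic), df=float(df),
        p_two_sided=float(p),
    )


def cohen_kappa(r1: Sequence, r2: Sequence) -> float:
    """Cohen's kappa between two categorical rating sequences.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected
    agreement.  Two identical constant raters give p_e = 1; agreement is
    then perfect by inspection and kappa is defined as 1.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if len(r1) != len(r2) or len(r1) < 2:
        raise ValueError("ratings must have equal length >= 2")
    n = len(r1)
    cats = np.union1d(r1, r2)
    p_o = np.mean(r1 == r2)
    m1 = np.array([(r1 == c).mean() for c in cats])
    m2 = np.array([(r2 == c).mean() for c in cats])
    p_e = float(m1 @ m2)
    if p_e == 1.0:
        return 1.0  # both raters constant and identical
    return float((p_o - p_e) / (1.0 - p_e))


def tests_from_summary_frame(
    summary: pd.DataFrame, method: str = "t_pooled"
) -> pd.DataFrame:
    """One t-test per sector row of a case/control summary table.

    ``summary`` follows the summary-CSV layout (``sector, mean_case,
    sd_case, n_case, mean_control, sd_control, n_control``).
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise ValueError(f"summary table is missing columns: {missing}")
    rows = []
    for _, r in summary.iterrows():
        res = t_test_from_summary(
            r["mean_case"], r["sd_case"], int(r["n_case"]),
            r["mean_control"], r["sd_control"], int(r["n_control"]),
            method=method,
        )
        rows.append(
            {
                "sector": r["sector"],
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_two_sided,
            }
        )
    return pd.DataFrame(rows)


def tests_from_records(
    records: pd.DataFrame, method: str = "t_pooled"
) -> pd.DataFrame:
    """Per-sector case-vs-control t-tests from a long per-subject table."""
    rows = []
    for sector, sub in records.groupby("sector", sort=False):
        x = sub.loc[sub["group"] == "case", "value"].to_numpy(float)
        y = sub.loc[sub["group"] == "control", "value"].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            continue  # flagged by summarize(); untestable cell
        res = t_test_from_samples(x, y, method=method)
        rows.append(
            {
                "sector": sector,
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_two_sided,
            }
        )
    return pd.DataFrame(rows)
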