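"""Six-pattern classification of the textural grading index.

Choriocapillaris textures fall into six clinically recognised patterns
A-F, ordered by coarseness: A is the roughest (largest confluent flow
voids), F the finest, essentially control-like texture.  The letters are
clinical names, not an alphabetical coarseness order; the default ranking
(coarsest to finest) is A, B, E, D, C, F.  A subject's pattern is obtained
by binning its grading index with five ascending cut points — by default
the pooled sextile (1/6 .. 5/6) quantiles of the cohort's indices, so the
partition is balanced; fixed cuts can be supplied instead for
reproducibility across cohorts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: default pattern order from coarsest (rank 1) to finest (rank 6)
DEFAULT_ORDER = ("A", "B", "E", "D", "C", "F")

CLINICAL_TYPES = ("acute", "chronic", "recurrent", "control", "NA")


def coarseness_rank(label: str, order: Sequence[str] = DEFAULT_ORDER) -> int:
    """1 = coarsest ... 6 = finest under the given order."""
    return order.index(label) + 1


def quantile_cuts(indices: Sequence[float]) -> np.ndarray:
    """Five pooled empirical sextile cuts (linear-interpolation quantiles)."""
    indices = np.asarray(indices, dtype=float)
    if np.unique(indices).size < 6:
        raise ValueError("need at least 6 distinct index values for sextile cuts")
    return np.quantile(indices, np.arange(1, 6) / 6, method="linear")


def classify_by_thresholds(
    indices: Sequence[float],
    cuts: Sequence[float],
    order: Sequence[str] = DEFAULT_ORDER,
    subject_ids: Optional[Sequence[str]] = None,
    clinical_types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Bin grading indices into the six patterns.

    ``cuts`` are five strictly ascending thresholds.  An index at or below
    the first cut gets the finest label (rank 6); one above the last cut
    the coarsest (rank 1); boundary values fall to the finer bin.
    """
    cuts = np.asarray(cuts, dtype=float)
    if cuts.shape != (5,) or not np.all(np.diff(cuts) > 0):
        raise ValueError("cuts must be 5 strictly ascending values")
    if len(order) != 6 or set(order) != set("ABCDEF"):
        raise ValueError("order must be a permutation of A-F")
    indices = np.asarray(indices, dtype=float)
    # np.searchsorted(side='left'): count of cuts strictly below the index,
    # so a value equal to a cut stays in the lower (finer) bin.
    n_above = np.searchsorted(cuts, indices, side="left")
    ranks = 6 - n_above  # 6 = finest ... 1 = coarsest
    labels = [order[r - 1] for r in ranks]
    return pd.DataFrame(
        {
            "subject_id": (
                list(subject_ids)
                if subject_ids is not None
                else [f"S{i:03d}" for i in range(len(indices))]
            ),
            "grading_index": indices,
            "pattern": labels,
            "coarseness_rank": ranks,
            "clinical_type": (
                list(clinical_types) if clinical_types is not None else "NA"
            ),
        }
    )


def pattern_frequency_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of each pattern, split by clinical type.

    The percentage denominator is the number of assigned case subjects
    (clinical type other than ``control``), matching how pattern shares
    are quoted clinically; an all-control input yields zero percentages.
    """
    labels = sorted(set(DEFAULT_ORDER))
    if assignments.empty:
        return pd.DataFrame(
            {"pattern": labels, "count": 0, "percent_of_cases": 0.0}
        )
    is_case = assignments["clinical_type"] != "control"
    n_cases = int(is_case.sum())
    counts = (
        assignments.loc[is_case]
        .groupby("pattern")["subject_id"]
        .count()
        .reindex(labels, fill_value=0)
    )
    table = pd.DataFrame(
        {
            "pattern": labels,
            "count": counts.values,
            "percent_of_cases": (
                counts.values / n_cases * 100.0 if n_cases else 0.0
            ),
        }
    )
    by_type = (
        assignments.loc[is_case]
        .groupby(["pattern", "clinical_type"])["subject_id"]
        .count()
        .unstack(fill_value=0)
        .reindex(labels, fill_value=0)
    )
    for col in by_type.columns:
        table[f"n_{col}"] = by_type[col].values
    table.attrs["percent_denominator"] = n_cases
    return table


def cohort_share(count: int, total: int) -> float:
    """Percentage share of a subgroup in a cohort (e.g. 7 of 39 -> 17.9)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return count / total * 100.0
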