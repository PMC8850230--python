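import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from octatex import cfd_stats, reference_tables


def t_tail_by_integration(t_obs, df):
    """Two-sided t tail probability by direct numerical integration of the
    Student density; independent of the implementation's scipy call."""

    def pdf(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(pdf, abs(t_obs), math.inf)
    return 2 * tail


class TestSummarize:
    def records(self, case_values, control_values, sector="whole"):
        rows = [
            {"subject_id": f"P{i}", "group": "case", "sector": sector, "value": v}
            for i, v in enumerate(case_values)
        ] + [
            {"subject_id": f"C{i}", "group": "control", "sector": sector, "value": v}
            for i, v in enumerate(control_values)
        ]
        return pd.DataFrame(rows)

    def test_hand_arithmetic_cell(self):
        out = cfd_stats.summarize(self.records([1, 2, 3], [4, 4]))
        case = out[out["group"] == "case"].iloc[0]
        assert case["mean"] == 2 and case["sd"] == pytest.approx(1.0)
        assert case["median"] == 2 and case["n"] == 3

    def test_single_record_cell_flagged_unusable(self):
        out = cfd_stats.summarize(self.records([1.0], [4, 5]))
        case = out[out["group"] == "case"].iloc[0]
        assert not case["usable"]
        assert out[out["group"] == "control"].iloc[0]["usable"]

    def test_constant_cell_has_zero_spread(self):
        out = cfd_stats.summarize(self.records([5, 5, 5], [1, 2]))
        case = out[out["group"] == "case"].iloc[0]
        assert case["sd"] == 0 and case["iqr"] == 0


class TestTTest:
    def test_equal_means_give_t_zero_p_one(self):
        res = cfd_stats.t_test_from_summary(10, 2, 8, 10, 3, 9)
        assert res.statistic == 0 and res.p_two_sided == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["t_pooled", "t_welch"])
    def test_matches_numerical_integration_oracle(self, method):
        res = cfd_stats.t_test_from_summary(10, 2, 5, 12, 2, 5, method=method)
        # textbook arithmetic: se = 2*sqrt(2/5), t = -2/se, df = 8
        assert res.statistic == pytest.approx(-2 / (2 * math.sqrt(0.4)))
        assert res.df == pytest.approx(8.0)
        assert res.p_two_sided == pytest.approx(
            t_tail_by_integration(res.statistic, res.df), abs=1e-10
        )

    def test_parafovea_row_reproduces_printed_bound(self):
        for method in ("t_pooled", "t_welch"):
            res = cfd_stats.t_test_from_summary(
                53.02, 5.41, 41, 58.72, 5.41, 35, method=method
            )
            assert res.p_two_sided <= 0.0001

    def test_samples_path_equals_summary_path(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 15), rng.normal(1, 2, 12)
        for method in ("t_pooled", "t_welch"):
            a = cfd_stats.t_test_from_samples(x, y, method)
            b = cfd_stats.t_test_from_summary(
                x.mean(), x.std(ddof=1), 15, y.mean(), y.std(ddof=1), 12, method
            )
            assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
            assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)

    @pytest.mark.parametrize(
        "method,equal_var", [("t_pooled", True), ("t_welch", False)]
    )
    def test_cross_checked_against_scipy_ttest_ind(self, method, equal_var):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0.7, 1.5, 25)
        mine = cfd_stats.t_test_from_samples(x, y, method)
        ref = stats.ttest_ind(x, y, equal_var=equal_var)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_samples_give_t_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert cfd_stats.t_test_from_samples(x, x).statistic == 0

    def test_well_separated_samples_are_significant_across_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            res = cfd_stats.t_test_from_samples(
                rng.normal(0, 1, 20), rng.normal(5, 1, 20)
            )
            assert res.p_two_sided < 0.001

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(3, 1, 10), rng.normal(5, 2, 14)
        base = cfd_stats.t_test_from_samples(x, y)
        shifted = cfd_stats.t_test_from_samples(x + 100, y + 100)
        scaled = cfd_stats.t_test_from_samples(x * 7, y * 7)
        assert base.statistic == pytest.approx(shifted.statistic, abs=1e-9)
        assert base.statistic == pytest.approx(scaled.statistic, abs=1e-9)

    def test_pooled_equals_welch_for_balanced_equal_sd(self):
        a = cfd_stats.t_test_from_summary(10, 3, 12, 14, 3, 12, "t_pooled")
        b = cfd_stats.t_test_from_summary(10, 3, 12, 14, 3, 12, "t_welch")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.df == pytest.approx(b.df, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cfd_stats.t_test_from_summary(1, 0, 5, 2, 0, 5)
        with pytest.raises(ValueError):
            cfd_stats.t_test_from_summary(1, 1, 1, 2, 1, 5)
        with pytest.raises(ValueError):
            cfd_stats.t_test_from_samples([1.0], [2.0, 3.0])


class TestChiSquared:
    def test_homogeneous_table_gives_zero_statistic(self):
        res = cfd_stats.chi_squared_test([[10, 10], [10, 10]])
        assert res.statistic == 0 and res.p_two_sided == pytest.approx(1.0)

    def test_diagonal_table_hand_computation(self):
        res = cfd_stats.chi_squared_test([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)
        assert res.df == 1

    def test_2x3_uniform_table_df(self):
        assert cfd_stats.chi_squared_test([[5, 5, 5], [5, 5, 5]]).df == 2

    def test_cross_checked_against_scipy_contingency(self):
        table = np.array([[12, 5, 9], [3, 14, 7]])
        mine = cfd_stats.chi_squared_test(table)
        ref = stats.chi2_contingency(table, correction=False)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)

    def test_permutation_invariance(self):
        table = np.array([[12, 5, 9], [3, 14, 7]])
        base = cfd_stats.chi_squared_test(table)
        assert cfd_stats.chi_squared_test(table[::-1]).statistic == pytest.approx(
            base.statistic
        )
        assert cfd_stats.chi_squared_test(
            table[:, [2, 0, 1]]
        ).statistic == pytest.approx(base.statistic)

    def test_zero_margin_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="expected"):
            cfd_stats.chi_squared_test([[5, 0], [7, 0]])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cfd_stats.cohen_kappa(list("AABB"), list("AABB")) == 1.0

    def test_perfect_disagreement(self):
        # p_o = 0, p_e = 0.5 by hand
        assert cfd_stats.cohen_kappa(list("AABB"), list("BBAA")) == -1.0

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(3)
        r1 = rng.integers(0, 4, 5000)
        r2 = rng.integers(0, 4, 5000)
        assert abs(cfd_stats.cohen_kappa(r1, r2)) < 0.05

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r1 = rng.integers(0, 3, 30)
            r2 = rng.integers(0, 3, 30)
            k = cfd_stats.cohen_kappa(r1, r2)
            assert k == pytest.approx(cfd_stats.cohen_kappa(r2, r1), abs=1e-12)
            assert -1.0 <= k <= 1.0

    def test_cross_checked_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        r1 = rng.integers(0, 3, 100)
        r2 = np.where(rng.random(100) < 0.7, r1, rng.integers(0, 3, 100))
        assert cfd_stats.cohen_kappa(r1, r2) == pytest.approx(
            cohen_kappa_score(r1, r2), abs=1e-12
        )

    def test_identical_constant_raters_defined_as_one(self):
        assert cfd_stats.cohen_kappa(["A", "A"], ["A", "A"]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cfd_stats.cohen_kappa([1, 2], [1, 2, 3])


class TestSummaryFrame:
    def test_every_sector_row_tested(self):
        table = cfd_stats.tests_from_summary_frame(
            reference_tables.case_control_summary()
        )
        assert set(table["sector"]) == set(reference_tables.SECTORS)
        assert (table["p"] <= 1).all() and (table["p"] >= 0).all()

    def test_missing_column_named_in_error(self):
        bad = reference_tables.case_control_summary().drop(columns=["sd_case"])
        with pytest.raises(ValueError, match="sd_case"):
            cfd_stats.tests_from_summary_frame(bad)

    def test_records_path_agrees_with_summary_path(self):
        rng = np.random.default_rng(6)
        rows = []
        for sector in ("whole", "fovea"):
            for group, mu in (("case", 50), ("control", 55)):
                for i, v in enumerate(rng.normal(mu, 5, 12)):
                    rows.append(
                        {
                            "subject_id": f"{group}{i}",
                            "group": group,
                            "sector": sector,
                            "value": v,
                        }
                    )
        records = pd.DataFrame(rows)
        from_records = cfd_stats.tests_from_records(records)
        for _, row in from_records.iterrows():
            sub = records[records["sector"] == row["sector"]]
            x = sub[sub["group"] == "case"]["value"].to_numpy()
            y = sub[sub["group"] == "control"]["value"].to_numpy()
            direct = cfd_stats.t_test_from_samples(x, y)
            assert row["p"] == pytest.approx(direct.p_two_sided, abs=1e-12)
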