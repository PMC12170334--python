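import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lashearmap.stats import (
    assign_quartiles,
    auto_test_selection,
    classify_fibrosis,
    compare_correlations_fisher,
    per_case_correlations,
    pooled_quartile_chisq,
    quartile_analysis,
)


def bivariate_case(rho, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    return x, y


class TestPerCaseCorrelations:
    def test_perfect_negative(self):
        x = np.linspace(0, 1, 100)
        df = pd.DataFrame({"TAWSS": x, "BV": -x})
        out = per_case_correlations(df, pairs=[("TAWSS", "BV")])
        assert out.loc[0, "r"] == pytest.approx(-1.0)
        assert out.loc[0, "p"] < 1e-10

    def test_null_case_near_zero(self):
        x, y = bivariate_case(0.0, 20000, 0)
        df = pd.DataFrame({"TAWSS": x, "BV": y})
        out = per_case_correlations(df, pairs=[("TAWSS", "BV")])
        assert abs(out.loc[0, "r"]) < 0.03

    def test_prescribed_rho_and_covariance_oracle(self):
        x, y = bivariate_case(-0.4, 20000, 1)
        df = pd.DataFrame({"TAWSS": x, "BV": y})
        out = per_case_correlations(df, pairs=[("TAWSS", "BV")])
        assert -0.43 <= out.loc[0, "r"] <= -0.37
        # brute-force covariance-formula oracle
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out.loc[0, "r"] == pytest.approx(oracle, abs=1e-12)

    def test_pairwise_deletion_counts(self):
        x = np.arange(30.0)
        y = -x.copy()
        y[:5] = np.nan
        out = per_case_correlations(
            pd.DataFrame({"TAWSS": x, "BV": y}), pairs=[("TAWSS", "BV")]
        )
        assert out.loc[0, "n"] == 25

    def test_zero_variance_flagged(self):
        out = per_case_correlations(
            pd.DataFrame({"TAWSS": np.ones(20), "BV": np.arange(20.0)}),
            pairs=[("TAWSS", "BV")],
        )
        assert np.isnan(out.loc[0, "r"])
        assert "variance" in out.loc[0, "reason"]

    def test_affine_invariance_sign_aware(self):
        x, y = bivariate_case(0.5, 2000, 2)
        r1 = per_case_correlations(
            pd.DataFrame({"TAWSS": x, "BV": y}), pairs=[("TAWSS", "BV")]
        ).loc[0, "r"]
        r2 = per_case_correlations(
            pd.DataFrame({"TAWSS": 3 * x + 7, "BV": -2 * y + 1}), pairs=[("TAWSS", "BV")]
        ).loc[0, "r"]
        assert r2 == pytest.approx(-r1, abs=1e-12)


class TestQuartiles:
    def test_exact_small_case(self):
        q = assign_quartiles(np.arange(1.0, 9.0))
        np.testing.assert_array_equal(q, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        x = rng.random(500)
        np.testing.assert_array_equal(assign_quartiles(x), assign_quartiles(x + 100.0))

    def test_balanced_partition(self):
        rng = np.random.default_rng(4)
        q = assign_quartiles(rng.random(10007))
        counts = np.bincount(q)[1:]
        assert counts.max() - counts.min() <= 3

    def test_identical_response_gives_null_kruskal(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"TAWSS": rng.random(400), "BV": np.full(400, 1.0)})
        res = quartile_analysis(df, responses=("BV",))
        assert res["tests"]["BV"]["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["tests"]["BV"]["p"] == pytest.approx(1.0)

    def test_monotone_response_and_rank_oracle(self):
        """Strictly decreasing response: quartile means monotone and the
        Kruskal-Wallis statistic matches a brute-force rank-sum oracle."""
        rng = np.random.default_rng(6)
        x = rng.random(800)
        y = -x + 0.01 * rng.random(800)
        df = pd.DataFrame({"TAWSS": x, "BV": y})
        res = quartile_analysis(df, responses=("BV",))
        means = res["summaries"]["BV"]["mean"].to_numpy()
        assert (np.diff(means) < 0).all()
        # brute-force KW: H = (12 / (N (N+1))) sum n_i (Rbar_i - Rbar)^2
        q = res["quartile"]
        ranks = sps.rankdata(y)
        N = len(y)
        H = 0.0
        for k in (1, 2, 3, 4):
            ri = ranks[q == k]
            H += len(ri) * (ri.mean() - (N + 1) / 2) ** 2
        H *= 12 / (N * (N + 1))
        assert res["tests"]["BV"]["statistic"] == pytest.approx(H, abs=1e-9)


class TestClassifyFibrosis:
    def test_iir_threshold_inclusive(self):
        labels = classify_fibrosis(np.array([1.2]), np.array([1.0]))
        assert labels.fibrosis[0]

    def test_bv_threshold_strict(self):
        labels = classify_fibrosis(np.array([1.0]), np.array([0.5]))
        assert not labels.scar[0]
        assert classify_fibrosis(np.array([1.0]), np.array([0.49])).scar[0]

    def test_all_below_threshold_no_flags(self):
        labels = classify_fibrosis(np.full(50, 1.0), np.full(50, 2.0))
        assert labels.fibrosis.sum() == 0
        assert labels.scar.sum() == 0

    def test_counts_exclude_undefined(self):
        iir = np.array([1.3, np.nan, 1.5])
        bv = np.array([0.2, 0.3, np.nan])
        c = classify_fibrosis(iir, bv).counts()
        assert c["n_fibrosis_defined"] == 2 and c["fibrosis"] == 2
        assert c["n_scar_defined"] == 2 and c["scar"] == 2


class TestPooledChiSquare:
    def test_uniform_prevalence_null(self):
        rng = np.random.default_rng(7)
        q = np.repeat([1, 2, 3, 4], 250)
        flags = rng.random(1000) < 0.3
        res = pooled_quartile_chisq(flags, q)
        assert res["p"] > 0.01

    def test_matches_direct_formula_oracle(self):
        """Contingency [[90,10],[80,20],[60,40],[30,70]] vs hand-computed
        sum (O-E)^2 / E."""
        table = np.array([[90, 10], [80, 20], [60, 40], [30, 70]])
        q = np.repeat([1, 2, 3, 4], 100)
        flags = np.concatenate([
            np.r_[np.ones(a, bool), np.zeros(b, bool)] for a, b in table
        ])
        res = pooled_quartile_chisq(flags, q)
        col = table.sum(axis=0)
        row = table.sum(axis=1)
        expected = np.outer(row, col) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert res["statistic"] == pytest.approx(oracle, abs=1e-9)
        assert res["df"] == 3

    def test_monotone_prevalence_detected(self):
        rng = np.random.default_rng(8)
        q = np.repeat([1, 2, 3, 4], 1000)
        p_by_q = np.repeat([0.05, 0.15, 0.3, 0.5], 1000)
        flags = rng.random(4000) < p_by_q
        res = pooled_quartile_chisq(flags, q)
        assert (np.diff(res["prevalence"]) > 0).all()
        assert res["p"] < 0.001

    def test_empty_quartile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pooled_quartile_chisq(np.ones(10, bool), np.repeat([1, 2, 3], [4, 3, 3]))


class TestFisherComparison:
    def test_identical_groups_p_one(self):
        r = [0.3, 0.4, 0.35, 0.45]
        res = compare_correlations_fisher(r, r)
        assert res["p"] == pytest.approx(1.0)

    def test_atanh_transform_value(self):
        # atanh(0.5) = 0.5493 to 4 decimals
        res = compare_correlations_fisher([0.5, 0.5], [0.5, 0.5])
        assert res["z_mean_a"] == pytest.approx(0.5493, abs=5e-5)

    def test_boundary_r_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            compare_correlations_fisher([1.0, 0.5], [0.3, 0.4])

    def test_type_one_error_quick_check(self):
        """Null rejection rate over 200 replicates is near alpha (loose
        band; the calibrated 1,000-replicate version runs in acceptance)."""
        rng = np.random.default_rng(0)
        rej = 0
        reps = 200
        for _ in range(reps):
            def group_r(k, n=300, rho=0.3):
                z = rng.standard_normal((k, n, 2))
                x = z[:, :, 0]
                y = rho * x + np.sqrt(1 - rho**2) * z[:, :, 1]
                xm = x - x.mean(1, keepdims=True)
                ym = y - y.mean(1, keepdims=True)
                return (xm * ym).sum(1) / np.sqrt((xm**2).sum(1) * (ym**2).sum(1))

            rej += compare_correlations_fisher(group_r(8), group_r(8))["p"] < 0.05
        assert 0.01 <= rej / reps <= 0.10


class TestAutoTestSelection:
    def test_normal_groups_use_anova(self):
        rng = np.random.default_rng(42)
        res = auto_test_selection([rng.standard_normal(200), rng.standard_normal(200) + 0.1])
        assert res["test"] == "anova"

    def test_heavy_tails_use_kruskal(self):
        rng = np.random.default_rng(43)
        res = auto_test_selection([rng.standard_cauchy(200), rng.standard_cauchy(200)])
        assert res["test"] == "kruskal-wallis"

    def test_unequal_variances_use_welch(self):
        rng = np.random.default_rng(44)
        res = auto_test_selection([rng.standard_normal(120), 3.2 * rng.standard_normal(120)])
        assert res["test"] == "welch-anova"

    def test_decision_trail_recorded(self):
        rng = np.random.default_rng(42)
        res = auto_test_selection([rng.standard_normal(200), rng.standard_normal(200)])
        assert res["trail"][0]["step"] == "shapiro-wilk"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            auto_test_selection([[1.0, 2.0], [3.0, 4.0, 5.0]])
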