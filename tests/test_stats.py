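"""Reliability (ICC/SEM), correlation, agreement and power statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from jumpmetrics import (
    f2_from_r2,
    icc_absolute_agreement,
    paired_comparison,
    power_min_n,
    regression_power,
    reliability_report,
    sem_from_icc,
)
from jumpmetrics.stats import correlations_bonferroni, normality_check


def icc21_by_sums_of_squares(x: np.ndarray) -> float:
    """Definitional two-way ANOVA ICC(2,1), written out from scratch."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_trials_give_perfect_reliability(self):
        x = np.tile(np.array([[10.0], [20.0], [30.0], [40.0]]), (1, 3))
        res = icc_absolute_agreement(x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_toy_matrix_matches_definitional_anova(self):
        x = np.array(
            [[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0], [7.0, 1.0, 2.0]]
        )
        res = icc_absolute_agreement(x)
        assert res.icc == pytest.approx(icc21_by_sums_of_squares(x), abs=1e-10)

    def test_random_matrices_match_definitional_anova(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n, k = rng.integers(3, 12), rng.integers(2, 6)
            x = rng.normal(50, 10, size=(n, 1)) + rng.normal(0, 4, size=(n, k))
            res = icc_absolute_agreement(x)
            assert res.icc == pytest.approx(icc21_by_sums_of_squares(x), abs=1e-10)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(13)
        x = rng.normal(100, 15, size=(10, 1)) + rng.normal(0, 5, size=(10, 3))
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subj", raters="rater", ratings="y")
        row1 = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        rowk = ref[ref["Type"] == "ICC(A,k)"].iloc[0]
        single = icc_absolute_agreement(x, form="single")
        average = icc_absolute_agreement(x, form="average")
        assert single.icc == pytest.approx(row1["ICC"], abs=1e-9)
        assert average.icc == pytest.approx(rowk["ICC"], abs=1e-9)
        assert single.ci_low == pytest.approx(row1["CI95"][0], abs=0.01)
        assert single.ci_high == pytest.approx(row1["CI95"][1], abs=0.01)

    def test_pure_noise_has_near_zero_icc(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, size=(200, 3))  # zero subject variance
        res = icc_absolute_agreement(x)
        assert abs(res.icc) < 0.1

    def test_rejects_missing_cells_and_zero_variance(self):
        x = np.ones((4, 3))
        with pytest.raises(ValueError, match="variance"):
            icc_absolute_agreement(x)
        x = np.random.default_rng(0).normal(size=(4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_absolute_agreement(x)

    def test_reliability_report_bands_use_ci_lower_bound(self):
        rng = np.random.default_rng(15)
        x = rng.normal(100, 30, size=(12, 1)) + rng.normal(0, 2, size=(12, 3))
        rep = reliability_report(x)
        assert rep.icc_ci_low <= rep.icc <= rep.icc_ci_high
        assert rep.interpretation in ("poor", "moderate", "good", "excellent")
        assert rep.sem == pytest.approx(rep.sd * np.sqrt(1 - rep.icc))
        assert rep.sem_percent == pytest.approx(100 * rep.sem / rep.mean)


class TestSEM:
    def test_closed_forms(self):
        assert sem_from_icc(10.0, 0.84) == pytest.approx(4.0)
        assert sem_from_icc(10.0, 1.0) == 0.0
        sem, pct = sem_from_icc(10.0, 0.84, mean=200.0)
        assert pct == pytest.approx(2.0)

    def test_published_sem_percent_row(self):
        # SEM 219.64 W against a mean of 4336.2 W is the printed "5%"
        sem = 219.64
        pct = 100 * sem / 4336.2
        assert round(pct) == 5

    @given(st.floats(0.0, 0.99), st.floats(0.0, 0.99))
    def test_monotone_decreasing_in_icc(self, icc_a, icc_b):
        lo, hi = sorted((icc_a, icc_b))
        assert sem_from_icc(10.0, hi) <= sem_from_icc(10.0, lo)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sem_from_icc(10.0, 1.2)
        with pytest.raises(ValueError):
            sem_from_icc(10.0, 0.5, mean=0.0)


class TestCorrelations:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        out = correlations_bonferroni({"m": x}, 2 * x + 1, m_tests=10)
        assert out.loc["m", "r"] == pytest.approx(1.0)
        assert out.loc["m", "p_adjusted"] <= 10 * out.loc["m", "p_raw"] + 1e-15
        assert out.loc["m", "magnitude"] == "extremely high"

    def test_toy_pairs_match_definitional_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_def = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        out = correlations_bonferroni({"m": x}, y, m_tests=1)
        assert out.loc["m", "r"] == pytest.approx(r_def, abs=1e-12)
        assert out.loc["m", "r"] == pytest.approx(0.8220, abs=5e-4)

    def test_bonferroni_clamped_at_one(self):
        rng = np.random.default_rng(16)
        out = correlations_bonferroni(
            {"m": rng.normal(size=8)}, rng.normal(size=8), m_tests=10
        )
        assert out["p_adjusted"].iloc[0] <= 1.0
        assert out["p_adjusted"].iloc[0] >= out["p_raw"].iloc[0]

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="flatline"):
            correlations_bonferroni(
                {"flatline": np.ones(6)}, np.arange(6.0), m_tests=1
            )


class TestPairedComparison:
    def test_perfect_agreement(self):
        m = np.array([100.0, 110.0, 120.0])
        rep = paired_comparison(m, m)
        assert rep.bias == 0.0
        assert rep.loa_low == rep.loa_high == 0.0
        assert rep.cohens_d == 0.0
        assert rep.t_p_value == 1.0
        assert rep.d_interpretation == "negligible"

    def test_alternating_differences_closed_form(self):
        m = np.zeros(4)
        e = np.array([1.0, -1.0, 1.0, -1.0])
        rep = paired_comparison(e, m)
        assert rep.bias == 0.0
        assert rep.sd_diff == pytest.approx(1.1547, abs=1e-4)
        assert rep.loa_high == pytest.approx(2.2632, abs=1e-3)
        assert rep.loa_low == pytest.approx(-2.2632, abs=1e-3)

    def test_exact_constant_offset(self):
        m = np.array([1.0, 2.0, 3.0])
        rep = paired_comparison(m + 5.0, m)
        assert rep.t_p_value == 0.0
        assert np.isinf(rep.cohens_d)

    def test_loa_cover_95_percent_of_large_normal_sample(self):
        rng = np.random.default_rng(17)
        m = rng.normal(120, 40, size=10000)
        e = m + rng.normal(2, 12, size=10000)
        rep = paired_comparison(e, m)
        inside = np.mean((e - m >= rep.loa_low) & (e - m <= rep.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)


class TestPower:
    def test_f2_from_r2_values(self):
        assert f2_from_r2(0.60) == pytest.approx(1.50)
        assert f2_from_r2(0.0) == 0.0
        assert f2_from_r2(0.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            f2_from_r2(1.0)

    def test_study_sample_size(self):
        assert power_min_n(1.5, 0.05, 0.80, 2) == 11

    def test_small_effect_sample_size(self):
        # frozen from a 1e4-replicate Monte-Carlo rejection-rate oracle
        assert power_min_n(0.15, 0.05, 0.80, 2) == 68

    def test_minimality_contract(self):
        n = power_min_n(1.5, 0.05, 0.80, 2)
        assert regression_power(n, 1.5, 2) >= 0.80
        assert regression_power(n - 1, 1.5, 2) < 0.80

    def test_power_monotone_in_n_and_f2(self):
        p = [regression_power(n, 0.5, 2) for n in range(5, 40)]
        assert all(b >= a for a, b in zip(p, p[1:]))
        assert regression_power(20, 0.8, 2) >= regression_power(20, 0.5, 2)

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="reaches"):
            power_min_n(1e-9, 0.05, 0.99, 2, max_n=50)


class TestNormality:
    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(18)
        pvals = [normality_check(rng.normal(size=100))[1] for _ in range(1000)]
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_skewed_samples_rejected(self):
        rng = np.random.default_rng(19)
        rejected = sum(
            normality_check(rng.exponential(size=100))[1] < 0.05 for _ in range(200)
        )
        assert rejected >= 0.95 * 200
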