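import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewasrf import (
    AssociationResult,
    associate_all,
    bonferroni_alpha,
    crude_vs_adjusted,
    fit_logistic,
    load_atopy_summary,
    prevalence_chi2,
    significance_filter,
)
from ewasrf.errors import CollinearityError, DegenerateInputError, SeparationError


def _grouped_2x2(a, b, c, d):
    """Binary exposure/outcome data with cells (exposed events a, exposed
    non-events b, unexposed events c, unexposed non-events d)."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = pd.Series(np.r_[np.ones(a + b), np.zeros(c + d)])
    return y, x


class TestFitLogistic:
    def test_matches_closed_form_log_odds_ratio(self):
        y, x = _grouped_2x2(30, 10, 20, 40)
        fit = fit_logistic(y, x)
        assert fit.coef == pytest.approx(np.log((30 * 40) / (20 * 10)),
                                         abs=1e-6)

    def test_null_exposure_coefficient_small(self):
        rng = np.random.default_rng(30)
        n = 10_000
        y = rng.binomial(1, 0.5, n)
        x = pd.Series(rng.normal(size=n))
        assert abs(fit_logistic(y, x).coef) < 0.1

    def test_constant_outcome_rejected(self):
        x = pd.Series(np.random.default_rng(31).normal(size=50))
        with pytest.raises(DegenerateInputError):
            fit_logistic(np.ones(50), x)

    def test_wald_p_affine_equivariant(self):
        rng = np.random.default_rng(32)
        x = pd.Series(rng.normal(size=300))
        y = rng.binomial(1, 1 / (1 + np.exp(-0.5 * x)))
        f1 = fit_logistic(y, x)
        f2 = fit_logistic(y, 2 * x)
        assert f2.coef == pytest.approx(f1.coef / 2, rel=1e-6)
        assert f2.wald_p == pytest.approx(f1.wald_p, abs=1e-9)

    def test_separation_flagged(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        x = pd.Series(np.r_[np.linspace(-2, -0.1, 20), np.linspace(0.1, 2, 20)])
        with pytest.raises(SeparationError):
            fit_logistic(y, x)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(33)
        x = pd.Series(rng.normal(size=200))
        cov = pd.DataFrame({"a": rng.normal(size=200)})
        cov["b"] = cov["a"] * 2.0
        y = rng.binomial(1, 0.4, 200)
        with pytest.raises(CollinearityError, match="b"):
            fit_logistic(y, x, cov)

    def test_casewise_deletion(self):
        y, x = _grouped_2x2(30, 10, 20, 40)
        x_miss = x.copy()
        x_miss.iloc[:5] = np.nan
        fit = fit_logistic(y, x_miss)
        assert fit.n_used == 95


class TestCrudeVsAdjusted:
    def test_equal_coefficients_zero_pct(self):
        res = AssociationResult("p", "atopy", 1.5, 0.1, 0.01, 1.5, 0.1, 0.01,
                                100, 0.05)
        assert res.pct_diff_beta == 0.0

    def test_published_orientation(self):
        """Printed crude 2.43 -> adjusted 2.61 is reported as +7.49%; the
        (adjusted - crude)/crude orientation lands within 0.5 points from
        rounded inputs."""
        res = AssociationResult("p", "atopy", 2.43, 0.1, 0.01, 2.61, 0.1,
                                0.01, 100, 0.05)
        assert res.pct_diff_beta == pytest.approx(7.49, abs=0.5)

    def test_zero_crude_undefined(self):
        res = AssociationResult("p", "atopy", 0.0, 0.1, 0.5, 0.2, 0.1, 0.3,
                                100, 0.05)
        assert res.pct_diff_beta is None

    def test_orthogonal_covariates_small_shift(self):
        """Covariates independent of the exposure barely move the
        coefficient in a large null-ish simulation."""
        rng = np.random.default_rng(34)
        n = 5_000
        x = pd.Series(rng.normal(size=n))
        cov = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.8 * x))))
        res = crude_vs_adjusted(y, x, cov)
        assert abs(res.pct_diff_beta) < 5.0


class TestBonferroni:
    @pytest.mark.parametrize("n,expected", [(62, 0.05 / 62), (1, 0.05),
                                            (10, 0.005)])
    def test_values(self, n, expected):
        assert bonferroni_alpha(n) == pytest.approx(expected, rel=1e-12)

    def test_printed_precision(self):
        assert f"{bonferroni_alpha(62):.2E}" == "8.06E-04"

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


class TestSignificanceFilter:
    def test_published_counts(self):
        """The 22 printed atopy p-values and 12 of the 22 high-IgE p-values
        clear the 0.05/62 threshold."""
        summary = load_atopy_summary()
        alpha = bonferroni_alpha(62)
        assert significance_filter(summary["atopy_p"], alpha)[1] == 22
        assert significance_filter(summary["ige_p"], alpha)[1] == 12

    def test_zero_alpha_retains_nothing(self):
        assert significance_filter([0.001, 0.5], 0.0)[1] == 0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(35)
        pvals = rng.random(200)
        retained, n = significance_filter(pvals, 0.3)
        oracle = [p for p in pvals if p < 0.3]
        assert n == len(oracle)
        assert retained == oracle  # stable order

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50),
           st.floats(min_value=0, max_value=1),
           st.floats(min_value=0, max_value=1))
    def test_count_monotone_in_alpha(self, pvals, a1, a2):
        lo, hi = sorted([a1, a2])
        assert significance_filter(pvals, lo)[1] <= \
            significance_filter(pvals, hi)[1]


class TestPrevalenceChi2:
    def test_published_high_ige_comparison(self):
        """Yates-corrected chi-square on (24/77 females vs 18/25 males)
        reproduces the printed p = 0.047."""
        _, p = prevalence_chi2([[24, 77], [18, 25]], continuity_correction=True)
        assert round(p, 3) == 0.047

    def test_balanced_table_clamps_to_zero(self):
        stat, p = prevalence_chi2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_uncorrected_matches_hand_formula(self):
        a, b, c, d = 76, 166, 49, 71
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / \
            ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = prevalence_chi2([[a, b], [c, d]], continuity_correction=False)
        assert stat == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            prevalence_chi2([[0, 0], [5, 5]])


class TestFamilywiseControl:
    def test_null_fwer_bounded(self):
        """With m null probes tested at 0.05/m, the share of replicates with
        any false positive stays near or below 5% (binomial tolerance over
        100 seeded replicates)."""
        m, n = 20, 150
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            y = rng.binomial(1, 0.4, n)
            M = pd.DataFrame(rng.normal(size=(m, n)),
                             index=[f"p{i}" for i in range(m)],
                             columns=[f"s{i}" for i in range(n)])
            cov = pd.DataFrame(rng.dirichlet(np.ones(3) * 10, n)[:, :2],
                               index=M.columns, columns=["c1", "c2"])
            results, _ = associate_all(M, pd.Series(y, index=M.columns), cov,
                                       "atopy")
            alpha = bonferroni_alpha(m)
            if significance_filter(results, alpha)[1] > 0:
                hits += 1
        assert hits <= 10  # binomial(100, 0.05) upper tolerance
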