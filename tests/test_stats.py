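"""Voom weights, moderated contrasts, the decision rule, π0/FDR, thinning."""

import numpy as np
import pytest
from scipy import stats as sps

from splicescope.stats import (
    DesignSpec,
    estimate_pi0_fdr,
    fit_contrasts,
    fit_variance_prior,
    moderate,
    subsample_counts,
    summarize_event,
    summarize_p,
    voom_transform,
)


def two_group_design(n_per_group):
    cond = ["a"] * n_per_group + ["b"] * n_per_group
    return DesignSpec.from_factors(["x"] * 2 * n_per_group, cond)


class TestDesignSpec:
    def test_rank_deficiency_names_columns(self):
        with pytest.raises(ValueError, match="collinear"):
            DesignSpec(np.ones((4, 2)), [1, 0], ["intercept", "dup"])

    def test_factor_design_shape(self):
        d = DesignSpec.from_factors(["l1", "l1", "l2", "l2"], ["c", "t", "c", "t"])
        assert d.design.shape == (4, 3)
        assert d.contrast.tolist() == [0.0, 0.0, 1.0]


class TestVoom:
    def test_zero_count_log_cpm(self):
        y, _ = voom_transform(np.zeros((1, 2)), [1e6, 1e6])
        assert y[0, 0] == pytest.approx(np.log2(0.5 / 1000001 * 1e6), abs=1e-9)
        assert y[0, 0] == pytest.approx(-1.0, abs=1e-4)

    def test_few_rows_fall_back_to_unit_weights(self):
        y, w = voom_transform(np.arange(20).reshape(4, 5) + 1, np.full(5, 1e6))
        assert np.all(w == 1.0)

    def test_constant_counts_give_equal_weights_within_row(self, rng):
        counts = np.tile(rng.integers(5, 500, size=(60, 1)), (1, 6))
        y, w = voom_transform(counts, np.full(6, 1e6))
        assert np.allclose(w, w[:, :1])

    def test_weights_increase_with_count(self, rng):
        """Under NB noise the fitted trend gives low counts low precision."""
        means = np.repeat([5.0, 50.0, 500.0], 40)
        shape = 1 / 0.1
        lam = rng.gamma(shape, means[:, None] / shape, size=(120, 8))
        counts = rng.poisson(lam)
        _, w = voom_transform(counts, np.full(8, 1e6))
        mean_w = w.mean(axis=1)
        assert mean_w[:40].mean() < mean_w[40:80].mean() < mean_w[80:].mean()


class TestFitContrasts:
    def test_two_group_contrast_is_difference_of_means(self, rng):
        d = two_group_design(4)
        y = rng.normal(size=(3, 8))
        fit = fit_contrasts(y, None, d)
        want = y[:, 4:].mean(axis=1) - y[:, :4].mean(axis=1)
        assert np.allclose(fit.coefficients, want)

    def test_recovers_known_effect(self, rng):
        d = two_group_design(10)
        beta = 1.0
        y = np.where(np.arange(20) >= 10, beta, 0.0) + rng.normal(0, 0.2, (50, 20))
        fit = fit_contrasts(y, None, d)
        se = np.sqrt(fit.sigma2) * fit.stdev_unscaled_rows
        assert np.all(np.abs(fit.coefficients - beta) < 3 * se)

    def test_weight_scale_invariance(self, rng):
        d = two_group_design(4)
        y = rng.normal(size=(5, 8))
        w = rng.uniform(0.5, 2.0, size=(5, 8))
        f1 = fit_contrasts(y, w, d)
        f2 = fit_contrasts(y, 2.0 * w, d)
        assert np.allclose(f1.coefficients, f2.coefficients)


class TestModerate:
    def test_infinite_prior_shrinks_to_s0(self, rng):
        s2 = rng.uniform(0.5, 2.0, 20)
        _, _, s2_post, _ = moderate(
            np.ones(20), np.ones(20), s2, df=6, d0=np.inf, s0_2=1.3
        )
        assert np.allclose(s2_post, 1.3)

    def test_zero_prior_equals_ordinary_t(self, rng):
        n = 12
        coef = rng.normal(size=n)
        s2 = rng.uniform(0.5, 2.0, n)
        se_u = np.full(n, 0.5)
        t, p, _, df_tot = moderate(coef, se_u, s2, df=8, d0=0.0, s0_2=1.0)
        t_ref = coef / (np.sqrt(s2) * se_u)
        assert np.allclose(t, t_ref)
        assert df_tot == 8
        assert np.allclose(p, 2 * sps.t.sf(np.abs(t_ref), 8))

    def test_null_p_values_are_uniform(self, rng):
        """Moderated p-values on pure-noise rows pass a KS uniformity test."""
        y = rng.normal(size=(5000, 10))
        d = two_group_design(5)
        fit = fit_contrasts(y, None, d)
        _, p, _, _ = moderate(
            fit.coefficients, fit.stdev_unscaled_rows, fit.sigma2, fit.df_residual
        )
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_prior_fit_on_f_distributed_variances(self, rng):
        df, d0_true, s0_true = 6.0, 10.0, 1.5
        s2 = s0_true * rng.f(df, d0_true, size=20000) * 1.0
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0 == pytest.approx(s0_true, rel=0.1)


class TestDecisionRule:
    def test_opposite_signs_and_small_p_is_significant(self):
        r = summarize_event("e", 1e-5, 1e-4, +1.0, -1.0)
        assert r.sig_class == "significant" and r.p_summary == 1e-4

    def test_same_direction_never_significant(self):
        r = summarize_event("e", 1e-5, 1e-4, +1.0, +1.0)
        assert r.sig_class == "non_significant" and not r.direction_ok

    def test_intermediate_p_is_inconclusive(self):
        r = summarize_event("e", 0.0005, 0.05, +1.0, -1.0)
        assert r.p_summary == 0.05 and r.sig_class == "inconclusive"

    def test_large_p_is_non_significant(self):
        r = summarize_event("e", 0.5, 0.01, +1.0, -1.0)
        assert r.sig_class == "non_significant"

    def test_alternative_combiners(self):
        assert summarize_p(0.01, 0.02, "max") == 0.02
        assert 0.0 < summarize_p(0.01, 0.02, "fisher") < 0.01
        assert summarize_p(0.3, 0.4, "irwin_hall") == pytest.approx(0.7**2 / 2)


class TestPi0Fdr:
    def test_uniform_null_pi0_near_one(self, rng):
        res = estimate_pi0_fdr(rng.uniform(size=10000))
        assert res.pi0 == pytest.approx(1.0, abs=0.05)

    def test_mixture_recovers_pi0(self, rng):
        """54% uniform + 46% Beta(0.1, 10) alternatives → π̂0 ≈ 0.54."""
        m = 10000
        n_alt = int(0.46 * m)
        p = np.concatenate([
            rng.beta(0.1, 10.0, n_alt), rng.uniform(size=m - n_alt)
        ])
        res = estimate_pi0_fdr(p)
        assert res.pi0 == pytest.approx(0.54, abs=0.1)

    def test_q_values_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        res = estimate_pi0_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.q_values[order]) >= -1e-12)

    def test_fdr_non_decreasing_in_threshold(self, rng):
        p = np.concatenate([rng.beta(0.2, 5, 300), rng.uniform(size=700)])
        fdrs = [estimate_pi0_fdr(p, threshold=t).fdr_at_threshold
                for t in (0.001, 0.01, 0.05, 0.2)]
        # the q-value construction enforces monotone step-up estimates
        q = estimate_pi0_fdr(p).q_values
        assert np.all(np.diff(np.sort(q)) >= -1e-12)
        assert all(np.isfinite(fdrs))


class TestSubsampling:
    def test_fraction_one_is_identity(self):
        c = np.arange(12).reshape(3, 4)
        assert np.array_equal(subsample_counts(c, 1.0, seed=0), c)

    def test_binomial_moments(self):
        reps = np.full(1000, 1000)
        thinned = subsample_counts(reps, 0.1, seed=1)
        sd = np.sqrt(1000 * 0.1 * 0.9)
        assert abs(thinned.mean() - 100) < 3 * sd / np.sqrt(1000)

    def test_composition_matches_single_thinning(self):
        base = np.full(4000, 500)
        twice = subsample_counts(subsample_counts(base, 0.5, seed=2), 0.5, seed=3)
        once = subsample_counts(base, 0.25, seed=4)
        assert abs(twice.mean() - once.mean()) < 3 * np.sqrt(2 * 500 * 0.25 / 4000) * 10
        assert abs(twice.var() - once.var()) / once.var() < 0.2

    def test_deterministic_under_seed_and_rescales_libraries(self):
        c = np.arange(100)
        a = subsample_counts(c, 0.3, seed=9)
        b = subsample_counts(c, 0.3, seed=9)
        assert np.array_equal(a, b)
        thinned, libs = subsample_counts(c, 0.5, seed=1, library_sizes={"s": 100.0})
        assert libs == {"s": 50.0}

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            subsample_counts(np.ones(3), 0.0, seed=0)
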