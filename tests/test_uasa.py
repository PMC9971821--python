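"""Priors, Latin hypercube design, rejection filter and Morris screening."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from dphpkin.errors import ConfigurationError, FitFailureError, InvalidInputError
from dphpkin.pbpk import OBSERVABLE_NAMES, STATE_NAMES, TimeCourse
from dphpkin.priors import PriorSpec, fit_prior_from_summary, sample_prior
from dphpkin.uasa import (
    DesignMatrix,
    _lhs_unit,
    build_ua_priors,
    lhs_maximin,
    morris_screen,
    rejection_filter,
)


class TestPriorSpec:
    def test_analytic_medians_match_tabulated_values(self):
        assert PriorSpec("FB_DPHP", "uniform", (0.95, 1.00)).median() == pytest.approx(0.975)
        assert PriorSpec("FB_MPHP", "uniform", (0.90, 1.00)).median() == pytest.approx(0.950)
        assert PriorSpec("sigma", "halfnormal", (1.0,)).median() == pytest.approx(0.674, abs=5e-3)

    def test_sample_median_uniform(self):
        x = sample_prior(PriorSpec("u", "uniform", (0.95, 1.00)), 100_000, seed=1)
        assert np.median(x) == pytest.approx(0.975, abs=1e-3)

    def test_sample_median_halfnormal(self):
        x = sample_prior(PriorSpec("h", "halfnormal", (1.0,)), 100_000, seed=2)
        assert np.median(x) == pytest.approx(0.674, abs=5e-3)

    def test_degenerate_uniform_rejected(self):
        with pytest.raises(ConfigurationError):
            PriorSpec("u", "uniform", (0.5, 0.5))

    def test_truncation_respected_by_samples_and_logpdf(self):
        spec = PriorSpec("n", "normal", (0.0, 1.0)).truncated_at_quantiles(0.05, 0.95)
        x = spec.sample(10_000, np.random.default_rng(3))
        lo, hi = spec.support()
        assert x.min() >= lo and x.max() <= hi
        assert np.isinf(spec.logpdf(hi + 0.1))
        # renormalisation: density integrates to one over the truncated support
        from scipy.integrate import quad

        integral, _ = quad(lambda v: np.exp(spec.logpdf(v)), lo, hi)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_empty_truncation_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            PriorSpec("n", "normal", (0.0, 1.0), lower=5.0, upper=4.0)


class TestFitPriorFromSummary:
    def test_normal_back_fit(self):
        spec = fit_prior_from_summary(0.35, 0.21, 0.49, "normal")
        assert spec.params[0] == pytest.approx(0.35)
        assert spec.params[1] == pytest.approx(0.0714, abs=1e-3)

    def test_uniform_inversion(self):
        spec = fit_prior_from_summary(0.975, 0.95125, 0.99875, "uniform")
        assert spec.params[0] == pytest.approx(0.95, abs=1e-6)
        assert spec.params[1] == pytest.approx(1.00, abs=1e-6)

    def test_halfnormal_back_fit(self):
        spec = fit_prior_from_summary(6.62, 0.322, 22.34, "halfnormal")
        assert spec.median() == pytest.approx(6.62, rel=1e-6)

    def test_zero_truncated_normal_fallback(self):
        # median above the interval midpoint: only explicable by truncation at 0
        spec = fit_prior_from_summary(3.92, 0.58, 7.79, "normal")
        assert spec.lower == 0.0
        assert spec.median() == pytest.approx(3.92, abs=0.15)

    def test_degenerate_interval_fails(self):
        with pytest.raises(FitFailureError):
            fit_prior_from_summary(0.5, 0.5, 0.5, "normal")

    def test_round_trip_quantiles(self):
        spec = fit_prior_from_summary(2.52, 0.15, 4.87, "uniform")
        med, (lo, hi) = spec.median(), spec.interval95()
        width = 4.87 - 0.15
        assert abs(med - 2.52) / width < 0.01
        assert abs(lo - 0.15) / width < 0.01
        assert abs(hi - 4.87) / width < 0.01


class TestLHSMaximin:
    def test_stratification_is_exact(self):
        priors = [PriorSpec("a", "uniform", (0.0, 1.0)), PriorSpec("b", "normal", (0.0, 1.0))]
        design = lhs_maximin(priors, n=16, seed=0, n_candidates=5)
        for j in range(2):
            strata = np.floor(design.unit[:, j] * 16).astype(int)
            assert sorted(strata) == list(range(16))

    def test_four_point_quartile_occupancy(self):
        design = lhs_maximin([PriorSpec("u", "uniform", (0.0, 1.0))], n=4, seed=1)
        strata = np.floor(np.sort(design.df["u"].to_numpy()) * 4).astype(int)
        assert list(strata) == [0, 1, 2, 3]

    def test_maximin_at_least_first_candidate(self):
        priors = [PriorSpec(f"p{i}", "uniform", (0.0, 1.0)) for i in range(3)]
        rng = np.random.default_rng(7)
        first = pdist(_lhs_unit(20, 3, rng)).min()
        design = lhs_maximin(priors, n=20, seed=7, n_candidates=30)
        assert pdist(design.unit).min() >= first

    def test_column_means_match_priors(self):
        priors = build_ua_priors()
        design = lhs_maximin(priors, n=500, seed=3, n_candidates=10)
        rng = np.random.default_rng(10)
        for spec in priors:
            ref = spec.sample(20_000, rng)
            se = ref.std() / np.sqrt(500)
            assert abs(design.df[spec.name].mean() - ref.mean()) < 3 * se + 1e-12

    def test_needs_two_points(self):
        with pytest.raises(InvalidInputError):
            lhs_maximin([PriorSpec("u", "uniform", (0.0, 1.0))], n=1, seed=0)


def _fake_timecourse(curve, t=None):
    t = t if t is not None else np.linspace(0.0, 48.0, len(curve))
    states = np.zeros((len(t), len(STATE_NAMES)))
    obs = np.zeros((len(t), len(OBSERVABLE_NAMES)))
    obs[:, OBSERVABLE_NAMES.index("CBlood_MPHP")] = curve
    return TimeCourse(t=t, states=states, observables=obs)


class TestRejectionFilter:
    def test_flat_zero_rejected(self):
        tc = _fake_timecourse(np.zeros(97))
        assert rejection_filter(None, [tc]).size == 0

    def test_mid_band_retained(self):
        curve = 0.1 * np.exp(-0.2 * np.linspace(0.0, 48.0, 97))
        assert list(rejection_filter(None, [_fake_timecourse(curve)])) == [0]

    def test_high_tail_rejected(self):
        curve = np.full(97, 0.03)
        curve[:10] = 0.1
        assert rejection_filter(None, [_fake_timecourse(curve)]).size == 0

    def test_short_horizon_rejected(self):
        tc = _fake_timecourse(np.zeros(10), t=np.linspace(0.0, 40.0, 10))
        with pytest.raises(InvalidInputError):
            rejection_filter(None, [tc])

    def test_pure_predicate_under_permutation(self, rng):
        curves = [rng.uniform(0.0, 0.4) * np.exp(-rng.uniform(0.05, 0.3) *
                                                 np.linspace(0.0, 48.0, 97))
                  for _ in range(12)]
        sims = [_fake_timecourse(c) for c in curves]
        kept = set(rejection_filter(None, sims))
        perm = rng.permutation(12)
        kept_perm = rejection_filter(None, [sims[i] for i in perm])
        assert {int(perm[i]) for i in kept_perm} == kept


class TestMorris:
    @staticmethod
    def _unit_priors(k):
        return [PriorSpec(f"x{i}", "uniform", (0.0, 1.0)) for i in range(k)]

    def test_run_count_is_r_times_k_plus_one(self):
        calls = []

        def model(v):
            calls.append(v)
            return {"y": 0.0}

        res = morris_screen(self._unit_priors(4), model, r=2, seed=0)
        assert res.n_runs == 2 * (4 + 1)
        assert len(calls) == 10

    def test_additive_linear_function(self):
        slopes = np.array([3.0, -1.5, 0.5])
        priors = self._unit_priors(3)

        def model(v):
            x = np.array([v["x0"], v["x1"], v["x2"]])
            return {"y": float(slopes @ x)}

        res = morris_screen(priors, model, r=4, seed=1)
        table = res.tables["y"]
        np.testing.assert_allclose(table["mu_star"], np.abs(slopes), rtol=1e-9)
        np.testing.assert_allclose(table["sigma"], 0.0, atol=1e-9)

    def test_ignored_parameter_has_zero_mu_star(self):
        priors = self._unit_priors(2)
        res = morris_screen(priors, lambda v: {"y": v["x0"] ** 2}, r=3, seed=2)
        assert res.tables["y"].loc["x1", "mu_star"] == 0.0
        assert res.tables["y"].loc["x0", "mu_star"] > 0.0

    def test_mu_star_scales_with_output(self):
        priors = self._unit_priors(2)

        def model_scale(c):
            return lambda v: {"y": c * (v["x0"] + 2.0 * v["x1"] ** 2)}

        a = morris_screen(priors, model_scale(1.0), r=4, seed=3).tables["y"]
        b = morris_screen(priors, model_scale(10.0), r=4, seed=3).tables["y"]
        np.testing.assert_allclose(b["mu_star"], 10.0 * a["mu_star"], rtol=1e-9)

    def test_nonfinite_output_excluded_with_warning(self):
        priors = self._unit_priors(2)

        def model(v):
            return {"y": np.nan if v["x0"] > 0.5 else v["x0"]}

        with pytest.warns(UserWarning):
            res = morris_screen(priors, model, r=3, seed=4)
        assert res.n_excluded > 0


class TestUAPriorSet:
    def test_count_and_uniqueness(self):
        priors = build_ua_priors()
        names = [s.name for s in priors]
        assert len(names) == len(set(names))
        assert len(names) == 54

    def test_fraction_parameters_clipped_to_unit_interval(self):
        priors = {s.name: s for s in build_ua_priors()}
        for name in ("Escape_gu", "Escape_Li", "FracDOSEHep", "FracDoseLymph"):
            lo, hi = priors[name].support()
            assert lo >= 0.0 and hi <= 1.0
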