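"""Error model, priors, sampler and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from dphpkin.calibration import (
    GLOBAL_PARAM_NAMES,
    LOCAL_PARAM_NAMES,
    SD_NAMES,
    PosteriorSample,
    adaptive_metropolis,
    build_calibration_priors,
    credible_bands,
    log_likelihood,
    log_prior,
    mcmc,
    summarize,
    ti_evidence,
    truncnorm_logpdf,
)
from dphpkin.config import ERROR_SD_POSTERIOR_MEDIANS
from dphpkin.errors import (
    ConfigurationError,
    InvalidInputError,
    NumericalFailureError,
)
from dphpkin.study import VolunteerDataset

LN2PI = np.log(2.0 * np.pi)


class TestTruncatedNormalDensity:
    def test_matches_numerically_renormalised_density(self, rng):
        for _ in range(10):
            mu = rng.uniform(-1.0, 3.0)
            sigma = rng.uniform(0.2, 2.0)
            z, _ = quad(lambda v: stats.norm.pdf(v, mu, sigma), 0.0, np.inf)
            for y in rng.uniform(0.0, 4.0, size=5):
                expected = stats.norm.logpdf(y, mu, sigma) - np.log(z)
                assert truncnorm_logpdf(y, mu, sigma) == pytest.approx(expected, abs=1e-8)

    def test_untruncated_limit_at_large_mean(self):
        # y = mu with mu >> sigma: the truncation factor vanishes
        val = truncnorm_logpdf(5.0, 5.0, 0.1)
        assert val == pytest.approx(-np.log(0.1) - 0.5 * LN2PI, abs=1e-10)

    def test_zero_mean_halves_support(self):
        y, sigma = 0.7, 0.5
        expected = np.log(2.0) + stats.norm.logpdf(y, 0.0, sigma)
        assert truncnorm_logpdf(y, 0.0, sigma) == pytest.approx(expected, abs=1e-12)

    def test_negative_observation_impossible(self):
        assert np.isinf(truncnorm_logpdf(-0.1, 1.0, 1.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidInputError):
            truncnorm_logpdf(1.0, 1.0, 0.0)


class TestLogLikelihood:
    def test_empty_dataset_contributes_zero(self):
        ds = VolunteerDataset(id="Z", BW=80.0, dose_mg_per_kg=0.7)
        total = log_likelihood({}, [{}], ERROR_SD_POSTERIOR_MEDIANS, [ds])
        assert total == 0.0

    def test_invariant_to_volunteer_ordering(self, study_data):
        sds = ERROR_SD_POSTERIOR_MEDIANS
        a = log_likelihood({}, [{}] * 4, sds, study_data)
        b = log_likelihood({}, [{}] * 4, sds, study_data[::-1])
        assert a == pytest.approx(b, rel=1e-12)

    def test_bad_sigma_rejected(self, study_data):
        sds = dict(ERROR_SD_POSTERIOR_MEDIANS, sigma_OH_U=0.0)
        with pytest.raises(InvalidInputError):
            log_likelihood({}, [{}] * 4, sds, study_data)


class TestLogPrior:
    def test_uniform_density_value(self):
        priors = build_calibration_priors()
        lp = log_prior({"FB_DPHP": 0.975}, [], {}, priors)
        assert lp == pytest.approx(np.log(20.0), abs=1e-10)

    def test_outside_support_is_minus_inf(self):
        priors = build_calibration_priors()
        assert np.isinf(log_prior({"FB_DPHP": 0.90}, [], {}, priors))

    def test_halfnormal_boundary_density(self):
        priors = build_calibration_priors()
        lp = log_prior({}, [], {"sigma_DPHP_B": 0.0}, priors)
        assert np.exp(lp) == pytest.approx(np.sqrt(2.0 / np.pi), abs=1e-10)

    def test_unknown_parameter_is_configuration_error(self):
        priors = build_calibration_priors()
        with pytest.raises(ConfigurationError):
            log_prior({"no_such": 1.0}, [], {}, priors)


def _toy_problem(seed=0, n=10, s0=2.0, sigma=1.0):
    rng = np.random.default_rng(seed)
    y = rng.normal(1.2, sigma, size=n)

    def logprior(v):
        return -0.5 * (v / s0) ** 2 - np.log(s0) - 0.5 * LN2PI

    def loglik(x, changed, cache):
        r = y - x[0]
        return float(-0.5 * r @ r / sigma**2 - n * np.log(sigma) - 0.5 * n * LN2PI), None

    post_var = 1.0 / (1.0 / s0**2 + n / sigma**2)
    post_mean = post_var * y.sum() / sigma**2
    f = lambda th: np.exp(loglik([th], None, None)[0] + logprior(th))  # noqa: E731
    log_z = np.log(quad(f, -10.0, 10.0)[0])
    return logprior, loglik, post_mean, np.sqrt(post_var), log_z


class TestAdaptiveMetropolis:
    def test_conjugate_posterior_recovered(self):
        logprior, loglik, post_mean, post_sd, _ = _toy_problem()
        s = adaptive_metropolis([logprior], loglik, np.array([0.0]),
                                n_iter=20000, thin=5, seed=1, names=["theta"])
        m = s.draws[:, 0]
        batches = m[: len(m) // 20 * 20].reshape(20, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(20)
        assert abs(m.mean() - post_mean) < 3.0 * se
        assert m.std() == pytest.approx(post_sd, rel=0.1)

    def test_fixed_seed_bit_identical(self):
        logprior, loglik, *_ = _toy_problem()
        kw = dict(n_iter=2000, thin=5, seed=9, names=["theta"])
        a = adaptive_metropolis([logprior], loglik, np.array([0.0]), **kw)
        b = adaptive_metropolis([logprior], loglik, np.array([0.0]), **kw)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_posterior, b.log_posterior)

    def test_all_rejected_chain_raises_diagnostic(self):
        def loglik(x, changed, cache):
            return (0.0 if x[0] == 0.0 else -np.inf), None

        with pytest.raises(NumericalFailureError):
            adaptive_metropolis([lambda v: 0.0], loglik, np.array([0.0]),
                                n_iter=500, thin=5, seed=0, names=["x"])

    def test_infinite_prior_start_rejected(self):
        logprior, loglik, *_ = _toy_problem()
        with pytest.raises(InvalidInputError):
            adaptive_metropolis([lambda v: -np.inf], loglik, np.array([0.0]),
                                n_iter=100, thin=1, seed=0)


class TestThermodynamicIntegration:
    @staticmethod
    def _toy_mcmc():
        logprior, loglik, *_ , = _toy_problem()

        def runner(data, priors=None, n_iter=5000, thin=10, seed=0, temperature=1.0):
            return adaptive_metropolis([logprior], loglik, np.array([0.0]),
                                       n_iter=n_iter, thin=thin, seed=seed,
                                       temperature=temperature, names=["theta"])

        return runner

    def test_evidence_within_tenth_of_a_nat(self):
        *_, log_z = _toy_problem()
        ladder = (np.arange(21) / 20.0) ** 5
        res = ti_evidence(None, ladder=ladder, n_iter=8000, thin=10, seed=3,
                          mcmc_fn=self._toy_mcmc())
        assert res["log_evidence"] == pytest.approx(log_z, abs=0.1)

    def test_ladder_refinement_approaches_oracle(self):
        *_, log_z = _toy_problem()
        runner = self._toy_mcmc()
        errs = []
        for rungs in (5, 21):
            ladder = (np.arange(rungs) / (rungs - 1)) ** 5
            res = ti_evidence(None, ladder=ladder, n_iter=8000, thin=10, seed=3,
                              mcmc_fn=runner)
            errs.append(abs(res["log_evidence"] - log_z))
        assert errs[1] < errs[0]

    def test_single_rung_ladder_rejected(self):
        with pytest.raises(InvalidInputError):
            ti_evidence(None, ladder=np.array([1.0]), mcmc_fn=self._toy_mcmc())


class TestPBPKChain:
    def test_prior_reproduced_at_temperature_zero(self, study_data):
        """A tempered chain at t = 0 must sample the joint prior."""
        priors = build_calibration_priors()
        sample = mcmc(study_data[:1], priors, n_iter=12000, thin=10, seed=21,
                      temperature=0.0)
        specs = dict(priors.globals_)
        specs.update({f"{k}[A]": v for k, v in priors.locals_template.items()})
        specs.update(priors.sds)
        n_checked = 0
        for name, spec in specs.items():
            draws = sample.column(name)
            ind = (draws <= spec.median()).astype(float)
            batches = ind[: ind.size // 20 * 20].reshape(20, -1).mean(axis=1)
            se = batches.std(ddof=1) / np.sqrt(20)
            assert abs(ind.mean() - 0.5) < 3.0 * se + 0.02, name
            n_checked += 1
        assert n_checked == len(GLOBAL_PARAM_NAMES) + len(LOCAL_PARAM_NAMES) + len(SD_NAMES)

    def test_chain_layout_and_determinism(self, study_data):
        kw = dict(n_iter=300, thin=10, seed=4)
        a = mcmc(study_data[:1], n_iter=300, thin=10, seed=4)
        b = mcmc(study_data[:1], **kw)
        assert np.array_equal(a.draws, b.draws)
        assert a.n_draws == 30
        assert a.names[: len(GLOBAL_PARAM_NAMES)] == list(GLOBAL_PARAM_NAMES)
        assert a.names[-len(SD_NAMES):] == list(SD_NAMES)
        assert np.all(np.isfinite(a.log_posterior))


class TestSummaries:
    def test_percentiles_of_integer_ramp(self):
        draws = np.arange(1.0, 1001.0)[:, None]
        sample = PosteriorSample(names=["p"], draws=draws,
                                 log_posterior=np.zeros(1000),
                                 log_likelihood=np.zeros(1000),
                                 iterations=1000, thin=1, seed=0, temperature=1.0)
        table = summarize(sample)
        assert table.loc["p", "median"] == pytest.approx(500.5)
        assert table.loc["p", "lo2.5"] == pytest.approx(25.975)
        assert table.loc["p", "hi97.5"] == pytest.approx(975.025)

    def test_constant_chain_collapses(self):
        draws = np.full((200, 1), 3.3)
        sample = PosteriorSample(names=["p"], draws=draws,
                                 log_posterior=np.zeros(200),
                                 log_likelihood=np.zeros(200),
                                 iterations=200, thin=1, seed=0, temperature=1.0)
        table = summarize(sample)
        assert table.loc["p", "median"] == table.loc["p", "lo2.5"] == table.loc["p", "hi97.5"] == 3.3

    def test_mode_has_maximal_log_posterior(self, short_chain):
        i = int(np.argmax(short_chain.log_posterior))
        mode = short_chain.mode()
        for k, name in enumerate(short_chain.names):
            assert mode[name] == short_chain.draws[i, k]

    def test_too_few_draws_rejected(self):
        sample = PosteriorSample(names=["p"], draws=np.zeros((5, 1)),
                                 log_posterior=np.zeros(5), log_likelihood=np.zeros(5),
                                 iterations=5, thin=1, seed=0, temperature=1.0)
        with pytest.raises(InvalidInputError):
            summarize(sample)


class TestCredibleBands:
    def test_single_draw_bands_collapse_onto_central(self, short_chain, study_data):
        one = PosteriorSample(names=short_chain.names, draws=short_chain.draws[:1],
                              log_posterior=short_chain.log_posterior[:1],
                              log_likelihood=short_chain.log_likelihood[:1],
                              iterations=1, thin=1, seed=0, temperature=1.0)
        grid = np.arange(0.0, 48.1, 1.0)
        bands = credible_bands(one, study_data[0], grid=grid)
        for table in bands.values():
            np.testing.assert_allclose(table["lower"], table["central"], rtol=1e-9)
            np.testing.assert_allclose(table["upper"], table["central"], rtol=1e-9)

    def test_bands_are_pointwise_ordered(self, short_chain, study_data):
        grid = np.arange(0.0, 48.1, 1.0)
        bands = credible_bands(short_chain, study_data[1], grid=grid, draw_stride=30)
        for table in bands.values():
            assert (table["lower"] <= table["upper"] + 1e-12).all()
            assert (table["lower"] >= -1e-12).all()


class TestBandCalibration:
    def test_converged_bands_cover_noiseless_truth(self):
        """On a well-identified synthetic calibration (five free parameters,
        the rest fixed at the data-generating values) the pointwise 95%
        bands contain at least 90% of the noiseless true-curve points."""
        from dphpkin import DoseEvent, simulate
        from dphpkin.calibration import (
            GLOBAL_PARAM_NAMES as GN,
            LOCAL_PARAM_NAMES as LN,
            PBPKLikelihood,
        )
        from dphpkin.config import (
            ERROR_SD_POSTERIOR_MEDIANS,
            GLOBAL_POSTERIOR_MEDIANS,
            LOCAL_POSTERIOR_MEDIANS,
        )
        from dphpkin.study import generate_study, true_parameters_for

        data = generate_study(seed=100, volunteer_ids=("A",))
        lik = PBPKLikelihood(data)
        priors = build_calibration_priors()
        free = ["Escape_gu", "Escape_Li", "FB_DPHP", "K1_MPHP", "FracDOSEHep"]
        specs = [priors.globals_.get(n) or priors.locals_template[n] for n in free]
        specs += [priors.sds[n] for n in SD_NAMES]
        truth = {**GLOBAL_POSTERIOR_MEDIANS, **LOCAL_POSTERIOR_MEDIANS["A"]}

        def loglik(x, changed, cache):
            overrides = dict(truth)
            overrides.update(zip(free, x[:5]))
            sds = dict(zip(SD_NAMES, x[5:]))
            pred = cache if (cache is not None and changed is not None and changed >= 5) \
                else lik.predict(0, overrides)
            return lik.loglik_volunteer(0, pred, sds), pred

        x0 = np.array([truth[n] for n in free]
                      + [ERROR_SD_POSTERIOR_MEDIANS[k] for k in SD_NAMES])
        sample = adaptive_metropolis([s.logpdf for s in specs], loglik, x0,
                                     n_iter=20_000, thin=10, seed=3,
                                     target_accept=0.4, names=free + list(SD_NAMES))

        names_full = list(GN) + [f"{n}[A]" for n in LN] + list(SD_NAMES)
        draws = np.empty((sample.n_draws, len(names_full)))
        for j, name in enumerate(names_full):
            base = name.split("[")[0]
            if base in free:
                draws[:, j] = sample.draws[:, free.index(base)]
            elif name in SD_NAMES:
                draws[:, j] = sample.draws[:, 5 + list(SD_NAMES).index(name)]
            else:
                draws[:, j] = truth[base]
        full = PosteriorSample(names=names_full, draws=draws,
                               log_posterior=sample.log_posterior,
                               log_likelihood=sample.log_likelihood,
                               iterations=sample.iterations, thin=sample.thin,
                               seed=3, temperature=1.0)
        grid = np.arange(0.0, 48.01, 0.5)
        bands = credible_bands(full, data[0], grid=grid, draw_stride=20)
        truth_tc = simulate(true_parameters_for("A"),
                            DoseEvent(0.0, data[0].dose_mg), grid)
        inside = n_pts = 0
        for name, table in bands.items():
            curve = truth_tc.obs(name)
            inside += int(((table["lower"] - 1e-12 <= curve)
                           & (curve <= table["upper"] + 1e-12)).sum())
            n_pts += len(curve)
        assert inside / n_pts >= 0.90, f"band coverage {inside}/{n_pts}"


class TestChainExport:
    def test_csv_round_trip(self, short_chain, tmp_path):
        path = tmp_path / "chain.csv"
        short_chain.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[:len(short_chain.names)]) == short_chain.names
        np.testing.assert_allclose(df["log_posterior"], short_chain.log_posterior, rtol=1e-9)
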