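"""Likelihood, priors, MCMC sampler, convergence diagnostics, predictive bands."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mixkin import (
    ConfigurationError,
    DomainError,
    ExposureScenario,
    KineticDataset,
    MCMCSettings,
    PosteriorSample,
    PriorSpec,
    SolverSettings,
    gelman_rubin,
    gsd_from_moments,
    log_likelihood,
    posterior_predictive,
    run_mcmc,
    simulate,
    summarize,
)


class TestGsdFromMoments:
    def test_reference_point(self):
        """Mean 1.0 with arithmetic SD 0.25 gives GSD ~1.28."""
        assert gsd_from_moments(1.0, 0.25) == pytest.approx(1.28, abs=0.005)

    def test_zero_sd_gives_gsd_one(self):
        assert gsd_from_moments(3.0, 0.0) == 1.0

    def test_scale_invariance(self):
        assert gsd_from_moments(1.0, 0.25) == pytest.approx(gsd_from_moments(4.0, 1.0))

    def test_domain(self):
        with pytest.raises(DomainError):
            gsd_from_moments(0.0, 0.1)
        with pytest.raises(DomainError):
            gsd_from_moments(1.0, -0.1)


class TestPriorSpec:
    def test_lognormal_density_matches_scipy(self):
        prior = PriorSpec("x", "lognormal", 62.5, 1.1)
        dist = stats.lognorm(s=math.log(1.1), scale=62.5)
        for x in (40.0, 62.5, 80.0, 100.0):
            assert prior.log_density(x) == pytest.approx(dist.logpdf(x), rel=1e-10)

    def test_uniform_density_and_support(self):
        prior = PriorSpec("x", "uniform", 2.0, 50.0)
        assert prior.log_density(10.0) == pytest.approx(-math.log(48.0))
        assert prior.log_density(1.0) == -np.inf
        assert prior.log_density(51.0) == -np.inf

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            PriorSpec("x", "lognormal", 10.0, 0.9)
        with pytest.raises(ConfigurationError):
            PriorSpec("x", "uniform", 5.0, 2.0)
        with pytest.raises(ConfigurationError):
            PriorSpec("x", "cauchy", 0.0, 1.0)


@pytest.fixture(scope="module")
def benzene_dataset(benzene_model):
    """A small fabricated dataset lying close to the model prediction."""
    scen = ExposureScenario.constant({"benzene": 100.0})
    times = [264.0, 288.0, 312.0, 336.0, 360.0]
    res = simulate(benzene_model, scen, grid=[0.0, *times])
    cven = res.venous("benzene")
    obs = pd.DataFrame({
        "time_min": times,
        "conc_mean": [float(cven[np.argmin(np.abs(res.times - t))]) * f
                      for t, f in zip(times, (1.1, 0.95, 1.0, 1.05, 0.9))],
        "conc_sd": [0.25, 0.2, 0.3, 0.25, 0.2],
        "n": [5] * 5,
    })
    return KineticDataset("benzene", scen, obs)


class TestLogLikelihood:
    def test_matches_brute_force_scipy_evaluation(self, benzene_model, benzene_dataset):
        """Engine likelihood equals an independent scipy.stats.lognorm sum."""
        ll = log_likelihood({}, [benzene_dataset], benzene_model,
                            SolverSettings(rtol=1e-8, atol=1e-11))
        res = simulate(benzene_model, benzene_dataset.scenario,
                       SolverSettings(rtol=1e-8, atol=1e-11),
                       grid=benzene_dataset.observations.time_min.tolist())
        cven = res.venous("benzene")
        expected = 0.0
        for _, row in benzene_dataset.observations.iterrows():
            pred = float(cven[np.argmin(np.abs(res.times - row.time_min))])
            sigma = math.log(gsd_from_moments(row.conc_mean, row.conc_sd))
            expected += stats.lognorm(s=sigma, scale=pred).logpdf(row.conc_mean)
        assert ll == pytest.approx(expected, rel=1e-8)

    def test_perfect_fit_maximizes_each_point(self, benzene_model, benzene_dataset):
        """Data placed exactly at the prediction scores the density maximum."""
        res = simulate(benzene_model, benzene_dataset.scenario,
                       grid=benzene_dataset.observations.time_min.tolist())
        cven = res.venous("benzene")
        exact = benzene_dataset.observations.copy()
        exact["conc_mean"] = [float(cven[np.argmin(np.abs(res.times - t))])
                              for t in exact.time_min]
        ds_exact = KineticDataset("benzene", benzene_dataset.scenario, exact)
        ll_exact = log_likelihood({}, [ds_exact], benzene_model)
        # any multiplicative distortion of the data lowers the likelihood
        for f in (0.8, 1.3):
            distorted = exact.copy()
            distorted["conc_mean"] *= f
            ds = KineticDataset("benzene", benzene_dataset.scenario, distorted)
            assert log_likelihood({}, [ds], benzene_model) < ll_exact

    def test_flatter_penalty_with_larger_sd(self, benzene_model, benzene_dataset):
        """Doubling the SDs raises the likelihood of poorly fitting points."""
        bad = benzene_dataset.observations.copy()
        bad["conc_mean"] *= 3.0  # badly fitting data
        ds_tight = KineticDataset("benzene", benzene_dataset.scenario, bad)
        loose = bad.copy()
        loose["conc_sd"] *= 2.0
        ds_loose = KineticDataset("benzene", benzene_dataset.scenario, loose)
        assert (log_likelihood({}, [ds_loose], benzene_model)
                > log_likelihood({}, [ds_tight], benzene_model))

    def test_zero_prediction_rejects_draw(self, benzene_model):
        scen = ExposureScenario.constant({"benzene": 100.0})
        obs = pd.DataFrame({"time_min": [0.0], "conc_mean": [1.0],
                            "conc_sd": [0.2], "n": [5]})
        ds = KineticDataset("benzene", scen, obs)
        assert log_likelihood({}, [ds], benzene_model) == -np.inf

    def test_dataset_validation(self):
        scen = ExposureScenario.constant({"benzene": 100.0})
        with pytest.raises(ConfigurationError):
            KineticDataset("benzene", scen, pd.DataFrame({
                "time_min": [100.0], "conc_mean": [-1.0]}))
        with pytest.raises(ConfigurationError):
            KineticDataset("benzene", scen, pd.DataFrame({
                "time_min": [1000.0], "conc_mean": [1.0]}))


@pytest.fixture(scope="module")
def prior_only(benzene_model):
    priors = [PriorSpec("k3:benzene", "uniform", 2.0, 50.0),
              PriorSpec("blood_air:benzene", "lognormal", 15.0, 1.1)]
    return run_mcmc(benzene_model, priors, [],
                    MCMCSettings(n_chains=5, n_iter=4000, seed=11))


class TestPriorOnlySampling:
    """With no data the sampler must reproduce the prior itself."""

    def test_uniform_prior_recovered(self, prior_only):
        j = prior_only.parameters.index("k3:benzene")
        draws = prior_only.flat[:, j]
        assert draws.mean() == pytest.approx(26.0, abs=1.5)
        assert np.percentile(draws, 50) == pytest.approx(26.0, abs=2.0)
        assert draws.min() >= 2.0 and draws.max() <= 50.0

    def test_lognormal_prior_recovered(self, prior_only):
        j = prior_only.parameters.index("blood_air:benzene")
        draws = prior_only.flat[:, j]
        assert np.median(draws) == pytest.approx(15.0, rel=0.03)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(15.0 * 1.1 ** -1.96, rel=0.05)
        assert hi == pytest.approx(15.0 * 1.1 ** 1.96, rel=0.05)

    def test_chains_mix(self, prior_only):
        assert all(r < 1.1 for r in prior_only.rhat().values())

    def test_fixed_seed_bit_identical(self, benzene_model, prior_only):
        priors = [PriorSpec("k3:benzene", "uniform", 2.0, 50.0),
                  PriorSpec("blood_air:benzene", "lognormal", 15.0, 1.1)]
        again = run_mcmc(benzene_model, priors, [],
                         MCMCSettings(n_chains=5, n_iter=4000, seed=11))
        np.testing.assert_array_equal(again.chains, prior_only.chains)


class TestGelmanRubin:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 10_000))
        assert gelman_rubin(chains) < 1.05

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(4)
        chains = rng.standard_normal((2, 500)) + np.array([[0.0], [50.0]])
        assert gelman_rubin(chains) > 1.5

    def test_constant_chains_degenerate(self):
        assert math.isnan(gelman_rubin(np.ones((3, 100))))

    def test_agrees_with_arviz_on_stationary_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        chains = rng.standard_normal((4, 5_000))
        ours = gelman_rubin(chains)
        theirs = float(np.asarray(az.rhat(chains)))
        assert ours == pytest.approx(1.0, abs=0.01)
        assert theirs == pytest.approx(1.0, abs=0.01)
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_shape_validation(self):
        with pytest.raises(ConfigurationError):
            gelman_rubin(np.ones((1, 100)))


def _fake_posterior(draws: np.ndarray, names, seed=0) -> PosteriorSample:
    """Wrap raw draws (n_chains, n_iter, n_params) as a PosteriorSample."""
    n_chains, n_iter, _ = draws.shape
    logp = -0.5 * (draws ** 2).sum(axis=2)
    return PosteriorSample(parameters=list(names), chains=draws,
                           log_posterior=logp,
                           acceptance=np.full((n_chains, len(names)), 0.4),
                           seed=seed, n_burn=0)


class TestSummarize:
    def test_standard_normal_sample(self):
        rng = np.random.default_rng(7)
        draws = rng.standard_normal((4, 20_000, 1))
        table = summarize(_fake_posterior(draws, ["z"]))
        row = table.iloc[0]
        assert row["mean"] == pytest.approx(0.0, abs=0.02)
        assert row["sd"] == pytest.approx(1.0, abs=0.02)
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.05)
        assert row["q2.5"] < row["q97.5"]

    def test_mode_is_maximum_posterior_draw(self):
        draws = np.zeros((2, 5, 1))
        draws[1, 3, 0] = 0.0
        draws[0, 2, 0] = 4.0  # far draw, low log-posterior
        post = _fake_posterior(draws, ["z"])
        assert post.mode()["z"] == 0.0  # argmax of -z^2/2 is at 0


@pytest.fixture(scope="module")
def degenerate_posterior():
    """All draws identical: bands isolate the noise model."""
    draws = np.full((2, 50, 1), 7.8)
    return _fake_posterior(draws, ["k3:benzene"])


class TestPosteriorPredictive:
    def test_noise_free_bands_collapse(self, benzene_model, degenerate_posterior):
        scen = ExposureScenario.constant({"benzene": 100.0})
        bands = posterior_predictive(benzene_model, degenerate_posterior, scen,
                                     noise_gsd=1.0, n_draws=20, seed=0,
                                     grid=[0.0, 240.0, 300.0])["benzene"]
        np.testing.assert_allclose(bands["q2.5"], bands["q97.5"])
        res = simulate(benzene_model, scen, grid=[0.0, 240.0, 300.0])
        np.testing.assert_allclose(bands["q50"], res.venous("benzene"), rtol=1e-9)

    def test_median_band_insensitive_to_noise(self, benzene_model, degenerate_posterior):
        scen = ExposureScenario.constant({"benzene": 100.0})
        kw = dict(n_draws=400, seed=3, grid=[0.0, 240.0, 300.0])
        noisy = posterior_predictive(benzene_model, degenerate_posterior, scen,
                                     noise_gsd=1.28, **kw)["benzene"]
        clean = posterior_predictive(benzene_model, degenerate_posterior, scen,
                                     noise_gsd=1.0, **kw)["benzene"]
        ratio = noisy["q50"].to_numpy()[1:] / clean["q50"].to_numpy()[1:]
        np.testing.assert_allclose(ratio, 1.0, atol=0.06)

    def test_bad_gsd_rejected(self, benzene_model, degenerate_posterior):
        scen = ExposureScenario.constant({"benzene": 100.0})
        with pytest.raises(DomainError):
            posterior_predictive(benzene_model, degenerate_posterior, scen,
                                 noise_gsd=0.9)
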