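import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, uniform

from trophicniche import isotopes, synthetic
from trophicniche.isotopes import (
    FitConfig,
    ModelPriors,
    fit_hierarchical_model,
    interindividual_scales,
    posterior_predict_individuals,
    sample_prior_covariance,
)


class TestConfigValidation:
    def test_warmup_must_be_smaller(self):
        with pytest.raises(ValueError):
            FitConfig(iterations=100, warmup=100)

    def test_needs_two_chains(self):
        with pytest.raises(ValueError):
            FitConfig(chains=1)

    def test_priors_positive(self):
        with pytest.raises(ValueError):
            ModelPriors(hyper_shape=-1.0)

    def test_single_individual_rejected(self):
        df = pd.DataFrame(
            {
                "individual": ["a"] * 3,
                "species": ["x"] * 3,
                "segment_mm": [10.0, 20.0, 30.0],
                "d13C": [-15.0, -15.1, -14.9],
                "d15N": [16.0, 16.1, 15.9],
            }
        )
        with pytest.raises(ValueError, match="single individual"):
            fit_hierarchical_model(df, config=FitConfig(iterations=20, warmup=10))

    def test_too_few_segments_rejected(self):
        df = pd.DataFrame(
            {
                "individual": ["a", "a", "b", "b", "b"],
                "species": ["x"] * 5,
                "segment_mm": [10.0, 20.0, 10.0, 20.0, 30.0],
                "d13C": [-15.0] * 5,
                "d15N": [16.0] * 5,
            }
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_hierarchical_model(df)


class TestPriorPredictive:
    def test_marginal_correlation_uniform(self):
        """Induced prior correlation between tracers is uniform on (-1, 1)."""
        covs = sample_prior_covariance(2000, seed=0)
        rho = covs[:, 0, 1] / np.sqrt(covs[:, 0, 0] * covs[:, 1, 1])
        stat = kstest(rho, uniform(loc=-1, scale=2).cdf)
        assert stat.pvalue > 0.01

    def test_draws_are_spd(self):
        covs = sample_prior_covariance(200, seed=1)
        eig = np.linalg.eigvalsh(covs)
        assert (eig > 0).all()


class TestFit:
    def test_converged(self, whisker_fit):
        assert whisker_fit.converged
        assert whisker_fit.max_rhat < 1.05

    def test_mu_recovery_within_3sd(self, whisker_fit, isotope_truth):
        for sp, truth in isotope_truth.items():
            post = whisker_fit[sp]
            mean = post.mu_flat.mean(axis=0)
            sd = post.mu_flat.std(axis=0)
            assert (np.abs(mean - truth.mu) < 3 * sd).all()

    def test_covariance_draws_spd(self, whisker_fit):
        for post in whisker_fit.species.values():
            for arr in (post.omega_flat, post.sigma_flat):
                assert (np.linalg.eigvalsh(arr) > 0).all()

    def test_retained_draw_count(self, whisker_fit, fast_fit_config):
        expected = fast_fit_config.chains * (
            fast_fit_config.iterations - fast_fit_config.warmup
        )
        for post in whisker_fit.species.values():
            assert post.n_draws == expected >= 1000

    def test_determinism(self, whisker_series, fast_fit_config):
        import warnings as _warnings

        cfg = FitConfig(chains=2, iterations=60, warmup=30, seed=99)
        with _warnings.catch_warnings():
            # deliberately short chains: convergence warnings expected
            _warnings.simplefilter("ignore", UserWarning)
            a = fit_hierarchical_model(whisker_series, config=cfg)
            b = fit_hierarchical_model(whisker_series, config=cfg)
        for sp in a.species:
            np.testing.assert_array_equal(a[sp].mu, b[sp].mu)
            np.testing.assert_array_equal(a[sp].omega, b[sp].omega)

    def test_species_relabel_symmetry(self, fast_fit_config):
        """Duplicating the dataset under another species name gives
        posteriors agreeing within Monte-Carlo error."""
        truth = {
            "only": synthetic.SpeciesIsotopeTruth(
                mu=[-15.0, 17.0],
                omega=[[0.3, 0.0], [0.0, 0.3]],
                sigma=[[0.1, 0.0], [0.0, 0.1]],
                n_individuals=8,
            )
        }
        series = synthetic.simulate_whiskers(
            synthetic.IsotopeSimConfig(species=truth, segments_range=(8, 8), seed=2)
        )
        series.attrs = {}
        twin = series.copy()
        twin["species"] = "twin"
        both = pd.concat([series, twin], ignore_index=True)
        fit = fit_hierarchical_model(both, config=fast_fit_config)
        mu_a = fit["only"].mu_flat.mean(axis=0)
        mu_b = fit["twin"].mu_flat.mean(axis=0)
        mc_err = fit["only"].mu_flat.std(axis=0) / 10
        assert (np.abs(mu_a - mu_b) < 5 * mc_err).all()

    def test_between_exceeds_residual_when_planted(self, fast_fit_config):
        truth = {
            "sp": synthetic.SpeciesIsotopeTruth(
                mu=[-15.0, 17.0],
                omega=[[2.0, 0.0], [0.0, 2.0]],  # between >> residual
                sigma=[[0.05, 0.0], [0.0, 0.05]],
                n_individuals=12,
            ),
            "sp2": synthetic.SpeciesIsotopeTruth(
                mu=[-15.0, 17.0],
                omega=[[2.0, 0.0], [0.0, 2.0]],
                sigma=[[0.05, 0.0], [0.0, 0.05]],
                n_individuals=2,
            ),
        }
        series = synthetic.simulate_whiskers(
            synthetic.IsotopeSimConfig(species=truth, segments_range=(8, 8), seed=3)
        )
        fit = fit_hierarchical_model(series, config=fast_fit_config)
        post = fit["sp"]
        between = post.omega_flat[:, 1, 1]
        residual = post.sigma_flat[:, 1, 1]
        assert (between > residual).mean() > 0.95


class TestPosteriorPredict:
    def test_output_shape(self, whisker_fit):
        points, idx = posterior_predict_individuals(
            whisker_fit["harbour"], m=20, n_draw_sets=100, seed=0
        )
        assert points.shape == (100, 20, 2)
        assert len(idx) == 100

    def test_small_m_warns(self, whisker_fit):
        with pytest.warns(UserWarning, match="unstable"):
            posterior_predict_individuals(
                whisker_fit["harbour"], m=5, n_draw_sets=10, seed=0
            )

    def test_empirical_covariance_matches_draw(self, whisker_fit):
        post = whisker_fit["harbour"]
        points, idx = posterior_predict_individuals(
            post, m=10_000, n_draw_sets=1, seed=0
        )
        emp = np.cov(points[0].T)
        target = post.omega_flat[idx[0]]
        np.testing.assert_allclose(emp, target, rtol=0.05, atol=0.02)


class TestScales:
    def test_identical_species_prob_half(self, fast_fit_config):
        truth = synthetic.SpeciesIsotopeTruth(
            mu=[-15.0, 17.0],
            omega=[[0.4, 0.0], [0.0, 0.4]],
            sigma=[[0.1, 0.0], [0.0, 0.1]],
            n_individuals=8,
        )
        series = synthetic.simulate_whiskers(
            synthetic.IsotopeSimConfig(
                species={"a": truth, "b": truth}, segments_range=(8, 8), seed=21
            )
        )
        fit = fit_hierarchical_model(series, config=fast_fit_config)
        scales = interindividual_scales(fit, "a", "b")
        d15n = scales[(scales["tracer"] == "d15N") & (scales["species"] == "a")]
        # same generative parameters; exceedance should hover near 1/2
        assert 0.15 < float(d15n["p_exceeds_other"].iloc[0]) < 0.85

    def test_planted_2x_scale_detected(self, whisker_fit):
        # grey d15N omega = 0.8 vs harbour 0.2: scale ratio 2
        scales = interindividual_scales(whisker_fit, "harbour", "grey")
        grey = scales[(scales["species"] == "grey") & (scales["tracer"] == "d15N")]
        assert float(grey["p_exceeds_other"].iloc[0]) > 0.9

    def test_ci_brackets_median(self, whisker_fit):
        scales = interindividual_scales(whisker_fit, "harbour", "grey")
        assert (scales["lo"] <= scales["scale_median"]).all()
        assert (scales["scale_median"] <= scales["hi"]).all()


class TestPersistence:
    def test_roundtrip(self, whisker_fit, tmp_path):
        path = tmp_path / "draws.nc"
        isotopes.save_draws(whisker_fit, path)
        loaded = isotopes.load_draws(path)
        assert set(loaded.species) == set(whisker_fit.species)
        for sp in whisker_fit.species:
            np.testing.assert_allclose(loaded[sp].mu, whisker_fit[sp].mu)
            np.testing.assert_allclose(loaded[sp].omega, whisker_fit[sp].omega)
            assert loaded[sp].individuals == whisker_fit[sp].individuals
            assert loaded[sp].rhat == pytest.approx(whisker_fit[sp].rhat)


class TestSimulatorLimits:
    def test_zero_noise_limit(self):
        truth = synthetic.SpeciesIsotopeTruth(
            mu=[-15.0, 17.0],
            omega=[[0.5, 0.0], [0.0, 0.5]],
            sigma=[[1e-14, 0.0], [0.0, 1e-14]],
            n_individuals=4,
        )
        series = synthetic.simulate_whiskers(
            synthetic.IsotopeSimConfig(species={"a": truth}, segments_range=(5, 5), seed=0)
        )
        spread = series.groupby("individual")[["d13C", "d15N"]].std().max().max()
        assert spread < 1e-6

    def test_zero_between_limit(self):
        truth = synthetic.SpeciesIsotopeTruth(
            mu=[-15.0, 17.0],
            omega=[[1e-14, 0.0], [0.0, 1e-14]],
            sigma=[[0.2, 0.0], [0.0, 0.2]],
            n_individuals=20,
        )
        series = synthetic.simulate_whiskers(
            synthetic.IsotopeSimConfig(species={"a": truth}, segments_range=(8, 8), seed=1)
        )
        means = series.groupby("individual")[["d13C", "d15N"]].mean()
        se = np.sqrt(0.2 / 8)
        assert (np.abs(means.mean() - [-15.0, 17.0]) < 3 * se / np.sqrt(20)).all()

    def test_grand_mean_within_3se(self):
        truth = synthetic.SpeciesIsotopeTruth(
            mu=[-15.0, 17.0],
            omega=[[0.3, 0.0], [0.0, 0.3]],
            sigma=[[0.1, 0.0], [0.0, 0.1]],
            n_individuals=10,
        )
        series = synthetic.simulate_whiskers(
            synthetic.IsotopeSimConfig(species={"a": truth}, segments_range=(10, 10), seed=5)
        )
        ind_means = series.groupby("individual")[["d13C", "d15N"]].mean()
        grand = ind_means.mean()
        se = ind_means.std(ddof=1) / np.sqrt(len(ind_means))
        assert (np.abs(grand - [-15.0, 17.0]) < 3 * se).all()

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            synthetic.SpeciesIsotopeTruth(
                mu=[0, 0], omega=[[1.0, 2.0], [2.0, 1.0]], sigma=np.eye(2), n_individuals=3
            )
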