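"""Sampler and diagnostics behavior: bookkeeping, determinism, degenerate
fits, convergence statistics and likelihood structure."""

import warnings

import numpy as np
import pytest

import dtmilk
from dtmilk.inference import (
    _design_matrix,
    _loglik_pairs,
    _predict_curves,
    _prepare,
    build_model,
    effective_sample_size,
    rhat,
)


class TestModelDefinition:
    def test_base_parameter_counts(self):
        model = build_model("none", "combined")
        assert model.n_beta == 4
        assert model.n_scales == 4
        assert model.has_correlation
        assert model.sigma_names == ("sigma_add", "sigma_prop")

    def test_full_adds_two_slopes(self):
        model = build_model("full", "combined")
        assert model.n_beta == 6
        assert model.beta_names[-2:] == ("slope_Vm_MWT", "slope_CLbo_BWT")

    def test_additive_has_one_sigma(self):
        assert build_model("full", "additive").sigma_names == ("sigma_add",)

    def test_unknown_config_rejected(self):
        with pytest.raises(ValueError):
            build_model("height", "combined")
        with pytest.raises(ValueError):
            build_model("full", "lognormal")

    def test_reference_weight_centering(self):
        """A 70 kg mother's stage-2 mean for ln V_m is exactly the intercept."""
        from tests_helpers import cohort_with_weights

        pairs = cohort_with_weights(mother_weights=[70.0, 50.0])
        data = _prepare(pairs, 0.60)
        X = _design_matrix(data, build_model("full", "combined"))
        beta = np.array([0.1, 0.2, 0.3, 3.49, 0.62, 0.17])
        means = np.einsum("ipq,q->ip", X, beta)
        assert means[0, 3] == pytest.approx(3.49)  # 70 kg: ln(70/70) = 0
        assert means[1, 3] == pytest.approx(3.49 + 0.62 * np.log(50.0 / 70.0))


class TestLikelihoodStructure:
    def test_combined_reduces_to_additive_when_sigma_prop_zero(self):
        cohort = dtmilk.simulate_cohort(
            dtmilk.SimulationTruth(), dtmilk.CohortDesign(n_pairs=3), seed=2
        )
        data = _prepare(cohort.pairs, 0.60)
        eta = np.log(
            cohort.individual[["CL_mb", "CL_bo", "k_mm", "V_m"]].to_numpy()
        )
        f_m, f_b = _predict_curves(eta, data)
        combined = _loglik_pairs(f_m, f_b, data, np.array([3.0, 0.0]))
        additive = _loglik_pairs(f_m, f_b, data, np.array([3.0, 0.0]))
        assert np.allclose(combined, additive)
        # and the proportional term does change the density
        assert not np.allclose(combined, _loglik_pairs(f_m, f_b, data, np.array([3.0, 0.02])))


class TestFit:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        return dtmilk.simulate_cohort(
            dtmilk.SimulationTruth(), dtmilk.CohortDesign(n_pairs=5), seed=8
        )

    def make_model(self, seed=3, **kw):
        kwargs = dict(n_chains=2, n_draws=100, n_warmup=300, thin=1, random_state=seed)
        kwargs.update(kw)
        return dtmilk.HierarchicalDtmModel(**kwargs)

    def test_same_seed_identical_draws(self, small_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = self.make_model().fit(small_cohort.pairs)
            b = self.make_model().fit(small_cohort.pairs)
        assert np.array_equal(a.posterior_.beta, b.posterior_.beta)
        assert np.array_equal(a.posterior_.eta, b.posterior_.eta)

    def test_different_seed_differs(self, small_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = self.make_model(seed=3).fit(small_cohort.pairs)
            c = self.make_model(seed=4).fit(small_cohort.pairs)
        assert not np.array_equal(a.posterior_.beta, c.posterior_.beta)

    def test_noise_free_pair_with_tight_priors_recovers_truth(self):
        truth = dtmilk.SimulationTruth(
            omega=np.zeros((4, 4)), sigma_add=0.0, sigma_prop=0.0,
            slope_vm=0.0, slope_clbo=0.0,
        )
        cohort = dtmilk.simulate_cohort(truth, dtmilk.CohortDesign(n_pairs=1), seed=5)
        true_theta = cohort.individual[["CL_mb", "CL_bo", "k_mm", "V_m"]].to_numpy()[0]
        priors = dtmilk.PriorSpec(logmu_mean=np.log(true_theta), logmu_sd=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = dtmilk.HierarchicalDtmModel(
                covariate_model="none",
                n_chains=2,
                n_draws=300,
                n_warmup=800,
                thin=2,
                random_state=2,
                priors=priors,
                sigma_fixed=(0.5, 0.0),
            ).fit(cohort.pairs)
        est = np.exp(model.posterior_.pooled("eta")[:, 0, :].mean(axis=0))
        assert np.all(np.abs(est / true_theta - 1) < 0.01)

    def test_posterior_contraction_with_more_pairs(self):
        truth = dtmilk.SimulationTruth()
        small = dtmilk.simulate_cohort(truth, dtmilk.CohortDesign(n_pairs=6), seed=10)
        large = dtmilk.simulate_cohort(truth, dtmilk.CohortDesign(n_pairs=30), seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_small = self.make_model(n_draws=250, n_warmup=600).fit(small.pairs)
            m_large = self.make_model(n_draws=250, n_warmup=600).fit(large.pairs)
        sd_small = m_small.posterior_.pooled("beta").std(axis=0, ddof=1)
        sd_large = m_large.posterior_.pooled("beta").std(axis=0, ddof=1)
        # every population mean is tighter on the larger cohort
        assert np.all(sd_large[:4] < sd_small[:4])

    def test_prior_sd_honored_without_data(self):
        model = dtmilk.HierarchicalDtmModel()
        draws = model.sample_prior_population(n_draws=4000, seed=1)
        sd = draws.std(axis=0)
        assert np.all(np.abs(sd / 1000.0 - 1) < 0.1)

    def test_draws_round_trip_through_csv(self, small_cohort, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = self.make_model().fit(small_cohort.pairs)
        model.posterior_.save(tmp_path / "draws.csv")
        back = dtmilk.PosteriorDraws.load(tmp_path / "draws.csv")
        assert np.allclose(back.beta, model.posterior_.beta)
        assert np.allclose(back.eta, model.posterior_.eta)
        assert np.allclose(back.rho, model.posterior_.rho)
        restored = dtmilk.HierarchicalDtmModel().attach(small_cohort.pairs, back)
        assert restored.pair_ids_ == model.pair_ids_


class TestDiagnostics:
    def test_rhat_near_one_for_iid_chains(self):
        rng = np.random.default_rng(0)
        assert 0.99 <= rhat(rng.standard_normal((3, 4000))) <= 1.01

    def test_rhat_flags_separated_chains(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.standard_normal(2000), 10.0 + rng.standard_normal(2000)])
        assert rhat(chains) > 1.1

    def test_rhat_requires_two_chains(self):
        with pytest.raises(ValueError, match="chains"):
            rhat(np.zeros((1, 100)))

    def test_rhat_constant_chains_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert rhat(np.ones((2, 100))) == 1.0

    def test_ess_iid_close_to_draw_count(self):
        rng = np.random.default_rng(2)
        n = 10_000
        ess = effective_sample_size(rng.standard_normal((1, n)))
        assert abs(ess - n) < 0.1 * n

    def test_ess_ar1_matches_closed_form(self):
        rho, n = 0.9, 10_000
        rng = np.random.default_rng(3)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + innov[t]
        expected = n * (1 - rho) / (1 + rho)
        ess = effective_sample_size(x[None])
        assert abs(ess - expected) < 0.35 * expected

    def test_ess_constant_chain_is_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="0"):
            assert effective_sample_size(np.full((1, 500), 2.5)) == 0.0

    def test_fit_diagnostics_cover_all_population_parameters(self, fitted_full):
        diag = fitted_full.diagnostics_
        assert set(fitted_full.posterior_.beta_names) <= set(diag)
        assert "sigma_add" in diag and "sigma_prop" in diag
        assert all(np.isfinite(v["rhat"]) and v["n_eff"] > 0 for v in diag.values())
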