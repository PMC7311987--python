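import numpy as np
import pandas as pd
import pytest

import sf6duq as sq
from sf6duq.population_utility import (
    DEFAULT_ALPHA0,
    PopulationModel,
    decomposition_report,
    nested_mean_utility_draws,
    posterior_mean_utility,
    valueset_utility_draws,
)
from sf6duq.psa import CoefficientDraws, MeanUtilityEstimate


class TestPopulationModel:
    def test_default_concentration(self):
        model = PopulationModel(states=["111111"], counts=[5])
        assert model.alpha0 == DEFAULT_ALPHA0 == pytest.approx(1 / 18000)
        assert model.posterior_alpha[0] == pytest.approx(5 + 1 / 18000)
        assert model.rest_alpha == pytest.approx(17999 / 18000)

    def test_from_sample(self, measurement_sample):
        model = PopulationModel.from_sample(measurement_sample)
        assert model.n == 4596
        assert len(model.states) == len(measurement_sample.states)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PopulationModel(states=["111111"], counts=[1, 2])
        with pytest.raises(ValueError):
            PopulationModel(states=["111111"], counts=[1], alpha0=-0.1)
        with pytest.raises(ValueError):
            # zero concentration with zero count is degenerate
            PopulationModel(states=["111111"], counts=[0], alpha0=0.0)


class TestClosedFormOracles:
    def test_two_state_dirichlet_moments(self):
        """Counts (3, 1) on utilities (1, 0) with a flat-to-zero prior:
        fbar = p_A ~ Beta(3, 1), so E = 3/4 and var = (3/4)(1/4)/5."""
        model = PopulationModel(
            states=["111111", "645655"], counts=[3, 1], alpha0=0.0
        )
        est = posterior_mean_utility(
            model, np.array([[1.0, 0.0]]), n_p_draws=200_000, seed=5
        )
        assert est.mean == pytest.approx(0.75, abs=0.002)
        assert est.var_total == pytest.approx(0.0375, rel=0.02)

    def test_concentrated_counts_degenerate(self):
        model = PopulationModel(states=["123455"], counts=[50], alpha0=0.0)
        u = 0.42
        est = posterior_mean_utility(
            model, np.array([[u]]), n_p_draws=1000, seed=6
        )
        assert est.mean == pytest.approx(u)
        assert est.var_total == pytest.approx(0.0, abs=1e-12)

    def test_single_value_set_kills_valueset_component(self):
        model = PopulationModel(
            states=["111111", "645655"], counts=[3, 1], alpha0=0.0
        )
        est = posterior_mean_utility(
            model, np.array([[1.0, 0.0]]), n_p_draws=5000, seed=7
        )
        assert est.se_valueset == 0.0
        assert est.var_total == pytest.approx(est.var_sampling)


@pytest.fixture(scope="module")
def small_model_and_draws(uk_fit):
    states, w = sq.population_state_weights()
    sample = sq.generate_measurement_sample(states, w, n=800, seed=30)
    model = PopulationModel.from_sample(sample)
    cd = sq.draw_coefficients(uk_fit, B=800, seed=31)
    return model, cd


class TestNestedSimulation:
    def test_total_variance_additivity(self, small_model_and_draws):
        """Law of total variance: the pooled variance of all nested fbar
        draws equals the sum of the two reported components within 3%."""
        model, cd = small_model_and_draws
        U, u_rest = valueset_utility_draws(cd, model.states)
        fbar = nested_mean_utility_draws(
            model, U, u_rest, n_p_draws=100, seed=32
        )
        comp_sampling = fbar.var(axis=1, ddof=1).mean()
        comp_valueset = fbar.mean(axis=1).var(ddof=1)
        pooled = fbar.reshape(-1).var(ddof=1)
        assert pooled == pytest.approx(comp_sampling + comp_valueset, rel=0.03)

    def test_mean_within_utility_range(self, small_model_and_draws):
        model, cd = small_model_and_draws
        est = posterior_mean_utility(model, cd, n_p_draws=50, seed=33)
        U, u_rest = valueset_utility_draws(cd, model.states)
        assert U.min() <= est.mean <= max(U.max(), u_rest.max())

    def test_sampling_component_shrinks_at_rate_1_over_n(self, uk_fit):
        """With a fixed value set the Dirichlet (sampling) variance of
        fbar decays like 1/n."""
        states, w = sq.population_state_weights()
        point = CoefficientDraws(uk_fit.coef[None, :])
        comps = {}
        for n, seed in ((500, 40), (5000, 41)):
            sample = sq.generate_measurement_sample(states, w, n=n, seed=seed)
            model = PopulationModel.from_sample(sample)
            est = posterior_mean_utility(
                model, point, n_p_draws=4000, seed=seed
            )
            comps[n] = est.var_sampling
        assert comps[500] / comps[5000] == pytest.approx(10.0, rel=0.25)

    def test_dirichlet_sampling_se_matches_plugin_se(self, uk_fit):
        """The Dirichlet posterior SD of fbar under a fixed value set is
        the analogue of the usual sample-mean SE: sd/sqrt(n+1)."""
        states, w = sq.population_state_weights()
        sample = sq.generate_measurement_sample(states, w, n=2000, seed=44)
        model = PopulationModel.from_sample(sample, alpha0=0.0)
        point = CoefficientDraws(uk_fit.coef[None, :])
        est = posterior_mean_utility(model, point, n_p_draws=20_000, seed=45)
        u = uk_fit.predict_utilities(sample.states, anchored=False)[
            "utility"
        ].to_numpy()
        wts = sample.counts / sample.n
        m = wts @ u
        plugin_var = (wts @ (u - m) ** 2) / (sample.n + 1)
        assert est.var_sampling == pytest.approx(plugin_var, rel=0.05)

    def test_rest_category_required_when_alpha0_positive(self, uk_fit):
        model = PopulationModel(states=["111111", "645655"], counts=[3, 1])
        with pytest.raises(ValueError, match="rest_utilities"):
            nested_mean_utility_draws(
                model, np.array([[1.0, 0.0]]), None, n_p_draws=10, seed=0
            )

    def test_dimension_mismatch_raises(self):
        model = PopulationModel(
            states=["111111", "645655"], counts=[3, 1], alpha0=0.0
        )
        with pytest.raises(ValueError, match="states"):
            nested_mean_utility_draws(
                model, np.ones((5, 3)), None, n_p_draws=10, seed=0
            )

    def test_bayesian_source_shapes(self, small_dataset):
        res = sq.BayesianValuationModel(small_dataset).fit(
            n_chains=2, burn_in=50, n_iter=100, seed=50
        )
        codes = ["111112", "211111"]
        U, u_rest = valueset_utility_draws(res, codes, seed=51)
        assert U.shape == (200, 2)
        assert u_rest.shape == (200,)

    def test_seed_determinism(self, small_model_and_draws):
        model, cd = small_model_and_draws
        a = posterior_mean_utility(model, cd, n_p_draws=20, seed=60)
        b = posterior_mean_utility(model, cd, n_p_draws=20, seed=60)
        assert a.mean == b.mean
        assert a.se_total == b.se_total


class TestDecompositionReport:
    def test_worked_example_psa_row(self):
        """The printed PSA components: sampling SE 0.000353456 against a
        total SE of 0.001689017 gives 79.1% underestimation."""
        est = MeanUtilityEstimate(
            mean=0.576,
            se_sampling=0.000353456,
            se_valueset=0.001651620,
            n=4596,
            label="PSA",
        )
        assert est.se_total == pytest.approx(0.001689017, abs=5e-9)
        assert round(est.underestimation_pct, 1) == 79.1

    def test_worked_example_bayes_row(self):
        est = MeanUtilityEstimate(
            mean=0.589,
            se_sampling=0.001778340,
            se_valueset=0.012716254,
            n=4596,
            label="Bayesian",
        )
        assert est.se_total == pytest.approx(0.01284, abs=5e-6)
        assert round(est.underestimation_pct, 2) == 86.15

    def test_table_layout(self):
        est = MeanUtilityEstimate(
            mean=0.6, se_sampling=0.001, se_valueset=0.002, n=100
        )
        rep = decomposition_report(est)
        assert list(rep.index) == [
            "mean_health_utility",
            "usual_estimate_of_uncertainty",
            "uncertainty_due_to_value_set",
            "total",
        ]
        assert rep.loc["total", "variance"] == pytest.approx(5e-6)
        assert rep.attrs["underestimation_pct"] == pytest.approx(
            100 * (1 - 0.001 / np.sqrt(5e-6))
        )
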