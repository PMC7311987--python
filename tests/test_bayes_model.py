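import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sf6duq as sq
from sf6duq.bayes_model import (
    BayesianValuationModel,
    PosteriorDraws,
    PriorSpec,
    _split_rhat,
    gelman_rubin,
    posterior_state_utility,
)
from sf6duq.state_space import design_matrix
from sf6duq.synthetic_data import GenerativeParams, ValuationDataset


def conjugate_posterior(y, Z, sigma_eps2, coef_variance):
    """Closed-form normal posterior for the coefficients when all
    variance components are known and there are no random effects."""
    A = Z.T @ Z / sigma_eps2 + np.eye(Z.shape[1]) / coef_variance
    V = np.linalg.inv(A)
    m = V @ (Z.T @ y / sigma_eps2)
    return m, V


class TestConjugateReduction:
    def test_matches_closed_form(self, small_dataset):
        """With variances held fixed and random effects pinned at zero,
        the coefficient draws are exact iid samples from the conjugate
        normal posterior; their mean and covariance must match it."""
        ve = 0.05
        model = BayesianValuationModel(small_dataset)
        res = model.fit(
            n_chains=2, burn_in=50, n_iter=20_000, seed=4,
            fixed_variances={"sigma_alpha2": 0.0, "sigma_delta2": 0.0,
                             "sigma_eps2": ve},
        )
        draws = res.draws.pooled("coef")
        y = small_dataset.records["sg_score"].to_numpy()
        Z = design_matrix(small_dataset.records["state"].tolist())
        m_ref, V_ref = conjugate_posterior(y, Z, ve, PriorSpec().coef_variance)
        # compare on the coefficients the data identify
        active = np.flatnonzero(Z.sum(axis=0) > 0)
        sd_ref = np.sqrt(np.diag(V_ref))
        mcse = sd_ref / np.sqrt(draws.shape[0])
        err = np.abs(draws.mean(axis=0) - m_ref)[active]
        assert (err < np.maximum(4 * mcse[active], 1e-3)).all()
        emp_V = np.cov(draws[:, active].T)
        ref_V = V_ref[np.ix_(active, active)]
        scale = np.sqrt(np.outer(np.diag(ref_V), np.diag(ref_V)))
        assert (np.abs(emp_V - ref_V) / scale).max() < 0.05

    def test_joint_sampler_marginal_ks(self):
        """Intercept-only toy: the sampled marginal of mu matches the
        posterior obtained by numerically integrating sigma_eps^2 out of
        the exact semi-conjugate joint (KS distance < 0.02)."""
        rng = np.random.default_rng(8)
        n = 30
        y = rng.normal(0.7, 0.2, n)
        df = pd.DataFrame(
            {
                "respondent_id": np.arange(1, n + 1),
                "state": ["111111"] * n,
                "sg_score": y,
            }
        )
        data = ValuationDataset(records=df, valued_states=["111111"])
        model = BayesianValuationModel(data)
        res = model.fit(
            n_chains=2, burn_in=200, n_iter=10_000, seed=9,
            fixed_variances={"sigma_alpha2": 0.0, "sigma_delta2": 0.0},
        )
        mu_draws = res.draws.pooled("coef")[:, 0]
        pr = PriorSpec()
        a, b, v0 = pr.variance_shape, pr.variance_rate, pr.coef_variance
        grid = np.linspace(y.mean() - 8 * y.std(), y.mean() + 8 * y.std(), 4001)
        S = ((y[:, None] - grid[None, :]) ** 2).sum(axis=0)
        log_post = -0.5 * grid**2 / v0 - (a + n / 2) * np.log(b + S / 2)
        dens = np.exp(log_post - log_post.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        ks = stats.kstest(mu_draws, lambda x: np.interp(x, grid, cdf)).statistic
        assert ks < 0.02


class TestVarianceShrinkage:
    def test_absent_misspecification_component_shrinks(self):
        """Data generated with sigma_delta = 0: the posterior median of
        sigma_delta^2 falls below sigma_eps^2/10 in >= 90% of replicate
        fits at the UK-like design (run at reduced scale)."""
        cfg = sq.uk_like_config()
        hits = 0
        reps = 50
        for r in range(reps):
            data = sq.generate_study(cfg, seed=3000 + r)
            res = BayesianValuationModel(data).fit(
                n_chains=2, burn_in=200, n_iter=300, seed=r
            )
            med = np.median(res.draws.pooled("sigma_delta2"))
            hits += med < cfg.params.sigma_eps**2 / 10
        assert hits / reps >= 0.90


class TestGelmanRubin:
    def test_identical_chains_unity(self):
        chain = np.random.default_rng(1).normal(size=200)
        assert _split_rhat(np.stack([chain, chain])) == 1.0

    def test_iid_converged_chains(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 10_000))
        assert 1.0 <= _split_rhat(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(3)
        chains = np.stack(
            [rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)]
        )
        assert _split_rhat(chains) > 3.0

    def test_degenerate_chain_raises(self):
        with pytest.raises(ValueError, match="within-chain"):
            _split_rhat(np.zeros((2, 100)))

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="at least"):
            _split_rhat(np.random.default_rng(0).normal(size=(2, 6)))

    def test_cross_check_against_arviz(self):
        """Loose agreement with arviz's rank-normalised split R-hat on
        well-mixed chains."""
        import arviz as az

        rng = np.random.default_rng(4)
        chains = rng.normal(size=(3, 4000))
        ours = _split_rhat(chains)
        theirs = float(az.rhat(chains))
        assert abs(ours - theirs) < 0.05

    def test_fit_reports_per_parameter(self, small_dataset):
        res = BayesianValuationModel(small_dataset).fit(
            n_chains=2, burn_in=100, n_iter=200, seed=5
        )
        rh = res.gelman_rubin()
        assert "intercept" in rh.index
        assert "sigma_delta2" in rh.index
        assert (rh >= 1.0).all()


@pytest.fixture(scope="module")
def fit_small(small_dataset):
    return BayesianValuationModel(small_dataset).fit(
        n_chains=2, burn_in=300, n_iter=1000, seed=6
    )


class TestPosteriorUtility:
    def test_full_health_anchored(self, fit_small):
        m, sd, (lo, hi) = fit_small.posterior_state_utility("111111")
        assert (m, sd, lo, hi) == (1.0, 0.0, 1.0, 1.0)

    @staticmethod
    def _unvalued_code(fit):
        valued = set(fit.draws.valued_states)
        return next(
            s.code for s in sq.enumerate_states()
            if s.code not in valued and s.code != "111111"
        )

    def test_valued_flag_mismatch_raises(self, fit_small):
        with pytest.raises(ValueError, match="not valued"):
            fit_small.posterior_state_utility(
                self._unvalued_code(fit_small), valued=True
            )

    def test_unvalued_state_uses_fresh_delta(self, fit_small):
        code = self._unvalued_code(fit_small)
        m, sd, _ = fit_small.posterior_state_utility(code, seed=1)
        # fresh delta inflates the SD beyond the coefficient-only SD
        coef = fit_small.draws.pooled("coef")
        z = design_matrix([code])[0]
        sd_coef_only = (coef @ z).std(ddof=1)
        assert sd > sd_coef_only

    def test_fitted_vs_marginal_delta(self, fit_small):
        code = fit_small.draws.valued_states[1]
        m1, _, _ = fit_small.posterior_state_utility(code, use_fitted_delta=True)
        m2, _, _ = fit_small.posterior_state_utility(
            code, use_fitted_delta=False, seed=2
        )
        assert m1 != m2  # fitted delta shifts the posterior mean

    def test_misspecification_widens_posterior(self, uk_misspec_dataset):
        """Per-state posterior SDs under the misspecification model
        exceed those of the delta-free model fitted to the same data."""
        model = BayesianValuationModel(uk_misspec_dataset)
        full = model.fit(n_chains=2, burn_in=300, n_iter=600, seed=7)
        pinned = model.fit(
            n_chains=2, burn_in=300, n_iter=600, seed=7,
            fixed_variances={"sigma_delta2": 0.0},
        )
        codes = uk_misspec_dataset.valued_states[:40]
        wider = 0
        for c in codes:
            _, sd_f, _ = full.posterior_state_utility(c)
            _, sd_p, _ = pinned.posterior_state_utility(c)
            wider += sd_f > sd_p
        assert wider / len(codes) >= 0.95

    def test_pinned_delta_draws_are_zero(self, small_dataset):
        res = BayesianValuationModel(small_dataset).fit(
            n_chains=2, burn_in=50, n_iter=100, seed=8,
            fixed_variances={"sigma_delta2": 0.0},
        )
        assert (res.draws.pooled("delta") == 0).all()


class TestSamplerBehaviour:
    def test_seed_determinism(self, small_dataset):
        a = BayesianValuationModel(small_dataset).fit(
            n_chains=2, burn_in=50, n_iter=100, seed=11
        )
        b = BayesianValuationModel(small_dataset).fit(
            n_chains=2, burn_in=50, n_iter=100, seed=11
        )
        np.testing.assert_array_equal(a.draws.coef, b.draws.coef)
        np.testing.assert_array_equal(a.draws.sigma_delta2, b.draws.sigma_delta2)

    def test_variance_draws_positive(self, small_dataset):
        res = BayesianValuationModel(small_dataset).fit(
            n_chains=2, burn_in=50, n_iter=200, seed=12
        )
        for name in ("sigma_delta2", "sigma_alpha2", "sigma_eps2"):
            assert (res.draws.pooled(name) > 0).all()

    def test_doubling_respondents_shrinks_posterior(self):
        pool = sq.sample_state_pool(60, seed=13)
        params = GenerativeParams(sigma_delta=0.03)
        sds = {}
        for m in (150, 300):
            data = sq.generate_valuation_study(
                params, m, 6, pool, seed=13
            )
            res = BayesianValuationModel(data).fit(
                n_chains=2, burn_in=300, n_iter=800, seed=14
            )
            sds[m] = res.draws.pooled("coef").std(axis=0, ddof=1)
        assert (sds[300] < sds[150]).mean() > 0.9

    def test_save_load_round_trip(self, tmp_path, small_dataset):
        res = BayesianValuationModel(small_dataset).fit(
            n_chains=2, burn_in=50, n_iter=60, seed=15
        )
        res.draws.save(tmp_path / "bundle")
        back = PosteriorDraws.load(tmp_path / "bundle")
        np.testing.assert_allclose(back.coef, res.draws.coef)
        np.testing.assert_allclose(back.delta, res.draws.delta)
        assert back.valued_states == res.draws.valued_states
        assert back.seeds == res.draws.seeds

    def test_requires_two_chains_without_fixed_variances(self, small_dataset):
        with pytest.raises(ValueError, match="chains"):
            BayesianValuationModel(small_dataset).fit(
                n_chains=1, burn_in=10, n_iter=10, seed=0
            )
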