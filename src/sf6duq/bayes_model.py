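"""Bayesian hierarchical valuation model with a misspecification term.

The additive dummy model cannot be exactly right for every state; the
hierarchical model acknowledges this with a state-level effect delta_i:

    y_ij = mu + theta' I(x_ij) + alpha_j + delta_i + eps_ij,
    alpha_j ~ N(0, sigma_alpha^2),   delta_i ~ N(0, sigma_delta^2),
    eps_ij ~ N(0, sigma_eps^2),

with delta_i = 0 for all i recovering the pure random-effects model.
Priors are vague: each regression coefficient is N(0, 1e6) and each
variance is InverseGamma(0.001, 0.001) (equivalently a Gamma(0.001,
0.001) prior on the precision tau = 1/sigma^2).

Every full conditional is conjugate, so the model is fitted by a blocked
Gibbs sampler: the 27 fixed effects are drawn jointly from their
multivariate-normal conditional, each alpha_j and delta_i from a scalar
normal, and each variance from its inverse gamma.  Two (or more) chains
are started from overdispersed points and convergence is monitored with
the split-chain Gelman-Rubin potential scale reduction factor, with
R-hat <= 1.1 taken as converged.  Defaults are 10,000 burn-in and 10,000
retained iterations per chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .state_space import COEF_NAMES, HealthState, as_state, design_matrix
from .synthetic_data import ValuationDataset, _spawn_seeds

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "BayesianValuationModel",
    "BayesResults",
    "gibbs_fit",
    "gelman_rubin",
    "posterior_state_utility",
]

_FULL_HEALTH_CODE = "111111"
RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class PriorSpec:
    """Priors: coefficients N(0, coef_variance); variances
    InverseGamma(variance_shape, variance_rate)."""

    coef_variance: float = 1e6
    variance_shape: float = 0.001
    variance_rate: float = 0.001

    def __post_init__(self) -> None:
        if min(self.coef_variance, self.variance_shape, self.variance_rate) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws, one leading axis per chain.

    Shapes: ``coef`` (C, T, 27); ``sigma_delta2``, ``sigma_alpha2``,
    ``sigma_eps2`` (C, T); ``alpha`` (C, T, n_respondents); ``delta``
    (C, T, n_valued_states).
    """

    coef: np.ndarray
    sigma_delta2: np.ndarray
    sigma_alpha2: np.ndarray
    sigma_eps2: np.ndarray
    alpha: np.ndarray
    delta: np.ndarray
    valued_states: list[str]
    respondent_ids: list
    coef_names: tuple[str, ...] = COEF_NAMES
    burn_in: int = 0
    n_iter: int = 0
    seeds: tuple[int, ...] = ()

    @property
    def n_chains(self) -> int:
        return self.coef.shape[0]

    @property
    def n_kept(self) -> int:
        return self.coef.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one component with chains concatenated."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    # --- columnar text bundle ------------------------------------------

    def save(self, directory) -> None:
        """Persist the draws as a directory of CSV files plus a YAML
        manifest (chains, iterations, seeds, column labels)."""
        from pathlib import Path

        import yaml

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        C, T = self.n_chains, self.n_kept
        idx = pd.MultiIndex.from_product(
            [range(C), range(T)], names=["chain", "iteration"]
        )
        pd.DataFrame(
            self.pooled("coef"), index=idx, columns=list(self.coef_names)
        ).to_csv(d / "coef.csv")
        pd.DataFrame(
            {
                "sigma_delta2": self.pooled("sigma_delta2"),
                "sigma_alpha2": self.pooled("sigma_alpha2"),
                "sigma_eps2": self.pooled("sigma_eps2"),
            },
            index=idx,
        ).to_csv(d / "variances.csv")
        pd.DataFrame(
            self.pooled("alpha"), index=idx,
            columns=[str(r) for r in self.respondent_ids],
        ).to_csv(d / "alpha.csv")
        pd.DataFrame(
            self.pooled("delta"), index=idx, columns=self.valued_states
        ).to_csv(d / "delta.csv")
        manifest = {
            "n_chains": C,
            "n_kept": T,
            "burn_in": int(self.burn_in),
            "n_iter": int(self.n_iter),
            "seeds": [int(s) for s in self.seeds],
            "coef_names": list(self.coef_names),
            "valued_states": list(self.valued_states),
            "respondent_ids": [str(r) for r in self.respondent_ids],
        }
        (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        from pathlib import Path

        import yaml

        d = Path(directory)
        man = yaml.safe_load((d / "manifest.yaml").read_text())
        C, T = man["n_chains"], man["n_kept"]

        def read(name, ncols):
            df = pd.read_csv(d / name, index_col=[0, 1])
            return df.to_numpy().reshape(C, T, ncols)

        k = len(man["coef_names"])
        var = pd.read_csv(d / "variances.csv", index_col=[0, 1])
        return cls(
            coef=read("coef.csv", k),
            sigma_delta2=var["sigma_delta2"].to_numpy().reshape(C, T),
            sigma_alpha2=var["sigma_alpha2"].to_numpy().reshape(C, T),
            sigma_eps2=var["sigma_eps2"].to_numpy().reshape(C, T),
            alpha=read("alpha.csv", len(man["respondent_ids"])),
            delta=read("delta.csv", len(man["valued_states"])),
            valued_states=[str(s) for s in man["valued_states"]],
            respondent_ids=man["respondent_ids"],
            coef_names=tuple(man["coef_names"]),
            burn_in=man["burn_in"],
            n_iter=man["n_iter"],
            seeds=tuple(man["seeds"]),
        )


class BayesResults:
    """Results wrapper around :class:`PosteriorDraws`."""

    def __init__(self, draws: PosteriorDraws) -> None:
        self.draws = draws

    def gelman_rubin(self, include_random_effects: bool = False) -> pd.Series:
        return gelman_rubin(self.draws, include_random_effects)

    @property
    def converged(self) -> bool:
        return bool((self.gelman_rubin() <= RHAT_THRESHOLD).all())

    def posterior_state_utility(
        self,
        state: HealthState | str,
        valued: bool | None = None,
        level: float = 0.95,
        use_fitted_delta: bool = True,
        seed: int = 0,
    ):
        return posterior_state_utility(
            self.draws, state, valued=valued, level=level,
            use_fitted_delta=use_fitted_delta, seed=seed,
        )

    def state_summary(
        self,
        states: Sequence[HealthState | str],
        level: float = 0.95,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Posterior mean/SD/interval per state; index = state codes."""
        rows = {}
        for s in states:
            code = as_state(s).code
            m, sd, (lo, hi) = self.posterior_state_utility(
                code, level=level, seed=seed
            )
            rows[code] = [m, sd, lo, hi]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["mean", "sd", "lower", "upper"]
        )

    def utility_draws(
        self, states: Sequence[HealthState | str], seed: int = 0
    ) -> np.ndarray:
        """(n_draws, S) posterior draws of each state's utility (fitted
        delta for valued states, fresh delta otherwise)."""
        cols = [
            _utility_draws_one(self.draws, as_state(s).code, None, True,
                               seed + k)
            for k, s in enumerate(states)
        ]
        return np.column_stack(cols)

    def summary(self) -> str:
        coef = self.draws.pooled("coef")
        rhat = self.gelman_rubin()
        lines = [
            "Bayesian SF-6D valuation model (Gibbs)",
            f"  chains: {self.draws.n_chains}   kept iterations/chain: "
            f"{self.draws.n_kept}   burn-in: {self.draws.burn_in}",
            f"  max R-hat: {rhat.max():.4f}  "
            f"({'converged' if self.converged else 'NOT converged'} at "
            f"threshold {RHAT_THRESHOLD})",
            "",
            f"  {'term':<14}{'post. mean':>12}{'post. SD':>12}{'R-hat':>9}",
        ]
        for i, name in enumerate(self.draws.coef_names):
            lines.append(
                f"  {name:<14}{coef[:, i].mean():>12.5f}"
                f"{coef[:, i].std(ddof=1):>12.5f}{rhat[name]:>9.3f}"
            )
        for name in ("sigma_delta2", "sigma_alpha2", "sigma_eps2"):
            v = self.draws.pooled(name)
            lines.append(
                f"  {name:<14}{v.mean():>12.5f}{v.std(ddof=1):>12.5f}"
                f"{rhat[name]:>9.3f}"
            )
        return "\n".join(lines)


class BayesianValuationModel:
    """Hierarchical model fitted by Gibbs sampling.

    Parameters
    ----------
    data : ValuationDataset
    priors : PriorSpec, optional
    """

    def __init__(
        self, data: ValuationDataset, priors: PriorSpec | None = None
    ) -> None:
        self.data = data
        self.priors = priors or PriorSpec()
        df = data.records
        self._resp_ids, self._resp = np.unique(
            df["respondent_id"].to_numpy(), return_inverse=True
        )
        self.valued_states = sorted(set(df["state"]))
        state_pos = {s: i for i, s in enumerate(self.valued_states)}
        self._state = df["state"].map(state_pos).to_numpy()
        self._y = df["sg_score"].to_numpy(dtype=float)
        self._Z = design_matrix(df["state"].tolist())

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, priors: PriorSpec | None = None
    ) -> "BayesianValuationModel":
        data = ValuationDataset(
            records=df, valued_states=sorted(df["state"].unique())
        )
        return cls(data, priors)

    def fit(
        self,
        n_chains: int = 2,
        burn_in: int = 10_000,
        n_iter: int = 10_000,
        seed: int = 0,
        fixed_variances: dict[str, float] | None = None,
    ) -> BayesResults:
        """Run the Gibbs sampler.

        ``fixed_variances`` optionally pins any of ``sigma_delta2``,
        ``sigma_alpha2``, ``sigma_eps2`` at a known value (skipping its
        update); pinning a random-effect variance at 0 removes that
        effect entirely.  Used for conjugate reductions and model
        comparisons.
        """
        if n_chains < 2 and fixed_variances is None:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if n_chains < 1:
            raise ValueError("need at least one chain")
        seeds = _spawn_seeds(seed, n_chains)
        chains = [
            self._run_chain(
                burn_in, n_iter, chain_seed=s, chain_index=c,
                fixed_variances=fixed_variances,
            )
            for c, s in enumerate(seeds)
        ]
        stack = {
            key: np.stack([ch[key] for ch in chains])
            for key in ("coef", "sigma_delta2", "sigma_alpha2", "sigma_eps2",
                        "alpha", "delta")
        }
        draws = PosteriorDraws(
            valued_states=self.valued_states,
            respondent_ids=list(self._resp_ids),
            burn_in=burn_in,
            n_iter=n_iter,
            seeds=tuple(seeds),
            **stack,
        )
        return BayesResults(draws)

    # --- the sampler ---------------------------------------------------

    def _run_chain(
        self,
        burn_in: int,
        n_iter: int,
        chain_seed: int,
        chain_index: int,
        fixed_variances: dict[str, float] | None,
    ) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(chain_seed)
        y, Z, resp, state = self._y, self._Z, self._resp, self._state
        N, k = Z.shape
        m = len(self._resp_ids)
        S = len(self.valued_states)
        pr = self.priors
        a0, b0, v0 = pr.variance_shape, pr.variance_rate, pr.coef_variance
        ZtZ = Z.T @ Z
        n_resp = np.bincount(resp, minlength=m).astype(float)
        n_state = np.bincount(state, minlength=S).astype(float)

        fixed = dict(fixed_variances or {})
        for key in fixed:
            if key not in ("sigma_delta2", "sigma_alpha2", "sigma_eps2"):
                raise ValueError(f"unknown variance component {key!r}")

        # overdispersed starting points: OLS +/- a few SE, variances
        # scattered over two orders of magnitude across chains
        beta_ols, *_ = linalg.lstsq(Z, y)
        resid = y - Z @ beta_ols
        v_tot = max(float(resid.var()), 1e-8)
        spread = 10.0 ** (chain_index - (0 if chain_index == 0 else 1))
        coef = beta_ols + rng.normal(0, 2 * np.sqrt(v_tot / N), size=k) * (
            1 + 3 * chain_index
        )
        se2 = fixed.get("sigma_eps2", v_tot * spread)
        sa2 = fixed.get("sigma_alpha2", 0.25 * v_tot * spread)
        sd2 = fixed.get("sigma_delta2", 0.1 * v_tot * spread)
        alpha = np.zeros(m)
        delta = np.zeros(S)

        out_coef = np.empty((n_iter, k))
        out_sd2 = np.empty(n_iter)
        out_sa2 = np.empty(n_iter)
        out_se2 = np.empty(n_iter)
        out_alpha = np.empty((n_iter, m))
        out_delta = np.empty((n_iter, S))

        eye_k = np.eye(k)
        for it in range(burn_in + n_iter):
            # fixed effects jointly: N(A^-1 Z'r / se2, A^-1)
            r = y - alpha[resp] - delta[state]
            A = ZtZ / se2 + eye_k / v0
            L = linalg.cholesky(A, lower=True)
            mean = linalg.cho_solve((L, True), Z.T @ r / se2)
            coef = mean + linalg.solve_triangular(
                L.T, rng.standard_normal(k), lower=False
            )
            fitted = Z @ coef

            # respondent effects
            if fixed.get("sigma_alpha2") == 0.0:
                alpha[:] = 0.0
            else:
                r2 = y - fitted - delta[state]
                prec = n_resp / se2 + 1.0 / sa2
                mu_a = np.bincount(resp, weights=r2, minlength=m) / se2 / prec
                alpha = mu_a + rng.standard_normal(m) / np.sqrt(prec)

            # state misspecification effects
            if fixed.get("sigma_delta2") == 0.0:
                delta[:] = 0.0
            else:
                r3 = y - fitted - alpha[resp]
                prec = n_state / se2 + 1.0 / sd2
                mu_d = np.bincount(state, weights=r3, minlength=S) / se2 / prec
                delta = mu_d + rng.standard_normal(S) / np.sqrt(prec)

            # variances (inverse gamma conditionals)
            if "sigma_eps2" not in fixed:
                eps = y - fitted - alpha[resp] - delta[state]
                se2 = _draw_inv_gamma(rng, a0 + N / 2, b0 + eps @ eps / 2)
            if "sigma_alpha2" not in fixed:
                sa2 = _draw_inv_gamma(rng, a0 + m / 2, b0 + alpha @ alpha / 2)
            if "sigma_delta2" not in fixed:
                sd2 = _draw_inv_gamma(rng, a0 + S / 2, b0 + delta @ delta / 2)
            if not np.isfinite(coef).all() or not np.isfinite([se2, sa2, sd2]).all():
                raise FloatingPointError(
                    "non-finite Gibbs state: data or priors are pathological"
                )

            j = it - burn_in
            if j >= 0:
                out_coef[j] = coef
                out_sd2[j] = sd2
                out_sa2[j] = sa2
                out_se2[j] = se2
                out_alpha[j] = alpha
                out_delta[j] = delta

        return {
            "coef": out_coef,
            "sigma_delta2": out_sd2,
            "sigma_alpha2": out_sa2,
            "sigma_eps2": out_se2,
            "alpha": out_alpha,
            "delta": out_delta,
        }


def _draw_inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape))


def gibbs_fit(
    data: ValuationDataset,
    priors: PriorSpec | None = None,
    n_chains: int = 2,
    burn_in: int = 10_000,
    n_iter: int = 10_000,
    seed: int = 0,
    fixed_variances: dict[str, float] | None = None,
) -> PosteriorDraws:
    """Functional entry point; see :class:`BayesianValuationModel`."""
    model = BayesianValuationModel(data, priors)
    return model.fit(
        n_chains=n_chains, burn_in=burn_in, n_iter=n_iter, seed=seed,
        fixed_variances=fixed_variances,
    ).draws


def _split_rhat(chains: np.ndarray) -> float:
    """Classical split-chain potential scale reduction factor.

    ``chains`` is (C, T); each chain is split in half, W is the mean
    within-chain variance, B/n the variance of the chain means, and
    R-hat = sqrt(((n-1)/n W + B/n) / W), floored at 1.
    """
    C, T = chains.shape
    n = T // 2
    if n < 5:
        raise ValueError("need at least 10 kept iterations per chain")
    halves = chains[:, : 2 * n].reshape(C * 2, n)
    within = halves.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0:
        raise ValueError("zero within-chain variance (degenerate chain)")
    B_over_n = halves.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * W + B_over_n
    return float(max(np.sqrt(var_hat / W), 1.0))


def gelman_rubin(
    draws: PosteriorDraws, include_random_effects: bool = False
) -> pd.Series:
    """Split-R-hat per scalar parameter (coefficients and variances; the
    individual alpha/delta effects too if requested)."""
    if draws.n_chains < 2:
        raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")
    out = {}
    for i, name in enumerate(draws.coef_names):
        out[name] = _split_rhat(draws.coef[:, :, i])
    for name in ("sigma_delta2", "sigma_alpha2", "sigma_eps2"):
        out[name] = _split_rhat(getattr(draws, name))
    if include_random_effects:
        for j, rid in enumerate(draws.respondent_ids):
            out[f"alpha[{rid}]"] = _split_rhat(draws.alpha[:, :, j])
        for i, code in enumerate(draws.valued_states):
            out[f"delta[{code}]"] = _split_rhat(draws.delta[:, :, i])
    return pd.Series(out, name="rhat")


def _utility_draws_one(
    draws: PosteriorDraws,
    code: str,
    valued: bool | None,
    use_fitted_delta: bool,
    seed: int,
) -> np.ndarray:
    z = design_matrix([code])[0]
    coef = draws.pooled("coef")
    u = coef @ z
    is_valued = code in draws.valued_states if valued is None else valued
    if is_valued and code not in draws.valued_states:
        raise ValueError(f"state {code} was not valued in the fitted data")
    if is_valued and use_fitted_delta:
        u = u + draws.pooled("delta")[:, draws.valued_states.index(code)]
    elif not is_valued or not use_fitted_delta:
        sd2 = draws.pooled("sigma_delta2")
        rng = np.random.default_rng(seed)
        u = u + rng.standard_normal(len(u)) * np.sqrt(sd2)
    return u


def posterior_state_utility(
    draws: PosteriorDraws,
    state: HealthState | str,
    valued: bool | None = None,
    level: float = 0.95,
    use_fitted_delta: bool = True,
    seed: int = 0,
) -> tuple[float, float, tuple[float, float]]:
    """Posterior mean, SD and percentile credible interval of a state's
    population utility.

    For a state valued in the study the fitted delta_i draws are used by
    default (``use_fitted_delta=False`` integrates delta out instead);
    for an unvalued state a fresh delta ~ N(0, sigma_delta2 draw) is
    attached to each retained draw.  Full health 111111 is anchored at
    (1, 0)."""
    code = as_state(state).code
    if code == _FULL_HEALTH_CODE:
        return 1.0, 0.0, (1.0, 1.0)
    u = _utility_draws_one(draws, code, valued, use_fitted_delta, seed)
    lo, hi = np.percentile(u, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(u.mean()), float(u.std(ddof=1)), (float(lo), float(hi))
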