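"""Population mean utility under a Dirichlet-multinomial state model.

A measurement sample records each subject's self-reported SF-6D state,
i(j) ~ Multinomial(p) with p a probability vector over the 18,000-state
space.  With a symmetric Dirichlet prior p ~ Dirichlet(alpha0, ...,
alpha0) (default alpha0 = 1/18000, so the prior carries one pseudo-count
in total and is negligible next to the data), the posterior of p is
Dirichlet(alpha0 + counts).  The population mean utility for a value set
u is fbar = sum_i p_i u_i, and when the value set itself is uncertain
its variance decomposes by the law of total variance:

    var(fbar) = E{var(fbar | value set)} + var{E(fbar | value set)}

— the first term is the sampling component (the usual uncertainty of a
sample mean), the second the value-set component, which does not shrink
as the measurement sample grows.

Both uncertainty sources are propagated by nested Monte Carlo: for each
value-set draw (PSA coefficient draw or Bayesian posterior draw), several
p vectors are drawn from the posterior Dirichlet and fbar is formed for
each; the two variance components are the mean of the within-value-set
variances and the variance of the within-value-set means.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_model import BayesResults, PosteriorDraws
from .psa import CoefficientDraws, MeanUtilityEstimate
from .state_space import N_STATES, as_state, design_matrix, enumerate_states
from .synthetic_data import MeasurementSample, _spawn_seeds

__all__ = [
    "PopulationModel",
    "posterior_mean_utility",
    "valueset_utility_draws",
    "nested_mean_utility_draws",
    "decomposition_report",
]

DEFAULT_ALPHA0 = 1.0 / N_STATES
DEFAULT_N_P_DRAWS = 100


@dataclass
class PopulationModel:
    """Dirichlet-multinomial model of the population state distribution.

    Conceptually the support is the full 18,000-state space with
    concentration ``alpha0`` per state; only observed states are stored,
    the remainder carrying aggregate prior mass alpha0 * (18000 - k).
    """

    states: list[str]
    counts: np.ndarray
    alpha0: float = DEFAULT_ALPHA0
    n_total_states: int = N_STATES

    def __post_init__(self) -> None:
        self.states = [as_state(s).code for s in self.states]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.states),):
            raise ValueError("counts must align with states")
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be nonnegative")
        if (self.posterior_alpha <= 0).any():
            raise ValueError("posterior_alpha must be strictly positive")

    @classmethod
    def from_sample(
        cls, sample: MeasurementSample, alpha0: float = DEFAULT_ALPHA0
    ) -> "PopulationModel":
        return cls(states=list(sample.states), counts=sample.counts.copy(),
                   alpha0=alpha0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def posterior_alpha(self) -> np.ndarray:
        """Posterior Dirichlet concentration for the observed states."""
        return self.alpha0 + self.counts

    @property
    def rest_alpha(self) -> float:
        """Aggregate posterior concentration of the unobserved states."""
        return self.alpha0 * (self.n_total_states - len(self.states))


@lru_cache(maxsize=1)
def _mean_design_all_states() -> np.ndarray:
    """Average 27-entry design vector over the full state space."""
    return design_matrix([s.code for s in enumerate_states()]).mean(axis=0)


def valueset_utility_draws(
    source: CoefficientDraws | BayesResults | PosteriorDraws,
    states: Sequence[str],
    rest_mean: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-draw utilities for ``states`` plus, optionally, each draw's
    mean utility over the rest of the 18,000-state space.

    PSA input: utilities are coef . [1, I(x)].  Bayesian input: the
    state-level misspecification term is attached per the fitting model
    (fitted delta for valued states, fresh delta draws otherwise); the
    rest-of-space mean uses the mean design vector, over which the fresh
    deltas average out.
    """
    codes = [as_state(s).code for s in states]
    Z = design_matrix(codes)
    zbar = _mean_design_all_states()
    k = len(codes)
    zrest = (N_STATES * zbar - Z.sum(axis=0)) / max(N_STATES - k, 1)
    if isinstance(source, CoefficientDraws):
        U = source.draws @ Z.T
        u_rest = source.draws @ zrest if rest_mean else None
        return U, u_rest
    draws = source.draws if isinstance(source, BayesResults) else source
    res = source if isinstance(source, BayesResults) else BayesResults(source)
    U = res.utility_draws(codes, seed=seed)
    u_rest = draws.pooled("coef") @ zrest if rest_mean else None
    return U, u_rest


def nested_mean_utility_draws(
    model: PopulationModel,
    utilities: np.ndarray,
    rest_utilities: np.ndarray | None = None,
    n_p_draws: int = DEFAULT_N_P_DRAWS,
    seed: int = 0,
    chunk: int = 200,
) -> np.ndarray:
    """(B, K) nested draws of fbar: for each of the B value sets, K
    independent draws of p from the posterior Dirichlet.

    ``utilities`` is (B, k) over the model's observed states;
    ``rest_utilities`` (B,) is each value set's mean utility over the
    unobserved remainder of the space, whose aggregate Dirichlet mass
    alpha0*(18000-k) is represented as one pseudo-category (its internal
    composition contributes O(alpha0) variance and is neglected).
    """
    U = np.atleast_2d(np.asarray(utilities, dtype=float))
    B, k = U.shape
    if k != len(model.states):
        raise ValueError(
            f"utilities cover {k} states but the model observes "
            f"{len(model.states)}"
        )
    alpha = model.posterior_alpha
    use_rest = model.rest_alpha > 0
    if use_rest:
        if rest_utilities is None:
            raise ValueError(
                "alpha0 > 0 with unobserved states: rest_utilities required"
            )
        alpha = np.append(alpha, model.rest_alpha)
        U = np.column_stack([U, np.asarray(rest_utilities, dtype=float)])
    rng = np.random.default_rng(seed)
    fbar = np.empty((B, n_p_draws))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        g = rng.gamma(alpha, size=(hi - lo, n_p_draws, len(alpha)))
        p = g / g.sum(axis=-1, keepdims=True)
        fbar[lo:hi] = np.einsum("ckj,cj->ck", p, U[lo:hi])
    return fbar


def posterior_mean_utility(
    model: PopulationModel,
    valueset_draws: CoefficientDraws | BayesResults | PosteriorDraws | np.ndarray,
    n_p_draws: int = DEFAULT_N_P_DRAWS,
    seed: int = 0,
    label: str = "",
) -> MeanUtilityEstimate:
    """Population mean utility with the law-of-total-variance split.

    ``valueset_draws`` may be PSA coefficient draws, a Bayesian fit, or a
    raw (B, k) utility array over the model's observed states (k must
    then match; with alpha0 > 0 pass a source object instead so the
    unobserved remainder can be valued).

    Returns a :class:`MeanUtilityEstimate` whose ``se_sampling`` is the
    square root of E{var(fbar|value set)} and ``se_valueset`` the square
    root of var{E(fbar|value set)}.
    """
    u_seed, p_seed = _spawn_seeds(seed, 2)
    if isinstance(valueset_draws, np.ndarray):
        U, u_rest = np.atleast_2d(valueset_draws), None
    else:
        U, u_rest = valueset_utility_draws(
            valueset_draws, model.states, seed=u_seed
        )
    fbar = nested_mean_utility_draws(
        model, U, u_rest, n_p_draws=n_p_draws, seed=p_seed
    )
    within_var = fbar.var(axis=1, ddof=1) if n_p_draws > 1 else np.zeros(len(fbar))
    within_mean = fbar.mean(axis=1)
    comp_sampling = float(within_var.mean())
    comp_valueset = float(within_mean.var(ddof=1)) if len(fbar) > 1 else 0.0
    return MeanUtilityEstimate(
        mean=float(fbar.mean()),
        se_sampling=float(np.sqrt(comp_sampling)),
        se_valueset=float(np.sqrt(comp_valueset)),
        n=model.n,
        label=label,
    )


def decomposition_report(estimate: MeanUtilityEstimate) -> pd.DataFrame:
    """Variance-decomposition table for a population mean utility.

    Rows: the mean itself, the usual (sampling-only) uncertainty, the
    uncertainty due to the value set, and the total; the table's
    ``attrs["underestimation_pct"]`` records by how many percent the
    usual SE understates the total SE."""
    rows = [
        ("mean_health_utility", estimate.mean, np.nan, np.nan),
        ("usual_estimate_of_uncertainty", np.nan, estimate.se_sampling,
         estimate.var_sampling),
        ("uncertainty_due_to_value_set", np.nan, estimate.se_valueset,
         estimate.var_valueset),
        ("total", np.nan, estimate.se_total, estimate.var_total),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "estimate", "se", "variance"])
    df = df.set_index("quantity")
    df.attrs["underestimation_pct"] = estimate.underestimation_pct
    df.attrs["label"] = estimate.label
    df.attrs["n"] = estimate.n
    return df
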