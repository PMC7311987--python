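"""Synthetic valuation studies and measurement samples.

No individual-level SF-6D valuation data are publicly deposited, so this
module generates studies with the same generative structure the models in
this package assume, under known true parameters:

    y_ij = mu + theta' I(x_ij) + alpha_j + delta_i + eps_ij

where ``y_ij`` is respondent *j*'s adjusted standard-gamble (SG) score for
health state *i* (dead = 0, full health = 1; adjusted scores below 0 are
allowed), ``alpha_j ~ N(0, sigma_alpha^2)`` is a respondent effect,
``delta_i ~ N(0, sigma_delta^2)`` is a state-level misspecification effect
(zero when the additive dummy model is exactly right), and
``eps_ij ~ N(0, sigma_eps^2)`` is observation noise.

Two presets emulate the published study designs: a UK-like study (249
valued states, 611 respondents, 6 valuations each, ~4% missing, for an
expected ~3518 records) and a HK-like study (197 states, 582 respondents,
8 valuations each).  Measurement samples — one self-reported state per
subject — are multinomial draws over the 18,000-state space.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .state_space import (
    COEF_NAMES,
    DUMMY_NAMES,
    HealthState,
    N_DUMMIES,
    N_PREDICTORS,
    as_state,
    design_matrix,
    enumerate_states,
)

__all__ = [
    "GenerativeParams",
    "ValuationDataset",
    "MeasurementSample",
    "StudyConfig",
    "default_true_params",
    "generate_valuation_study",
    "generate_study",
    "generate_measurement_sample",
    "sample_state_pool",
    "population_state_weights",
    "uk_like_config",
    "hk_like_config",
]

# Plausible utility decrements for the 25 level dummies plus MOST, on the
# dead=0 / full-health=1 scale, increasing in severity within each
# dimension; with mu = 1 they put predicted utilities roughly in
# [0.30, 1.0], spanning the range typical of published SF-6D value sets.
_DEFAULT_THETA = {
    "PF2": -0.035, "PF3": -0.035, "PF4": -0.044, "PF5": -0.056, "PF6": -0.117,
    "RL2": -0.053, "RL3": -0.055, "RL4": -0.050,
    "SF2": -0.057, "SF3": -0.059, "SF4": -0.072, "SF5": -0.087,
    "PAIN2": -0.042, "PAIN3": -0.042, "PAIN4": -0.065, "PAIN5": -0.102,
    "PAIN6": -0.171,
    "MH2": -0.042, "MH3": -0.042, "MH4": -0.100, "MH5": -0.118,
    "VT2": -0.071, "VT3": -0.071, "VT4": -0.092, "VT5": -0.092,
    "MOST": -0.061,
}


@dataclass(frozen=True)
class GenerativeParams:
    """True parameters of the generative model.

    ``sigma_delta = 0`` reproduces the pure random-effects (no
    misspecification) model exactly.
    """

    mu: float = 1.0
    theta: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULT_THETA[n] for n in DUMMY_NAMES])
    )
    sigma_alpha: float = 0.10
    sigma_delta: float = 0.0
    sigma_eps: float = 0.20

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (N_PREDICTORS,):
            raise ValueError(
                f"theta must have {N_PREDICTORS} entries, got {theta.shape}"
            )
        for name in ("sigma_alpha", "sigma_delta", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        object.__setattr__(self, "theta", theta)

    @property
    def coef(self) -> np.ndarray:
        """27-vector (mu, theta) in the package's coefficient layout."""
        return np.concatenate([[self.mu], self.theta])

    def utility(self, states) -> np.ndarray:
        """Noise-free utilities mu + theta'I(x) for one or more states."""
        Z = design_matrix(np.atleast_1d(states))
        return Z @ self.coef

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "mu": float(self.mu),
            "theta": {n: float(v) for n, v in zip(DUMMY_NAMES, self.theta)},
            "sigma_alpha": float(self.sigma_alpha),
            "sigma_delta": float(self.sigma_delta),
            "sigma_eps": float(self.sigma_eps),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerativeParams":
        doc = yaml.safe_load(Path(path).read_text())
        theta = np.array([doc["theta"][n] for n in DUMMY_NAMES])
        return cls(
            mu=doc["mu"],
            theta=theta,
            sigma_alpha=doc["sigma_alpha"],
            sigma_delta=doc["sigma_delta"],
            sigma_eps=doc["sigma_eps"],
        )


def default_true_params(sigma_delta: float = 0.0) -> GenerativeParams:
    """The package's default true value set and noise levels."""
    return GenerativeParams(sigma_delta=sigma_delta)


@dataclass
class ValuationDataset:
    """Records of a valuation study: respondent x state SG scores.

    ``records`` has columns ``respondent_id`` (int), ``state`` (6-digit
    code) and ``sg_score`` (float); ``valued_states`` is the study's
    distinct state pool as codes.
    """

    records: pd.DataFrame
    valued_states: list[str]

    def __post_init__(self) -> None:
        required = {"respondent_id", "state", "sg_score"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        self.valued_states = [as_state(s).code for s in self.valued_states]
        extra = set(self.records["state"]) - set(self.valued_states)
        if extra:
            raise ValueError(
                f"records reference states outside the pool: {sorted(extra)[:5]}"
            )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_respondents(self) -> int:
        return self.records["respondent_id"].nunique()

    def observed_state_means(self) -> pd.Series:
        """Per-state sample mean of the SG scores (index: state code)."""
        return self.records.groupby("state")["sg_score"].mean()

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, valued_states: Sequence[str] | None = None
    ) -> "ValuationDataset":
        df = pd.read_csv(path, dtype={"state": str})
        if valued_states is None:
            valued_states = sorted(df["state"].unique())
        return cls(records=df, valued_states=list(valued_states))


@dataclass
class MeasurementSample:
    """Self-reported SF-6D states, one per subject.

    Stored as counts over the distinct observed states; ``expand()``
    recovers the per-subject list in a deterministic order.
    """

    states: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.states = [as_state(s).code for s in self.states]
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.states),):
            raise ValueError("counts must align with states")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def expand(self) -> list[str]:
        return [s for s, c in zip(self.states, self.counts) for _ in range(c)]

    @classmethod
    def from_states(cls, states: Sequence[str]) -> "MeasurementSample":
        codes = [as_state(s).code for s in states]
        ser = pd.Series(codes).value_counts().sort_index()
        return cls(states=list(ser.index), counts=ser.to_numpy())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"subject_id": range(1, self.n + 1), "state": self.expand()}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementSample":
        df = pd.read_csv(path, dtype={"state": str})
        return cls.from_states(df["state"].tolist())


def sample_state_pool(
    n_states: int, seed: int, include_pits: bool = True
) -> list[HealthState]:
    """Draw a pool of distinct states uniformly from the 18,000-state
    space.  Valuation studies routinely include the pits state to anchor
    the severe end, so it is included by default."""
    rng = np.random.default_rng(seed)
    all_states = enumerate_states()
    idx = rng.choice(len(all_states), size=n_states, replace=False)
    pool = [all_states[i] for i in sorted(idx)]
    pits = HealthState((6, 4, 5, 6, 5, 5))
    if include_pits and pits not in pool:
        pool[-1] = pits
    return pool


def generate_valuation_study(
    params: GenerativeParams,
    n_respondents: int,
    states_per_respondent: int,
    state_pool: Sequence[HealthState | str],
    missing_rate: float = 0.0,
    seed: int = 0,
    clamp: tuple[float, float] | None = None,
) -> ValuationDataset:
    """Simulate a valuation study.

    Each respondent values a uniform without-replacement subset of the
    pool; records are then deleted completely at random at
    ``missing_rate``.  Scores are not clamped by default (adjusted SG
    scores may fall below 0); pass ``clamp=(-1, 1)`` to truncate.
    """
    pool = [as_state(s) for s in state_pool]
    if not pool:
        raise ValueError("state_pool must be nonempty")
    if states_per_respondent > len(pool):
        raise ValueError(
            f"states_per_respondent ({states_per_respondent}) exceeds pool "
            f"size ({len(pool)})"
        )
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    S = len(pool)
    utils = params.utility(pool)  # noise-free state utilities
    delta = rng.normal(0.0, params.sigma_delta, size=S)
    alpha = rng.normal(0.0, params.sigma_alpha, size=n_respondents)

    resp_ids, state_idx = [], []
    for j in range(n_respondents):
        chosen = rng.choice(S, size=states_per_respondent, replace=False)
        resp_ids.extend([j + 1] * states_per_respondent)
        state_idx.extend(chosen.tolist())
    resp_ids = np.asarray(resp_ids)
    state_idx = np.asarray(state_idx)

    eps = rng.normal(0.0, params.sigma_eps, size=len(resp_ids))
    y = utils[state_idx] + delta[state_idx] + alpha[resp_ids - 1] + eps
    if clamp is not None:
        y = np.clip(y, clamp[0], clamp[1])

    keep = rng.random(len(y)) >= missing_rate
    df = pd.DataFrame(
        {
            "respondent_id": resp_ids[keep],
            "state": [pool[i].code for i in state_idx[keep]],
            "sg_score": y[keep],
        }
    )
    return ValuationDataset(records=df, valued_states=[s.code for s in pool])


def generate_measurement_sample(
    states: Sequence[HealthState | str],
    weights: Sequence[float],
    n: int,
    seed: int = 0,
) -> MeasurementSample:
    """Draw ``n`` subjects' self-reported states i(j) ~ Multinomial(p)."""
    codes = [as_state(s).code for s in states]
    w = np.asarray(weights, dtype=float)
    if len(codes) == 0:
        raise ValueError("empty support")
    if w.shape != (len(codes),) or (w < 0).any():
        raise ValueError("weights must be nonnegative and align with states")
    total = w.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, w / total)
    keep = counts > 0
    return MeasurementSample(
        states=[c for c, k in zip(codes, keep) if k], counts=counts[keep]
    )


def population_state_weights(
    tilt: float | None = None,
    class_probs: Sequence[float] = (0.6, 0.3, 0.1),
    class_tilts: Sequence[float] = (1.5, 0.6, 0.15),
) -> tuple[list[str], np.ndarray]:
    """Prevalence weights over the full 18,000-state space.

    By default a mixture of severity classes (healthy / moderate / poor
    health), each placing geometrically decaying within-dimension level
    probabilities exp(-t * (level - 1)) with a class-specific tilt t.
    The mixture induces the positive cross-dimension correlation seen in
    self-reported data, concentrating a general population on mild
    states (default mean utility ~0.86 under the default value set).

    Passing ``tilt`` instead uses a single class with that tilt
    (``tilt=0`` is the uniform distribution over all states).
    """
    from .state_space import LEVEL_BOUNDS

    if tilt is not None:
        class_probs, class_tilts = (1.0,), (tilt,)
    if len(class_probs) != len(class_tilts):
        raise ValueError("class_probs and class_tilts must align")
    all_states = enumerate_states()
    levels = np.array([s.levels for s in all_states])
    w = np.zeros(len(all_states))
    for pi, t in zip(class_probs, class_tilts):
        comp = np.ones(len(all_states))
        for d, bound in enumerate(LEVEL_BOUNDS):
            probs = np.exp(-t * np.arange(bound, dtype=float))
            probs /= probs.sum()
            comp *= probs[levels[:, d] - 1]
        w += pi * comp
    return [s.code for s in all_states], w / w.sum()


@dataclass(frozen=True)
class StudyConfig:
    """A valuation-study design plus the generative truth."""

    name: str
    n_pool_states: int
    n_respondents: int
    states_per_respondent: int
    missing_rate: float
    params: GenerativeParams = field(default_factory=GenerativeParams)

    @property
    def expected_records(self) -> float:
        return (
            self.n_respondents
            * self.states_per_respondent
            * (1 - self.missing_rate)
        )

    def with_params(self, **kwargs) -> "StudyConfig":
        return replace(self, params=replace(self.params, **kwargs))


def uk_like_config(**param_overrides) -> StudyConfig:
    """UK-like design: 249 valued states, 611 respondents, 6 valuations
    each, missing completely at random at 148/3666 so the expected record
    count is ~3518."""
    cfg = StudyConfig(
        name="uk_like",
        n_pool_states=249,
        n_respondents=611,
        states_per_respondent=6,
        missing_rate=148 / 3666,
    )
    return cfg.with_params(**param_overrides) if param_overrides else cfg


def hk_like_config(**param_overrides) -> StudyConfig:
    """HK-like design: 197 valued states, 582 respondents, 8 valuations
    each (4656 elicitations, 60 missing)."""
    cfg = StudyConfig(
        name="hk_like",
        n_pool_states=197,
        n_respondents=582,
        states_per_respondent=8,
        missing_rate=60 / 4656,
    )
    return cfg.with_params(**param_overrides) if param_overrides else cfg


def generate_study(config: StudyConfig, seed: int) -> ValuationDataset:
    """Generate a study from a preset: the state pool and the records are
    drawn from independent streams fanned out from ``seed``."""
    pool_seed, data_seed = _spawn_seeds(seed, 2)
    pool = sample_state_pool(config.n_pool_states, seed=pool_seed)
    return generate_valuation_study(
        params=config.params,
        n_respondents=config.n_respondents,
        states_per_respondent=config.states_per_respondent,
        state_pool=pool,
        missing_rate=config.missing_rate,
        seed=data_seed,
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) deterministically from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
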