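"""Probabilistic sensitivity analysis over the value-set coefficients.

Parameter uncertainty in a fitted value set is propagated by drawing
coefficient vectors from a multivariate normal centred at the estimates
with the fitted coefficient covariance matrix (10,000 draws by default),
recomputing every quantity of interest per draw, and summarising the
resulting distribution with percentile intervals.

For a measurement sample scored with the value set, the variance of the
population mean utility splits by the law of total variance into a
sampling component (the usual SE of the sample mean, value set held at
its point estimate) and a value-set component (the spread of the sample
mean as the coefficients vary over their distribution):

    var(fbar) = E{var(fbar | value set)} + var{E(fbar | value set)}.

Ignoring the second term is what understates the SE of a population's
mean utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .re_model import REResults
from .state_space import HealthState, as_state, design_matrix
from .synthetic_data import MeasurementSample

__all__ = [
    "CoefficientDraws",
    "MeanUtilityEstimate",
    "draw_coefficients",
    "psa_state_summary",
    "psa_population_mean",
    "coverage",
]

_FULL_HEALTH_CODE = "111111"
DEFAULT_N_DRAWS = 10_000


@dataclass
class CoefficientDraws:
    """Monte-Carlo draws of the value-set coefficient vector.

    ``draws`` is (B, 27); its column means and covariance converge to the
    fit's coefficients and vcov as B grows.
    """

    draws: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    def state_utilities(
        self, states: Sequence[HealthState | str]
    ) -> np.ndarray:
        """(B, S) utilities: each draw's value for each state."""
        Z = design_matrix([as_state(s) for s in states])
        return self.draws @ Z.T


@dataclass
class MeanUtilityEstimate:
    """Population mean utility with its variance decomposition.

    ``se_sampling`` is the usual SE of the sample mean with the value set
    fixed; ``se_valueset`` is the SD of the sample mean over the value
    set's distribution; the two add in quadrature (law of total
    variance).
    """

    mean: float
    se_sampling: float
    se_valueset: float
    n: int
    label: str = ""

    @property
    def var_sampling(self) -> float:
        return self.se_sampling**2

    @property
    def var_valueset(self) -> float:
        return self.se_valueset**2

    @property
    def var_total(self) -> float:
        return self.var_sampling + self.var_valueset

    @property
    def se_total(self) -> float:
        return float(np.sqrt(self.var_total))

    @property
    def underestimation_pct(self) -> float:
        """Percent by which the usual (sampling-only) SE understates the
        total SE: 100 * (1 - se_sampling / se_total)."""
        if self.se_total == 0:
            if self.se_sampling != 0:
                raise ValueError("se_total = 0 with nonzero components")
            return 0.0
        return 100.0 * (1.0 - self.se_sampling / self.se_total)


def draw_coefficients(
    fit: REResults, B: int = DEFAULT_N_DRAWS, seed: int = 0
) -> CoefficientDraws:
    """Draw B coefficient vectors from N(fit.coef, fit.vcov).

    The covariance is factored through its symmetric eigendecomposition;
    eigenvalues in [-1e-10 * max, 0) are clipped to 0 (numerical PSD
    repair), materially negative ones raise.
    """
    vcov = 0.5 * (fit.vcov + fit.vcov.T)
    evals, evecs = np.linalg.eigh(vcov)
    scale = max(evals.max(), 1.0)
    if evals.min() < -1e-10 * scale:
        raise ValueError(
            f"vcov has materially negative eigenvalue {evals.min():.3e}"
        )
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((B, len(fit.coef)))
    return CoefficientDraws(draws=fit.coef + z @ root.T, seed=seed)


def psa_state_summary(
    draws: CoefficientDraws,
    states: Sequence[HealthState | str],
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-state PSA summary: mean, SD and percentile interval of the
    utility over the coefficient draws.  Full health 111111 is anchored
    at (1, 0, 1, 1).  Index = state codes."""
    codes = [as_state(s).code for s in states]
    U = draws.state_utilities(codes)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ddof = 1 if draws.B > 1 else 0
    out = pd.DataFrame(
        {
            "mean": U.mean(axis=0),
            "sd": U.std(axis=0, ddof=ddof),
            "lower": np.percentile(U, lo_q, axis=0),
            "upper": np.percentile(U, hi_q, axis=0),
        },
        index=codes,
    )
    if _FULL_HEALTH_CODE in codes:
        out.loc[_FULL_HEALTH_CODE] = [1.0, 0.0, 1.0, 1.0]
    return out


def psa_population_mean(
    draws: CoefficientDraws,
    fit: REResults,
    sample: MeasurementSample,
) -> MeanUtilityEstimate:
    """Mean utility of a measurement sample with the Eq.-of-total-variance
    split: the empirical (plug-in) path, weighting states by their
    observed sample frequencies.

    - ``mean`` and ``se_sampling`` use the point-estimate value set:
      mean = average individual utility, se_sampling = SD of individual
      utilities / sqrt(n).
    - ``se_valueset`` is the SD over coefficient draws of the
      sample-mean utility.
    """
    if sample.n == 0:
        raise ValueError("measurement sample is empty")
    codes = sample.states
    w = sample.counts / sample.n
    u_point = fit.predict_utilities(codes, anchored=False)["utility"].to_numpy()
    mean = float(w @ u_point)
    var_ind = float(w @ (u_point - mean) ** 2) * sample.n / (sample.n - 1)
    se_sampling = float(np.sqrt(var_ind / sample.n))
    U = draws.state_utilities(codes)  # (B, S)
    sample_means = U @ w
    se_valueset = float(sample_means.std(ddof=1)) if draws.B > 1 else 0.0
    return MeanUtilityEstimate(
        mean=mean,
        se_sampling=se_sampling,
        se_valueset=se_valueset,
        n=sample.n,
        label="PSA",
    )


def coverage(
    observed_means: pd.Series | dict,
    intervals: pd.DataFrame | dict,
) -> float:
    """Fraction of states whose observed mean lies inside its interval
    (inclusive).  ``observed_means`` maps state code -> value;
    ``intervals`` maps state code -> (lower, upper) (a DataFrame with
    ``lower``/``upper`` columns also works).  State sets must match."""
    obs = pd.Series(observed_means, dtype=float)
    if isinstance(intervals, pd.DataFrame):
        iv = intervals[["lower", "upper"]]
    else:
        iv = pd.DataFrame(intervals, index=["lower", "upper"]).T
    if set(obs.index) != set(iv.index):
        raise ValueError("observed means and intervals cover different states")
    iv = iv.loc[obs.index]
    inside = (iv["lower"] <= obs) & (obs <= iv["upper"])
    return float(inside.mean())
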