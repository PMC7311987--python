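"""Random-effects estimation of the additive SF-6D valuation model.

The model for respondent *j*'s adjusted SG score on state *i* is

    y_ij = mu + theta' I(x_ij) + alpha_j + eps_ij,
    alpha_j ~ N(0, sigma_alpha^2),  eps_ij ~ N(0, sigma_eps^2),

a Gaussian linear mixed model with a random respondent intercept.  Because
alpha_j has mean zero, the population utility of state x is
mu + theta' I(x).

Estimation maximises the exact marginal likelihood.  Within each
respondent the covariance is compound-symmetric (variance
sigma_alpha^2 + sigma_eps^2, covariance sigma_alpha^2), so the GLS
normal equations, the quadratic form and the log-determinant all reduce
to closed forms in per-respondent cross-products; the fixed effects are
profiled out by GLS inside a 2-parameter optimisation over the variance
components.  The reported coefficient covariance matrix is the inverse
GLS information at the estimates (conditional on the fitted variance
components, the usual mixed-model convention) — it is the object the
probabilistic sensitivity analysis draws from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import linalg, optimize

from .state_space import COEF_NAMES, HealthState, as_state, design_matrix
from .synthetic_data import ValuationDataset

__all__ = ["RandomEffectsModel", "REResults", "REFit", "fit_re_model", "predict_utility"]

_FULL_HEALTH_CODE = "111111"


class RankDeficiencyWarning(UserWarning):
    """A design column could not be identified from the valued states."""


class VarianceIdentifiabilityWarning(UserWarning):
    """Variance components not separately identified (e.g. one record per
    respondent); sigma_alpha^2 pinned at 0."""


@dataclass
class REResults:
    """Fitted random-effects valuation model.

    Attributes
    ----------
    coef : (27,) ndarray
        Intercept mu followed by the 26 dummy coefficients theta, in the
        ``COEF_NAMES`` layout.  Dropped (unidentified) columns are 0.
    vcov : (27, 27) ndarray
        Covariance matrix of ``coef`` (zero rows/cols for dropped terms).
    sigma_alpha2, sigma_eps2 : float
        Respondent-effect and residual variances.
    """

    coef: np.ndarray
    vcov: np.ndarray
    sigma_alpha2: float
    sigma_eps2: float
    log_likelihood: float
    n_respondents: int
    n_records: int
    coef_names: tuple[str, ...] = COEF_NAMES
    dropped: tuple[str, ...] = ()
    converged: bool = True

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        k = len(self.coef_names)
        if self.coef.shape != (k,) or self.vcov.shape != (k, k):
            raise ValueError("coef/vcov shape mismatch with coef_names")
        if self.sigma_alpha2 < 0 or self.sigma_eps2 < 0:
            raise ValueError("variance components must be nonnegative")

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the coefficients."""
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def predict_utility(
        self, state: HealthState | str, anchored: bool = True
    ) -> tuple[float, float]:
        """Mean utility and analytic (delta-method) SE for a state.

        The predictor vector z = [1, I(x)] gives mean = coef.z and
        SE = sqrt(z' vcov z).  With ``anchored=True`` (default) full
        health 111111 is reported as (1, 0) by convention, as value-set
        tables display it; ``anchored=False`` returns the raw model
        prediction for every state.
        """
        st = as_state(state)
        if anchored and st.code == _FULL_HEALTH_CODE:
            return 1.0, 0.0
        z = design_matrix([st])[0]
        mean = float(z @ self.coef)
        var = float(z @ self.vcov @ z)
        return mean, float(np.sqrt(max(var, 0.0)))

    def predict_utilities(
        self, states: Sequence[HealthState | str], anchored: bool = True
    ) -> pd.DataFrame:
        """Vectorised ``predict_utility``; index = state codes."""
        codes = [as_state(s).code for s in states]
        Z = design_matrix(codes)
        mean = Z @ self.coef
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", Z, self.vcov, Z), 0, None))
        df = pd.DataFrame({"utility": mean, "se": se}, index=codes)
        if anchored and _FULL_HEALTH_CODE in codes:
            df.loc[_FULL_HEALTH_CODE, ["utility", "se"]] = [1.0, 0.0]
        return df

    def summary(self) -> str:
        lines = [
            "Random-effects SF-6D valuation model (ML)",
            f"  records: {self.n_records}   respondents: {self.n_respondents}",
            f"  sigma_alpha^2 = {self.sigma_alpha2:.6f}   "
            f"sigma_eps^2 = {self.sigma_eps2:.6f}",
            f"  log-likelihood = {self.log_likelihood:.3f}",
            "",
            f"  {'term':<10}{'estimate':>12}{'SE':>12}",
        ]
        for name, est, se in zip(self.coef_names, self.coef, self.bse):
            flag = "  (dropped)" if name in self.dropped else ""
            lines.append(f"  {name:<10}{est:>12.5f}{se:>12.5f}{flag}")
        return "\n".join(lines)

    # --- serialization: the "value set with uncertainty" artifact ---

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "coefficients": [
                {"name": n, "estimate": float(c), "se": float(s)}
                for n, c, s in zip(self.coef_names, self.coef, self.bse)
            ],
            "vcov": [[float(v) for v in row] for row in self.vcov],
            "sigma_alpha2": float(self.sigma_alpha2),
            "sigma_eps2": float(self.sigma_eps2),
            "log_likelihood": float(self.log_likelihood),
            "n_respondents": int(self.n_respondents),
            "n_records": int(self.n_records),
            "dropped": list(self.dropped),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "REResults":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            coef=np.array([c["estimate"] for c in doc["coefficients"]]),
            vcov=np.array(doc["vcov"]),
            sigma_alpha2=doc["sigma_alpha2"],
            sigma_eps2=doc["sigma_eps2"],
            log_likelihood=doc["log_likelihood"],
            n_respondents=doc["n_respondents"],
            n_records=doc["n_records"],
            coef_names=tuple(c["name"] for c in doc["coefficients"]),
            dropped=tuple(doc.get("dropped", ())),
        )


#: Spec-facing alias: the fitted-model container.
REFit = REResults


class RandomEffectsModel:
    """Random-intercept Gaussian model for valuation data.

    Build from a :class:`ValuationDataset` (or a dataframe with columns
    ``respondent_id``, ``state``, ``sg_score``) and call :meth:`fit`.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                 coef_names: Sequence[str] = COEF_NAMES) -> None:
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        if y.ndim != 1 or X.shape[0] != len(y) or groups.shape != y.shape:
            raise ValueError("y, X, groups must have matching first dimension")
        _, self._grp = np.unique(groups, return_inverse=True)
        self.n_respondents = int(self._grp.max()) + 1
        if self.n_respondents < 2:
            raise ValueError("need at least 2 respondents")
        self.y = y
        self.X = X
        self.coef_names = tuple(coef_names)
        self._prepare()

    @classmethod
    def from_dataset(cls, data: ValuationDataset) -> "RandomEffectsModel":
        return cls.from_dataframe(data.records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RandomEffectsModel":
        X = design_matrix(df["state"].tolist())
        return cls(df["sg_score"].to_numpy(), X, df["respondent_id"].to_numpy())

    # --- internal machinery -------------------------------------------

    def _prepare(self) -> None:
        """Drop unidentified columns and cache per-respondent and
        per-group-size cross-products used by the closed-form likelihood."""
        X = self.X
        # identify estimable columns from the pooled design via pivoted QR
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        keep_idx = np.sort(piv[:rank])
        dropped_idx = np.sort(piv[rank:])
        self._keep = keep_idx
        self.dropped = tuple(self.coef_names[i] for i in dropped_idx)
        if self.dropped:
            warnings.warn(
                "design matrix is rank deficient; dropping unidentified "
                f"terms: {', '.join(self.dropped)}",
                RankDeficiencyWarning,
                stacklevel=3,
            )
        Xk = X[:, keep_idx]
        m, p = self.n_respondents, Xk.shape[1]
        grp = self._grp
        self._n_j = np.bincount(grp, minlength=m)
        # s_j = X_j' 1,  t_j = y_j' 1
        s = np.zeros((m, p))
        for c in range(p):
            s[:, c] = np.bincount(grp, weights=Xk[:, c], minlength=m)
        t = np.bincount(grp, weights=self.y, minlength=m)
        self._XtX = Xk.T @ Xk
        self._Xty = Xk.T @ self.y
        self._yty = float(self.y @ self.y)
        # bucket by distinct group size n: C_n = sum s_j s_j', b_n = sum s_j t_j
        self._sizes = np.unique(self._n_j)
        self._C, self._b, self._q, self._mn = {}, {}, {}, {}
        for n in self._sizes:
            mask = self._n_j == n
            sj = s[mask]
            tj = t[mask]
            self._C[n] = sj.T @ sj
            self._b[n] = sj.T @ tj
            self._q[n] = float(tj @ tj)
            self._mn[n] = int(mask.sum())
        self._s = s
        self._t = t
        self._Xk = Xk

    def _gls_pieces(self, va: float, ve: float):
        """X'S^-1 X, X'S^-1 y, y'S^-1 y and log|S| for Sigma_j =
        ve*I + va*11' per respondent, via the Sherman-Morrison identity."""
        A = self._XtX / ve
        u = self._Xty / ve
        qf = self._yty / ve
        logdet = 0.0
        for n in self._sizes:
            d = ve + n * va
            c = va / (ve * d)
            if c != 0.0:
                A = A - c * self._C[n]
                u = u - c * self._b[n]
                qf = qf - c * self._q[n]
            logdet += self._mn[n] * ((n - 1) * np.log(ve) + np.log(d))
        return A, u, qf, logdet

    def profile_loglike(self, sigma_alpha2: float, sigma_eps2: float) -> float:
        """Marginal log-likelihood at (sigma_alpha2, sigma_eps2) with the
        fixed effects profiled out by GLS."""
        if sigma_eps2 <= 0 or sigma_alpha2 < 0:
            return -np.inf
        A, u, qf, logdet = self._gls_pieces(sigma_alpha2, sigma_eps2)
        try:
            beta = linalg.solve(A, u, assume_a="pos")
        except linalg.LinAlgError:
            return -np.inf
        quad = qf - beta @ u
        N = len(self.y)
        return -0.5 * (N * np.log(2 * np.pi) + logdet + quad)

    def fit(self, start: tuple[float, float] | None = None) -> REResults:
        """Maximise the marginal likelihood; returns :class:`REResults`.

        ``start`` optionally overrides the moment-based initial
        (sigma_alpha2, sigma_eps2).
        """
        pin_alpha = bool(self._n_j.max() <= 1)
        if pin_alpha:
            warnings.warn(
                "every respondent has a single record: sigma_alpha^2 and "
                "sigma_eps^2 are not separately identified; pinning "
                "sigma_alpha^2 = 0",
                VarianceIdentifiabilityWarning,
                stacklevel=2,
            )

        # moment-based start from OLS residuals
        beta0, *_ = linalg.lstsq(self._Xk, self.y)
        resid = self.y - self._Xk @ beta0
        v_tot = float(resid @ resid) / max(len(resid) - self._Xk.shape[1], 1)
        rbar = self._t / np.maximum(self._n_j, 1) - (
            self._s / np.maximum(self._n_j, 1)[:, None]
        ) @ beta0
        va0 = float(np.clip(np.var(rbar) - v_tot / max(self._n_j.mean(), 1.0),
                            1e-6, v_tot))
        ve0 = max(v_tot - va0, 1e-6)
        starts = [(va0, ve0), (0.1 * v_tot, 0.9 * v_tot), (1e-4, v_tot)]
        if start is not None:
            starts.insert(0, tuple(start))

        # floor keeps the perfect-fit (noiseless) limit numerically sane
        _VE_FLOOR = 1e-12

        def nll(log_params):
            va = 0.0 if pin_alpha else np.exp(log_params[0])
            ve = max(np.exp(log_params[-1]), _VE_FLOOR)
            return -self.profile_loglike(va, ve)

        best = None
        for va_s, ve_s in starts:
            x0 = (
                [np.log(max(ve_s, 1e-8))]
                if pin_alpha
                else [np.log(max(va_s, 1e-8)), np.log(max(ve_s, 1e-8))]
            )
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": 1e-10,
                                             "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
            if best.success:
                break  # the 2-parameter profile likelihood is unimodal in
                # practice; later starts only matter after a failure
        converged = bool(best.success)
        if pin_alpha:
            va, ve = 0.0, max(float(np.exp(best.x[-1])), _VE_FLOOR)
        else:
            va = float(np.exp(best.x[0]))
            ve = max(float(np.exp(best.x[1])), _VE_FLOOR)
            if va < max(1e-10 * ve, 1e-15):  # boundary: treat as zero
                va = 0.0
        if not converged:
            warnings.warn(
                "variance-component optimisation did not report convergence",
                UserWarning,
                stacklevel=2,
            )

        A, u, _, _ = self._gls_pieces(va, ve)
        beta = linalg.solve(A, u, assume_a="pos")
        vcov_k = linalg.inv(A)
        vcov_k = 0.5 * (vcov_k + vcov_k.T)
        k = len(self.coef_names)
        coef = np.zeros(k)
        vcov = np.zeros((k, k))
        coef[self._keep] = beta
        vcov[np.ix_(self._keep, self._keep)] = vcov_k
        return REResults(
            coef=coef,
            vcov=vcov,
            sigma_alpha2=va,
            sigma_eps2=ve,
            log_likelihood=self.profile_loglike(va, ve),
            n_respondents=self.n_respondents,
            n_records=len(self.y),
            coef_names=self.coef_names,
            dropped=self.dropped,
            converged=converged,
        )


def fit_re_model(data: ValuationDataset | pd.DataFrame) -> REResults:
    """Convenience wrapper: build a :class:`RandomEffectsModel` from a
    valuation dataset and fit it by ML."""
    if isinstance(data, pd.DataFrame):
        return RandomEffectsModel.from_dataframe(data).fit()
    return RandomEffectsModel.from_dataset(data).fit()


def predict_utility(
    fit: REResults, state: HealthState | str, anchored: bool = True
) -> tuple[float, float]:
    """Mean utility and analytic SE for ``state`` under a fitted model."""
    return fit.predict_utility(state, anchored=anchored)
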