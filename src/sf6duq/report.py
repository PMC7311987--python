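"""State-level summary tables, interval/coverage summaries and fixtures.

``build_summary`` assembles, per requested state, the observed sample
mean of its SG valuations alongside the predictions of up to three
methods:

- ``analytic``: the RE-model point prediction with its delta-method SE;
- ``psa``: the mean/SD/percentile interval over coefficient draws;
- ``bayes``: the posterior mean/SD/credible interval (including the
  misspecification term).

Two kinds of intervals coexist.  The per-method ``*_lower/upper`` bounds
quantify value-set (parameter) uncertainty only.  For coverage of the
*observed* state means, each method's ``*_cover_*`` interval additionally
folds in the sampling SE of the observed mean in quadrature; the
``naive`` method carries no parameter uncertainty at all, so its coverage
interval uses the sampling SE alone and is nested inside the others by
construction.

The numeric content of the published worked-example tables is packaged
as fixtures (``load_fixture``) for internal-consistency checks.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bayes_model import BayesResults
from .psa import CoefficientDraws, coverage, psa_state_summary
from .re_model import REResults
from .state_space import as_state
from .synthetic_data import ValuationDataset

__all__ = [
    "StateSummaryTable",
    "build_summary",
    "interval_width_summary",
    "coverage_by_method",
    "load_fixture",
    "plot_state_intervals",
]

#: A state-keyed table of observed means and per-method predictions.
StateSummaryTable = pd.DataFrame

_METHODS = ("naive", "analytic", "psa", "bayes")


def build_summary(
    dataset: ValuationDataset,
    re_fit: REResults | None = None,
    coef_draws: CoefficientDraws | None = None,
    bayes_results: BayesResults | None = None,
    states: Sequence[str] | None = None,
    level: float = 0.95,
    seed: int = 0,
) -> StateSummaryTable:
    """One row per requested state (default: all valued states)."""
    if states is None:
        codes = list(dataset.valued_states)
    else:
        codes = [as_state(s).code for s in states]
    if not codes:
        return pd.DataFrame(index=pd.Index([], name="state"))

    zcrit = stats.norm.ppf(0.5 + level / 2)
    grp = dataset.records.groupby("state")["sg_score"]
    obs_mean = grp.mean()
    obs_n = grp.size()
    obs_se = grp.std(ddof=1) / np.sqrt(obs_n)

    out = pd.DataFrame(index=pd.Index(codes, name="state"))
    out["observed"] = obs_mean.reindex(codes)
    out["n_obs"] = obs_n.reindex(codes).fillna(0).astype(int)
    out["se_obs"] = obs_se.reindex(codes)
    out["never_valued"] = out["n_obs"] == 0

    if re_fit is not None:
        pred = re_fit.predict_utilities(codes)
        out["analytic_predicted"] = pred["utility"].to_numpy()
        out["analytic_sd"] = pred["se"].to_numpy()
        out["analytic_lower"] = out["analytic_predicted"] - zcrit * out["analytic_sd"]
        out["analytic_upper"] = out["analytic_predicted"] + zcrit * out["analytic_sd"]
        # naive: same point prediction, no parameter uncertainty
        out["naive_predicted"] = out["analytic_predicted"]
        out["naive_sd"] = 0.0

    if coef_draws is not None:
        ps = psa_state_summary(coef_draws, codes, level=level)
        out["psa_predicted"] = ps["mean"].to_numpy()
        out["psa_sd"] = ps["sd"].to_numpy()
        out["psa_lower"] = ps["lower"].to_numpy()
        out["psa_upper"] = ps["upper"].to_numpy()

    if bayes_results is not None:
        bs = bayes_results.state_summary(codes, level=level, seed=seed)
        out["bayes_predicted"] = bs["mean"].to_numpy()
        out["bayes_sd"] = bs["sd"].to_numpy()
        out["bayes_lower"] = bs["lower"].to_numpy()
        out["bayes_upper"] = bs["upper"].to_numpy()

    # coverage intervals: parameter SD (0 for naive) + observed-mean
    # sampling SE, combined in quadrature around the method's prediction
    for m in _METHODS:
        if f"{m}_predicted" not in out.columns:
            continue
        se = np.sqrt(out[f"{m}_sd"] ** 2 + out["se_obs"].fillna(0.0) ** 2)
        out[f"{m}_cover_lower"] = out[f"{m}_predicted"] - zcrit * se
        out[f"{m}_cover_upper"] = out[f"{m}_predicted"] + zcrit * se
    return out


def interval_width_summary(
    table: StateSummaryTable, method: str
) -> tuple[float, float, float]:
    """Mean, min and max width of a method's parameter-uncertainty
    intervals across the table's states."""
    lo, hi = f"{method}_lower", f"{method}_upper"
    if lo not in table.columns:
        raise KeyError(f"no intervals for method {method!r} in table")
    widths = (table[hi] - table[lo]).to_numpy(dtype=float)
    if len(widths) == 0:
        return (np.nan, np.nan, np.nan)
    return float(widths.mean()), float(widths.min()), float(widths.max())


def coverage_by_method(
    table: StateSummaryTable, methods: Sequence[str] = _METHODS
) -> pd.Series:
    """Fraction of states whose observed mean falls in each method's
    coverage interval (states never valued are excluded)."""
    tab = table[~table["never_valued"]]
    out = {}
    for m in methods:
        lo = f"{m}_cover_lower"
        if lo not in tab.columns:
            continue
        iv = tab[[lo, f"{m}_cover_upper"]].rename(
            columns={lo: "lower", f"{m}_cover_upper": "upper"}
        )
        out[m] = coverage(tab["observed"], iv)
    return pd.Series(out, name="coverage")


def load_fixture(name: str) -> pd.DataFrame:
    """Packaged worked-example tables: ``"table1"`` (per-state inference
    for 25 selected states) or ``"table2"`` (population mean-utility
    variance decomposition)."""
    if name not in ("table1", "table2"):
        raise KeyError(f"unknown fixture {name!r}; use 'table1' or 'table2'")
    ref = resources.files("sf6duq").joinpath("data", f"{name}.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"state": str} if name == "table1" else None)
    return df


def plot_state_intervals(
    table: StateSummaryTable,
    method: str = "psa",
    ax=None,
    sort_by: str | None = "observed",
):
    """Observed means (dots), predictions (crosses) and 95% intervals:
    grey = no parameter uncertainty, black = the requested method."""
    import matplotlib.pyplot as plt

    tab = table[~table["never_valued"]]
    if sort_by:
        tab = tab.sort_values(sort_by)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.3 * len(tab)), 4))
    x = np.arange(len(tab))
    if "naive_cover_lower" in tab.columns:
        ax.vlines(x - 0.12, tab["naive_cover_lower"], tab["naive_cover_upper"],
                  color="0.6", lw=2, label="no parameter uncertainty")
    ax.vlines(x + 0.12, tab[f"{method}_cover_lower"],
              tab[f"{method}_cover_upper"], color="k", lw=2,
              label=f"{method} (with parameter uncertainty)")
    if f"{method}_predicted" in tab.columns:
        ax.plot(x, tab[f"{method}_predicted"], "x", color="0.4",
                label="predicted")
    ax.plot(x, tab["observed"], "o", color="k", ms=4, label="observed mean")
    ax.set_xticks(x)
    ax.set_xticklabels(tab.index, rotation=90, fontsize=7)
    ax.set_ylabel("utility")
    ax.legend(fontsize=8, loc="lower right")
    ax.figure.tight_layout()
    return ax
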