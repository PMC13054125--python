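"""AIC, BIC, likelihood-ratio tests and support classification."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["aic", "bic", "lrt", "aic_support", "compare_models"]


def aic(lnl: float, p: int) -> float:
    """Akaike information criterion: -2 lnL + 2p."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return -2.0 * lnl + 2.0 * p


def bic(lnl: float, p: int, n: int) -> float:
    """Bayesian information criterion: -2 lnL + ln(n) p."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    return -2.0 * lnl + np.log(n) * p


def lrt(lnl_less: float, lnl_more: float, df: int):
    """Likelihood-ratio statistic -2(lnL_less - lnL_more) and chi2 p-value.

    A negative statistic (possible when REML likelihoods from different
    fixed-effect structures are compared) is returned as computed, with a
    warning and p-value 1.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = -2.0 * (lnl_less - lnl_more)
    if stat < 0:
        warnings.warn(
            "negative LRT statistic: the 'larger' model has the lower likelihood",
            RuntimeWarning,
        )
        return float(stat), 1.0
    return float(stat), float(stats.chi2.sf(stat, df))


_SUPPORT_LABELS = ("substantial", "intermediate", "considerably_less", "essentially_none")


def aic_support(aics) -> pd.DataFrame:
    """Delta-AIC and support label per model.

    Cutpoints: delta <= 2 substantial; 4 <= delta <= 7 considerably less;
    delta > 10 essentially none; the gaps (2, 4) and (7, 10] are labelled
    intermediate.
    """
    aics = np.asarray(list(aics), dtype=float)
    if aics.size < 2:
        raise ValueError("need at least two models")
    delta = aics - aics.min()
    labels = []
    for d in delta:
        if d <= 2.0:
            labels.append("substantial")
        elif 4.0 <= d <= 7.0:
            labels.append("considerably_less")
        elif d > 10.0:
            labels.append("essentially_none")
        else:
            labels.append("intermediate")
    return pd.DataFrame({"aic": aics, "delta_aic": delta, "support": labels})


def compare_models(fits: dict, p_var: int = 2) -> pd.DataFrame:
    """Tabulate lnL, AIC, BIC and support for a dict of VarianceFit results.

    ``p`` counts the estimated variance components (2 for these single-trait
    models), matching the convention in which BIC - AIC = (ln n - 2) p.
    """
    rows = []
    for name, vf in fits.items():
        rows.append(
            {
                "model": name,
                "sigma_u2": vf.sigma_u2,
                "sigma_e2": vf.sigma_e2,
                "h2": vf.h2,
                "loglik": vf.loglik,
                "n": vf.n_records,
                "p": p_var,
                "aic": aic(vf.loglik, p_var),
                "bic": bic(vf.loglik, p_var, vf.n_records),
            }
        )
    out = pd.DataFrame(rows).set_index("model")
    if len(out) >= 2:
        support = aic_support(out["aic"])
        out["delta_aic"] = support["delta_aic"].to_numpy()
        out["support"] = support["support"].to_numpy()
    else:
        out["delta_aic"] = 0.0
        out["support"] = "substantial"
    return out
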