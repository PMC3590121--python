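"""Convergence diagnostics: potential scale reduction and Heidelberger-Welch.

``rhat`` is the classical between/within-chain variance ratio.  The
Heidelberger-Welch diagnostic follows the standard construction: a
Cramér-von Mises test of stationarity on the Brownian bridge of the
chain's cumulative sums, applied to the full chain and then iteratively
with the first 10%, 20%, ... 50% discarded; plus a halfwidth test
comparing the 95% CI halfwidth of the mean against a fraction of the
mean's magnitude.

The spectral density at frequency zero is estimated by batch means
rather than the AR fit some implementations use: an autoregression
absorbs a deterministic trend into a near-unit root and inflates the
denominator until trends pass as stationary, whereas batch means keeps
the Cramér-von Mises statistic sensitive to trends while remaining
calibrated on stationary chains (the AR estimator is still available as
:func:`spectrum0_ar`).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gamma as _gamma
from scipy.special import kv as _besselk


def rhat(chains) -> float | np.ndarray:
    """Potential scale reduction factor.

    Parameters
    ----------
    chains
        Array of shape (n_chains, n_draws) for one parameter, or
        (n_chains, n_draws, n_params) for many.
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim not in (2, 3):
        raise ValueError("chains must be 2-D or 3-D")
    C, K = a.shape[0], a.shape[1]
    if C < 2:
        raise ValueError("rhat requires at least two chains")
    if K < 10:
        raise ValueError("rhat requires at least 10 draws per chain")
    W = a.var(axis=1, ddof=1).mean(axis=0)
    B = a.mean(axis=1).var(axis=0, ddof=1) * K
    var_plus = (K - 1) / K * W + B / K
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    r = np.where((W == 0) & (B == 0), 1.0, r)
    return float(r) if r.ndim == 0 else r


def spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of ``x`` at frequency zero via an AIC-chosen AR fit.

    Returns sigma^2 / (1 - sum(phi))^2 for the selected autoregression.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 values")
    xc = x - x.mean()
    v0 = float(xc @ xc) / n
    if v0 == 0.0:
        return 0.0
    if max_order is None:
        max_order = min(int(10 * math.log10(n)), n // 2 - 1, 30)
    best_aic = n * math.log(v0)
    best = (v0, 0.0)
    for p in range(1, max_order + 1):
        X = np.column_stack([xc[p - k - 1 : n - k - 1] for k in range(p)])
        y = xc[p:]
        phi, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ phi
        s2 = float(resid @ resid) / y.size
        if s2 <= 0:
            continue
        aic = n * math.log(s2) + 2.0 * p
        if aic < best_aic:
            best_aic = aic
            best = (s2, float(phi.sum()))
    s2, phisum = best
    denom = (1.0 - phisum) ** 2
    return s2 / max(denom, 1e-12)


def spectrum0_batch(x: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means estimate of the spectral density at frequency zero.

    Splits the series into ``n_batches`` consecutive batches and returns
    batch_size * var(batch means); consistent for stationary chains with
    correlation length well below the batch size.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * n_batches:
        n_batches = max(n // 2, 2)
    size = n // n_batches
    means = x[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    return float(size * means.var(ddof=1))


def _pcramer(q: float, eps: float = 1e-5) -> float:
    """CDF of the asymptotic Cramér-von Mises distribution at ``q``."""
    if q <= 0:
        return 0.0
    total = 0.0
    for k in range(4):
        u = (4 * k + 1) ** 2 / (16.0 * q)
        if u > -math.log(eps):
            continue
        z = (
            _gamma(k + 0.5)
            * math.sqrt(4 * k + 1)
            / (_gamma(k + 1.0) * math.pi**1.5 * math.sqrt(q))
        )
        total += z * math.exp(-u) * float(_besselk(0.25, u))
    return min(max(total, 0.0), 1.0)


def heidelberger_welch(
    chain, alpha: float = 0.05, eps: float = 0.1
) -> dict:
    """Stationarity and halfwidth tests for a single chain.

    Returns a dict with ``stationarity`` (bool), ``halfwidth`` (bool),
    ``kept_fraction``, the stationarity ``pvalue`` of the retained
    portion, the retained ``mean`` and the CI ``halfwidth_value``.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n < 100:
        raise ValueError("heidelberger_welch requires at least 100 draws")
    if np.ptp(x) == 0.0:
        return {
            "stationarity": True, "halfwidth": True, "kept_fraction": 1.0,
            "pvalue": 1.0, "mean": float(x[0]), "halfwidth_value": 0.0,
        }
    s0 = spectrum0_batch(x[n // 2 :])
    result = None
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        y = x[int(frac * n) :]
        m = y.size
        ybar = y.mean()
        bridge = np.cumsum(y) - np.arange(1, m + 1) * ybar
        stat = float(np.sum(bridge**2)) / (m * m * max(s0, 1e-300))
        pvalue = 1.0 - _pcramer(stat)
        if pvalue > alpha:
            result = (frac, y, pvalue)
            break
    if result is None:
        return {
            "stationarity": False, "halfwidth": False, "kept_fraction": 0.0,
            "pvalue": pvalue, "mean": float("nan"), "halfwidth_value": float("nan"),
        }
    frac, y, pvalue = result
    s0_kept = spectrum0_batch(y)
    halfwidth = 1.96 * math.sqrt(s0_kept / y.size)
    mean = float(y.mean())
    if mean == 0.0:
        hw_pass = halfwidth == 0.0
    else:
        hw_pass = halfwidth / abs(mean) <= eps
    return {
        "stationarity": True,
        "halfwidth": bool(hw_pass),
        "kept_fraction": 1.0 - frac,
        "pvalue": pvalue,
        "mean": mean,
        "halfwidth_value": halfwidth,
    }
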