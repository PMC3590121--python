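"""Posterior predictive checks: replicated datasets and Bayesian p-values.

For each retained posterior draw theta a replicate dataset is simulated
from MVN(mu(theta), Sigma(theta)) at the draw's latent diameters, and
two discrepancy statistics are compared between replicate and observed
data, per trait:

* ``T_mean`` — the trait's column mean, probing whether the model
  captures the central tendency;
* ``T_fit`` — the residual sum of squares Sum_i (y_i - mu_i(theta))^2,
  a sums-of-squares measure of overall fit.

The Bayesian p-value ``P_B`` is the fraction of draws whose replicate
statistic is at least the observed one (ties count as extreme).  Values
near 0 or 1 indicate lack of fit; values near 0.5 are unremarkable.
``r^2`` is the squared Pearson correlation between each observed log
trait and its posterior-mean prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ParameterState, predicted_means
from .preprocess import N_TRAITS, TRAITS, ObservationTable
from .sampler import PosteriorSamples

log = logging.getLogger(__name__)


@dataclass
class PpcResult:
    """Per-trait fit summaries of the posterior predictive check."""

    trait_names: tuple
    r2: np.ndarray
    pb_mean: np.ndarray
    pb_fit: np.ndarray
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        for name in ("pb_mean", "pb_fit"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": list(self.trait_names),
                "r2": self.r2,
                "P_B_mean": self.pb_mean,
                "P_B_fit": self.pb_fit,
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "traits": {
                tr: {
                    "r2": None if np.isnan(self.r2[j]) else float(self.r2[j]),
                    "P_B_mean": float(self.pb_mean[j]),
                    "P_B_fit": float(self.pb_fit[j]),
                }
                for j, tr in enumerate(self.trait_names)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_replicate(
    state_draw: ParameterState, data: ObservationTable, rng: np.random.Generator
) -> np.ndarray:
    """One replicated (n, 4) log-trait matrix from a posterior draw."""
    mu = predicted_means(state_draw, data)
    L = np.linalg.cholesky(state_draw.Sigma)
    z = rng.standard_normal((data.n_obs, N_TRAITS))
    return mu + z @ L.T


def pb_statistics(
    samples: PosteriorSamples,
    data: ObservationTable,
    n_replicates: int = 1000,
    seed: int = 0,
) -> PpcResult:
    """Bayesian p-values and r^2 from one replicate per retained draw.

    Draws are subsampled evenly across the pooled chains down to
    ``n_replicates``.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be at least 100")
    if samples.log_rho is None:
        raise ValueError("posterior samples lack latent diameters (store_latents)")
    rng = np.random.default_rng(seed)
    C, K = samples.n_chains, samples.n_draws
    total = C * K
    n_rep = min(n_replicates, total)
    picks = np.unique(np.linspace(0, total - 1, n_rep).round().astype(int))

    Y = data.log_traits
    t_mean_obs = Y.mean(axis=0)
    t_mean_rep = np.empty((picks.size, N_TRAITS))
    t_fit_obs = np.empty((picks.size, N_TRAITS))
    t_fit_rep = np.empty((picks.size, N_TRAITS))
    mu_sum = np.zeros_like(Y)

    for j, flat in enumerate(picks):
        state = samples.state_at(flat // K, flat % K)
        mu = predicted_means(state, data)
        rep = simulate_replicate(state, data, rng)
        mu_sum += mu
        t_mean_rep[j] = rep.mean(axis=0)
        t_fit_obs[j] = ((Y - mu) ** 2).sum(axis=0)
        t_fit_rep[j] = ((rep - mu) ** 2).sum(axis=0)

    pb_mean = (t_mean_rep >= t_mean_obs).mean(axis=0)
    pb_fit = (t_fit_rep >= t_fit_obs).mean(axis=0)

    mu_bar = mu_sum / picks.size
    r2 = np.empty(N_TRAITS)
    for j in range(N_TRAITS):
        if np.std(Y[:, j]) == 0.0 or np.std(mu_bar[:, j]) == 0.0:
            log.warning(
                "trait %s has zero variance; r^2 undefined", TRAITS[j]
            )
            r2[j] = np.nan
        else:
            r2[j] = np.corrcoef(Y[:, j], mu_bar[:, j])[0, 1] ** 2

    return PpcResult(
        trait_names=tuple(samples.trait_names),
        r2=r2,
        pb_mean=pb_mean,
        pb_fit=pb_fit,
        n_replicates=int(picks.size),
        seed=seed,
    )
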