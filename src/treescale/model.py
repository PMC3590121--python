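"""Joint log-density of the hierarchical errors-in-variables allometry model.

The model relates four log-scale traits (length, aboveground mass, stem
mass, leaf mass) to latent log branch diameter through tree-specific
power laws fitted on the log scale,

    y_i ~ MVN(alpha_{t(i)} + b_{t(i)} * log rho_i, Sigma),

with a Berkson measurement model on observed diameter,

    D_i ~ LogNormal(log rho_i, sigma_rho^2),

and a three-level hierarchy on the regression parameters: tree-level
intercepts/exponents drawn around species-level means, species-level
means drawn around global means, independently per trait and parameter.
Hyperpriors are uniform on bounded intervals; the residual precision
matrix Sigma^{-1} carries a Wishart prior.  The hierarchy is placed on
alpha = log a, i.e. on the intercept of the log-log regression.

All densities here use natural logarithms.  Functions return ``-inf``
for states outside the prior support rather than raising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .preprocess import N_TRAITS, ObservationTable

log = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ModelConfig:
    """Fixed quantities of the model: measurement error and prior supports.

    sigma_rho
        Log-scale SD of diameter measurement error (0.05 ~ 5% relative
        error, applied to every observation).
    alpha_bounds, b_bounds
        Uniform hyperprior supports for the global intercepts A_Y and
        exponents B_Y.
    sd_bounds
        Uniform support shared by all hierarchical standard deviations.
    log_rho_bounds
        Support of the uniform latent log-diameter prior (cm scale).
    wishart_df, wishart_scale
        Degrees of freedom and scale of the Wishart prior on the
        residual precision matrix (df = dimension + 1 is the usual
        low-information choice).
    """

    sigma_rho: float = 0.05
    alpha_bounds: tuple[float, float] = (-20.0, 20.0)
    b_bounds: tuple[float, float] = (-5.0, 5.0)
    sd_bounds: tuple[float, float] = (0.0, 10.0)
    log_rho_bounds: tuple[float, float] = (math.log(0.5), math.log(500.0))
    wishart_df: float = 5.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(N_TRAITS))

    def __post_init__(self) -> None:
        self.wishart_scale = np.asarray(self.wishart_scale, dtype=float)
        if self.sigma_rho < 0:
            raise ValueError("sigma_rho must be non-negative")
        for lo, hi in (self.alpha_bounds, self.b_bounds, self.sd_bounds, self.log_rho_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("prior bounds must be finite with lower < upper")
        if self.wishart_df < N_TRAITS + 1:
            raise ValueError("Wishart df must be at least dimension + 1")
        np.linalg.cholesky(self.wishart_scale)  # must be SPD

    def to_dict(self) -> dict:
        return {
            "sigma_rho": self.sigma_rho,
            "alpha_bounds": list(self.alpha_bounds),
            "b_bounds": list(self.b_bounds),
            "sd_bounds": list(self.sd_bounds),
            "log_rho_bounds": list(self.log_rho_bounds),
            "wishart_df": self.wishart_df,
            "wishart_scale": self.wishart_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("alpha_bounds", "b_bounds", "sd_bounds", "log_rho_bounds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ParameterState:
    """Full parameter vector theta of the hierarchical model.

    Shapes: ``log_rho`` (n,), tree arrays (n_trees, 4), species arrays
    (n_species, 4), global and SD arrays (4,), ``Sigma`` (4, 4).
    ``tree_species`` maps each tree to its species index.
    """

    log_rho: np.ndarray
    tree_alpha: np.ndarray
    tree_b: np.ndarray
    species_alpha: np.ndarray
    species_b: np.ndarray
    global_alpha: np.ndarray
    global_b: np.ndarray
    sd_tree_alpha: np.ndarray
    sd_tree_b: np.ndarray
    sd_species_alpha: np.ndarray
    sd_species_b: np.ndarray
    Sigma: np.ndarray
    tree_species: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "log_rho", "tree_alpha", "tree_b", "species_alpha", "species_b",
            "global_alpha", "global_b", "sd_tree_alpha", "sd_tree_b",
            "sd_species_alpha", "sd_species_b", "Sigma",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.tree_species = np.asarray(self.tree_species, dtype=int)
        if self.Sigma.shape != (N_TRAITS, N_TRAITS):
            raise ValueError("Sigma must be 4x4")
        if self.tree_alpha.shape != self.tree_b.shape:
            raise ValueError("tree parameter shape mismatch")
        if self.tree_alpha.shape[0] != self.tree_species.size:
            raise ValueError("tree_species length mismatch")

    def copy(self) -> "ParameterState":
        return replace(
            self,
            **{
                f: getattr(self, f).copy()
                for f in (
                    "log_rho", "tree_alpha", "tree_b", "species_alpha",
                    "species_b", "global_alpha", "global_b", "sd_tree_alpha",
                    "sd_tree_b", "sd_species_alpha", "sd_species_b", "Sigma",
                    "tree_species",
                )
            },
        )


def _chol(Sigma: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Cholesky factor and log-determinant, or None if not SPD/symmetric."""
    if not np.allclose(Sigma, Sigma.T, rtol=1e-8, atol=1e-12):
        return None
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return None
    return L, 2.0 * float(np.sum(np.log(np.diag(L))))


def predicted_means(state: ParameterState, data: ObservationTable) -> np.ndarray:
    """Model mean mu_i = alpha_{t(i)} + b_{t(i)} * log rho_i, shape (n, 4)."""
    t = data.tree_idx
    return state.tree_alpha[t] + state.tree_b[t] * state.log_rho[:, None]


def log_likelihood(state: ParameterState, data: ObservationTable) -> float:
    """Sum over observations of the MVN log-density of the 4 log traits."""
    cd = _chol(state.Sigma)
    if cd is None:
        log.warning("Sigma not symmetric positive-definite; likelihood = -inf")
        return -np.inf
    L, logdet = cd
    resid = data.log_traits - predicted_means(state, data)
    z = np.linalg.solve(L, resid.T)
    quad = float(np.sum(z * z))
    n = data.n_obs
    return -0.5 * (n * N_TRAITS * _LOG2PI + n * logdet + quad)


def log_measurement(
    state: ParameterState, data: ObservationTable, config: ModelConfig
) -> float:
    """Berkson measurement term plus the uniform latent-diameter prior.

    Sum over observations of ``log LogNormal(D_i | log rho_i, sigma_rho^2)``
    plus the uniform prior log-density of ``log rho_i`` on its support;
    ``-inf`` if any latent falls outside the support.
    """
    lo, hi = config.log_rho_bounds
    lr = state.log_rho
    if np.any(lr < lo) or np.any(lr > hi):
        return -np.inf
    n = data.n_obs
    uniform_term = -n * math.log(hi - lo)
    log_d = np.log(data.diameter)
    s = config.sigma_rho
    if s == 0.0:
        return uniform_term if np.allclose(log_d, lr) else -np.inf
    quad = float(np.sum(((log_d - lr) / s) ** 2))
    lognormal_term = (
        -0.5 * quad - n * (0.5 * _LOG2PI + math.log(s)) - float(np.sum(log_d))
    )
    return lognormal_term + uniform_term


def _normal_sum(values: np.ndarray, means: np.ndarray, sds: np.ndarray) -> float:
    """Sum of scalar normal log-pdfs, columns sharing per-trait SDs.

    A zero SD contributes -inf on any mismatch and 0 on exact equality
    (degenerate point mass).
    """
    sds = np.broadcast_to(sds, values.shape)
    total = 0.0
    zero = sds == 0.0
    if np.any(zero):
        if not np.all(values[zero] == np.broadcast_to(means, values.shape)[zero]):
            return -np.inf
    ok = ~zero
    if np.any(ok):
        m = np.broadcast_to(means, values.shape)[ok]
        z = (values[ok] - m) / sds[ok]
        total = float(-0.5 * np.sum(z * z) - np.sum(np.log(sds[ok])) - 0.5 * ok.sum() * _LOG2PI)
    return total


def log_hierarchy(state: ParameterState) -> float:
    """Gaussian partial-pooling terms for both hierarchy levels.

    Tree parameters around their species means with per-trait tree-level
    SDs, and species parameters around the global means with per-trait
    species-level SDs, independently for intercepts and exponents.
    """
    sp = state.tree_species
    total = 0.0
    for values, means, sds in (
        (state.tree_alpha, state.species_alpha[sp], state.sd_tree_alpha),
        (state.tree_b, state.species_b[sp], state.sd_tree_b),
        (state.species_alpha, state.global_alpha[None, :], state.sd_species_alpha),
        (state.species_b, state.global_b[None, :], state.sd_species_b),
    ):
        term = _normal_sum(values, means, sds)
        if term == -np.inf:
            return -np.inf
        total += term
    return total


def _within(x: np.ndarray, bounds: tuple[float, float]) -> bool:
    return bool(np.all(x >= bounds[0]) and np.all(x <= bounds[1]))


def log_posterior(
    state: ParameterState, data: ObservationTable, config: ModelConfig
) -> float:
    """Unnormalized log-posterior: likelihood + measurement + hierarchy + priors.

    Uniform hyperpriors enter as support indicators; the Wishart prior is
    evaluated on the precision matrix ``Sigma^{-1}`` (the precision is the
    parameter carrying the prior, matching the conjugate Gibbs block).
    """
    if not _within(state.global_alpha, config.alpha_bounds):
        return -np.inf
    if not _within(state.global_b, config.b_bounds):
        return -np.inf
    for sd in (
        state.sd_tree_alpha, state.sd_tree_b,
        state.sd_species_alpha, state.sd_species_b,
    ):
        if not _within(sd, config.sd_bounds):
            return -np.inf
    cd = _chol(state.Sigma)
    if cd is None:
        return -np.inf
    ll = log_likelihood(state, data)
    lm = log_measurement(state, data, config)
    lh = log_hierarchy(state)
    if not np.isfinite(ll + lm + lh):
        return -np.inf
    precision = np.linalg.inv(state.Sigma)
    precision = 0.5 * (precision + precision.T)
    lw = float(
        stats.wishart.logpdf(precision, df=config.wishart_df, scale=config.wishart_scale)
    )
    return ll + lm + lh + lw
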