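"""Metropolis-within-Gibbs sampler for the hierarchical allometry model.

Update blocks per iteration:

1. latent log diameters — vectorized random-walk Metropolis against the
   measurement model, the MVN likelihood and the uniform latent support;
2. each tree's (alpha, b) across the four traits — one joint 8-dim
   conjugate normal draw per tree (the likelihood couples traits through
   the residual precision);
3. species means, then global means — scalar conjugate normal draws
   (the global draw is truncated to its uniform hyperprior support);
4. hierarchical SDs — log-scale random-walk Metropolis with Jacobian;
5. residual precision — conjugate Wishart draw.

Random-walk step sizes adapt toward ~30% acceptance during burn-in only
and are frozen afterwards, preserving ergodicity.  Runs are bit
reproducible from the sampler seed.

``SamplerConfig()`` defaults to the study protocol (3 chains of
1,000,000 iterations, 200,000 burn-in, thinning 10);
``SamplerConfig.desk_scale()`` gives the small-problem settings used
throughout the test-suite (3 x 6,000, burn-in 2,000, thin 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .diagnostics import heidelberger_welch, rhat  # noqa: F401  (module surface)
from .model import ModelConfig, ParameterState, log_posterior
from .preprocess import N_TRAITS, TRAITS, ObservationTable

log = logging.getLogger(__name__)

LEVELS = ("tree", "species", "global")


class SamplerError(RuntimeError):
    """Sampler could not start or produced an invalid state."""


@dataclass
class SamplerConfig:
    n_chains: int = 3
    n_iterations: int = 1_000_000
    burn_in: int = 200_000
    thin: int = 10
    seed: int = 0
    adapt_window: int = 100
    target_accept: float = 0.3
    jitter: float = 0.05
    store_latents: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, **kwargs) -> "SamplerConfig":
        """Small-problem protocol for tests and quick runs."""
        kwargs.setdefault("n_iterations", 6000)
        kwargs.setdefault("burn_in", 2000)
        kwargs.setdefault("thin", 2)
        return cls(seed=seed, **kwargs)

    @property
    def n_kept(self) -> int:
        return math.ceil((self.n_iterations - self.burn_in) / self.thin)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_chains", "n_iterations", "burn_in", "thin", "seed",
                "adapt_window", "target_accept", "jitter", "store_latents",
            )
        }


class _Prep:
    """Index bookkeeping shared by all chains (data is canonical-ordered)."""

    def __init__(self, data: ObservationTable):
        self.data = data
        self.Y = data.log_traits
        self.log_d = np.log(data.diameter)
        self.tidx = data.tree_idx
        self.n = data.n_obs
        self.T = data.n_trees
        self.S = data.n_species
        self.tree_species = data.tree_species
        change = np.flatnonzero(np.diff(self.tidx)) + 1
        self.tree_starts = np.concatenate(([0], change))
        if self.tree_starts.size != self.T:
            raise ValueError("observations are not grouped by tree")
        self.tree_counts = np.diff(np.concatenate((self.tree_starts, [self.n])))
        sp_change = np.flatnonzero(np.diff(self.tree_species)) + 1
        self.sp_tree_starts = np.concatenate(([0], sp_change))
        if self.sp_tree_starts.size != self.S:
            raise ValueError("trees are not grouped by species")
        self.sp_tree_counts = np.diff(
            np.concatenate((self.sp_tree_starts, [self.T]))
        )


def _ols_lines(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait least-squares intercepts and slopes of Y on x."""
    xbar = x.mean()
    ybar = Y.mean(axis=0)
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx < 1e-10:
        return ybar, np.zeros(Y.shape[1])
    b = (x - xbar) @ (Y - ybar) / sxx
    return ybar - b * xbar, b


def initial_state(
    prep: _Prep, mc: ModelConfig, rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> ParameterState:
    """OLS-based starting point: per-tree log-log fits (species or global
    pools for data-poor trees), residual covariance from the pooled fit,
    latents at observed log diameter."""
    x = np.clip(prep.log_d, *mc.log_rho_bounds)
    Y = prep.Y
    ga, gb = _ols_lines(x, Y)
    species_alpha = np.tile(ga, (prep.S, 1))
    species_b = np.tile(gb, (prep.S, 1))
    for s in range(prep.S):
        rows = prep.data.species_idx == s
        if rows.sum() >= 3 and np.ptp(x[rows]) > 1e-6:
            species_alpha[s], species_b[s] = _ols_lines(x[rows], Y[rows])
    tree_alpha = species_alpha[prep.tree_species].copy()
    tree_b = species_b[prep.tree_species].copy()
    for t in range(prep.T):
        lo = prep.tree_starts[t]
        hi = lo + prep.tree_counts[t]
        if prep.tree_counts[t] >= 3 and np.ptp(x[lo:hi]) > 1e-6:
            tree_alpha[t], tree_b[t] = _ols_lines(x[lo:hi], Y[lo:hi])
    resid = Y - tree_alpha[prep.tidx] - tree_b[prep.tidx] * x[:, None]
    Sigma = np.cov(resid.T) + 1e-4 * np.eye(N_TRAITS)

    def _spread(v: np.ndarray) -> np.ndarray:
        s = v.std(axis=0) if v.shape[0] > 1 else np.zeros(v.shape[1])
        return np.clip(s, 0.05, mc.sd_bounds[1] * 0.5)

    state = ParameterState(
        log_rho=x.copy(),
        tree_alpha=tree_alpha,
        tree_b=tree_b,
        species_alpha=species_alpha,
        species_b=species_b,
        global_alpha=np.clip(species_alpha.mean(axis=0), *mc.alpha_bounds),
        global_b=np.clip(species_b.mean(axis=0), *mc.b_bounds),
        sd_tree_alpha=_spread(tree_alpha - species_alpha[prep.tree_species]),
        sd_tree_b=_spread(tree_b - species_b[prep.tree_species]),
        sd_species_alpha=_spread(species_alpha),
        sd_species_b=_spread(species_b),
        Sigma=Sigma,
        tree_species=prep.tree_species.copy(),
    )
    if jitter > 0 and rng is not None:
        for name in ("tree_alpha", "tree_b", "species_alpha", "species_b"):
            arr = getattr(state, name)
            arr += jitter * rng.standard_normal(arr.shape)
        state.global_alpha = np.clip(
            state.global_alpha + jitter * rng.standard_normal(N_TRAITS),
            *mc.alpha_bounds,
        )
        state.global_b = np.clip(
            state.global_b + jitter * rng.standard_normal(N_TRAITS), *mc.b_bounds
        )
    return state


def conjugate_update_precision(
    residuals: np.ndarray,
    prior_df: float,
    prior_scale: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of the residual precision from its conjugate Wishart.

    Posterior is Wishart(prior_df + n, (prior_scale^-1 + R'R)^-1); drawn
    by Bartlett decomposition.  With no residual rows this is a draw from
    the prior.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[1] != N_TRAITS:
        raise ValueError("residuals must be an (n, 4) matrix")
    if not np.all(np.isfinite(R)):
        raise ValueError("residuals must be finite")
    prior_scale = np.asarray(prior_scale, dtype=float)
    try:
        scale_inv = np.linalg.inv(prior_scale)
    except np.linalg.LinAlgError as exc:
        raise ValueError("prior scale matrix is singular") from exc
    n = R.shape[0]
    df = prior_df + n
    post_scale = np.linalg.inv(scale_inv + R.T @ R)
    post_scale = 0.5 * (post_scale + post_scale.T)
    L = np.linalg.cholesky(post_scale)
    p = N_TRAITS
    A = np.zeros((p, p))
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    W = L @ A
    return W @ W.T


class _Chain:
    """One chain's state, step sizes and update blocks."""

    def __init__(
        self,
        prep: _Prep,
        mc: ModelConfig,
        sc: SamplerConfig,
        rng: np.random.Generator,
        init: ParameterState | None = None,
    ):
        self.prep = prep
        self.mc = mc
        self.sc = sc
        self.rng = rng
        self.state = (
            init.copy()
            if init is not None
            else initial_state(prep, mc, rng, jitter=sc.jitter)
        )
        lp = log_posterior(self.state, prep.data, mc)
        if not np.isfinite(lp):
            raise SamplerError(
                "non-finite log-posterior at initial state; "
                f"global_b={self.state.global_b}, Sigma diag={np.diag(self.state.Sigma)}"
            )
        self.Sinv = np.linalg.inv(self.state.Sigma)
        self.step_rho = np.full(prep.n, 0.1)
        self.step_sd_tree = np.full(2 * N_TRAITS, 0.5)
        self.step_sd_species = np.full(2 * N_TRAITS, 0.5)
        self.acc_rho = np.zeros(prep.n)
        self.acc_sd_tree = np.zeros(2 * N_TRAITS)
        self.acc_sd_species = np.zeros(2 * N_TRAITS)
        self.window = 0
        self.post_acc = {"latents": 0.0, "sd_tree": 0.0, "sd_species": 0.0, "iters": 0}

    # -- update blocks -------------------------------------------------

    def update_latents(self) -> None:
        st, prep, rng = self.state, self.prep, self.rng
        r = st.log_rho
        prop = r + self.step_rho * rng.standard_normal(prep.n)
        lo, hi = self.mc.log_rho_bounds
        in_bounds = (prop >= lo) & (prop <= hi)
        s2 = self.mc.sigma_rho**2
        d_meas = ((prep.log_d - r) ** 2 - (prep.log_d - prop) ** 2) / (2.0 * s2)
        a = st.tree_alpha[prep.tidx]
        b = st.tree_b[prep.tidx]
        base = prep.Y - a
        r_old = base - b * r[:, None]
        r_new = base - b * prop[:, None]
        q_old = np.einsum("ij,ij->i", r_old @ self.Sinv, r_old)
        q_new = np.einsum("ij,ij->i", r_new @ self.Sinv, r_new)
        delta = d_meas - 0.5 * (q_new - q_old)
        accept = in_bounds & (np.log(rng.random(prep.n)) < delta)
        r[accept] = prop[accept]
        self.acc_rho += accept

    def update_trees(self) -> None:
        st, prep, rng = self.state, self.prep, self.rng
        x = st.log_rho
        starts = prep.tree_starts
        Sx = np.add.reduceat(x, starts)
        Sxx = np.add.reduceat(x * x, starts)
        SY = np.add.reduceat(prep.Y, starts, axis=0)
        SxY = np.add.reduceat(prep.Y * x[:, None], starts, axis=0)
        nt = prep.tree_counts.astype(float)

        XtX = np.empty((prep.T, 2, 2))
        XtX[:, 0, 0] = nt
        XtX[:, 0, 1] = XtX[:, 1, 0] = Sx
        XtX[:, 1, 1] = Sxx
        # parameter order per tree: (alpha, b) nested within trait
        prec = np.einsum("ab,tij->taibj", self.Sinv, XtX).reshape(prep.T, 8, 8)
        prior_prec = np.empty(8)
        prior_prec[0::2] = 1.0 / st.sd_tree_alpha**2
        prior_prec[1::2] = 1.0 / st.sd_tree_b**2
        prec[:, np.arange(8), np.arange(8)] += prior_prec

        C = np.stack([SY, SxY], axis=1)  # (T, 2, 4)
        eta = (C @ self.Sinv).transpose(0, 2, 1).reshape(prep.T, 8)
        prior_mean = np.empty((prep.T, 8))
        prior_mean[:, 0::2] = st.species_alpha[prep.tree_species]
        prior_mean[:, 1::2] = st.species_b[prep.tree_species]
        eta = eta + prior_prec * prior_mean

        mean = np.linalg.solve(prec, eta[..., None])[..., 0]
        L = np.linalg.cholesky(prec)
        z = rng.standard_normal((prep.T, 8))
        noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[..., None])[..., 0]
        theta = (mean + noise).reshape(prep.T, N_TRAITS, 2)
        st.tree_alpha = np.ascontiguousarray(theta[:, :, 0])
        st.tree_b = np.ascontiguousarray(theta[:, :, 1])

    def update_species(self) -> None:
        st, prep, rng = self.state, self.prep, self.rng
        starts = prep.sp_tree_starts
        ns = prep.sp_tree_counts.astype(float)[:, None]
        for values, sds_tree, sds_sp, glob, attr in (
            (st.tree_alpha, st.sd_tree_alpha, st.sd_species_alpha,
             st.global_alpha, "species_alpha"),
            (st.tree_b, st.sd_tree_b, st.sd_species_b, st.global_b, "species_b"),
        ):
            sums = np.add.reduceat(values, starts, axis=0)
            prec = ns / sds_tree**2 + 1.0 / sds_sp**2
            mean = (sums / sds_tree**2 + glob / sds_sp**2) / prec
            draw = mean + rng.standard_normal(mean.shape) / np.sqrt(prec)
            setattr(st, attr, draw)

    def update_globals(self) -> None:
        st, rng = self.state, self.rng
        S = self.prep.S
        for values, sds, bounds, attr in (
            (st.species_alpha, st.sd_species_alpha, self.mc.alpha_bounds,
             "global_alpha"),
            (st.species_b, st.sd_species_b, self.mc.b_bounds, "global_b"),
        ):
            mu = values.mean(axis=0)
            sd = sds / math.sqrt(S)
            lo = ndtr((bounds[0] - mu) / sd)
            hi = ndtr((bounds[1] - mu) / sd)
            u = lo + (hi - lo) * rng.random(N_TRAITS)
            u = np.clip(u, 1e-12, 1.0 - 1e-12)
            setattr(st, attr, mu + sd * ndtri(u))

    @staticmethod
    def _sd_log_target(sd: np.ndarray, ss: np.ndarray, count: float,
                       hi: float) -> np.ndarray:
        """Log conditional of a hierarchy SD given its Gaussian children.

        Equals the corresponding log_posterior terms up to constants:
        -count*log(sd) - ss/(2 sd^2) on (0, hi], -inf outside.
        """
        out = -count * np.log(sd) - ss / (2.0 * sd**2)
        return np.where((sd > 0) & (sd <= hi), out, -np.inf)

    def _update_sd_group(
        self, values: tuple[np.ndarray, np.ndarray],
        centers: tuple[np.ndarray, np.ndarray],
        attrs: tuple[str, str], steps: np.ndarray, acc: np.ndarray,
    ) -> None:
        st, rng = self.state, self.rng
        hi = self.mc.sd_bounds[1]
        ss = np.concatenate(
            [((v - c) ** 2).sum(axis=0) for v, c in zip(values, centers)]
        )
        count = float(values[0].shape[0])
        cur = np.concatenate([getattr(st, a) for a in attrs])
        prop = cur * np.exp(steps * rng.standard_normal(cur.size))
        delta = (
            self._sd_log_target(prop, ss, count, hi)
            - self._sd_log_target(cur, ss, count, hi)
            + np.log(prop) - np.log(cur)  # log-scale proposal Jacobian
        )
        accept = np.log(rng.random(cur.size)) < delta
        cur[accept] = prop[accept]
        setattr(st, attrs[0], cur[:N_TRAITS].copy())
        setattr(st, attrs[1], cur[N_TRAITS:].copy())
        acc += accept

    def update_sds(self) -> None:
        st, prep = self.state, self.prep
        self._update_sd_group(
            (st.tree_alpha, st.tree_b),
            (st.species_alpha[prep.tree_species], st.species_b[prep.tree_species]),
            ("sd_tree_alpha", "sd_tree_b"),
            self.step_sd_tree, self.acc_sd_tree,
        )
        self._update_sd_group(
            (st.species_alpha, st.species_b),
            (st.global_alpha[None, :], st.global_b[None, :]),
            ("sd_species_alpha", "sd_species_b"),
            self.step_sd_species, self.acc_sd_species,
        )

    def update_sigma(self) -> None:
        st, prep = self.state, self.prep
        resid = (
            prep.Y
            - st.tree_alpha[prep.tidx]
            - st.tree_b[prep.tidx] * st.log_rho[:, None]
        )
        P = conjugate_update_precision(
            resid, self.mc.wishart_df, self.mc.wishart_scale, self.rng
        )
        self.Sinv = P
        st.Sigma = np.linalg.inv(P)

    # -- iteration -----------------------------------------------------

    def iterate(self, adapting: bool) -> None:
        self.update_latents()
        self.update_trees()
        self.update_species()
        self.update_globals()
        self.update_sds()
        self.update_sigma()
        self.window += 1
        if adapting and self.window >= self.sc.adapt_window:
            w = float(self.window)
            for steps, acc in (
                (self.step_rho, self.acc_rho),
                (self.step_sd_tree, self.acc_sd_tree),
                (self.step_sd_species, self.acc_sd_species),
            ):
                rate = acc / w
                steps *= np.exp(np.clip(rate - self.sc.target_accept, -0.5, 0.5))
                np.clip(steps, 1e-4, 10.0, out=steps)
                acc[:] = 0.0
            self.window = 0
        elif not adapting:
            self.post_acc["latents"] += float(self.acc_rho.mean())
            self.post_acc["sd_tree"] += float(self.acc_sd_tree.mean())
            self.post_acc["sd_species"] += float(self.acc_sd_species.mean())
            self.acc_rho[:] = 0.0
            self.acc_sd_tree[:] = 0.0
            self.acc_sd_species[:] = 0.0
            self.post_acc["iters"] += 1


@dataclass
class PosteriorSamples:
    """Kept posterior draws, chains x draws x parameter blocks.

    Every stored column is reachable through :meth:`registry` (hierarchy
    level, trait, parameter kind, unit label), and :meth:`flat` exposes a
    flat (chains, draws, params) view for diagnostics and persistence.
    """

    trait_names: tuple
    species_labels: tuple
    tree_labels: tuple
    tree_species: np.ndarray
    global_alpha: np.ndarray
    global_b: np.ndarray
    species_alpha: np.ndarray
    species_b: np.ndarray
    tree_alpha: np.ndarray
    tree_b: np.ndarray
    sd_tree_alpha: np.ndarray
    sd_tree_b: np.ndarray
    sd_species_alpha: np.ndarray
    sd_species_b: np.ndarray
    Sigma: np.ndarray
    log_rho: np.ndarray | None
    acceptance: dict = field(default_factory=dict)
    sampler_config: dict = field(default_factory=dict)
    model_config: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.global_b.shape[0]

    @property
    def n_draws(self) -> int:
        return self.global_b.shape[1]

    def _trait_index(self, trait: str) -> int:
        if trait not in self.trait_names:
            raise KeyError(f"unknown trait {trait!r}")
        return self.trait_names.index(trait)

    def draws(self, level: str, trait: str, kind: str = "b") -> np.ndarray:
        """Draws of an intercept/exponent: (chains, draws[, units])."""
        if kind not in ("alpha", "b"):
            raise KeyError(f"unknown parameter kind {kind!r}")
        if level not in LEVELS:
            raise KeyError(f"unknown level {level!r}")
        j = self._trait_index(trait)
        arr = getattr(self, f"{level}_{kind}" if level == "global" else f"{level}_{kind}")
        return arr[..., j]

    def unit_labels(self, level: str) -> tuple:
        if level == "global":
            return ("global",)
        if level == "species":
            return tuple(self.species_labels)
        if level == "tree":
            return tuple(self.tree_labels)
        raise KeyError(f"unknown level {level!r}")

    def state_at(self, chain: int, draw: int) -> ParameterState:
        if self.log_rho is None:
            raise ValueError("latent diameters were not stored")
        return ParameterState(
            log_rho=self.log_rho[chain, draw],
            tree_alpha=self.tree_alpha[chain, draw],
            tree_b=self.tree_b[chain, draw],
            species_alpha=self.species_alpha[chain, draw],
            species_b=self.species_b[chain, draw],
            global_alpha=self.global_alpha[chain, draw],
            global_b=self.global_b[chain, draw],
            sd_tree_alpha=self.sd_tree_alpha[chain, draw],
            sd_tree_b=self.sd_tree_b[chain, draw],
            sd_species_alpha=self.sd_species_alpha[chain, draw],
            sd_species_b=self.sd_species_b[chain, draw],
            Sigma=self.Sigma[chain, draw],
            tree_species=self.tree_species,
        )

    def registry(self) -> pd.DataFrame:
        names, levels, traits, kinds, units = [], [], [], [], []

        def add(name, level, trait, kind, unit):
            names.append(name)
            levels.append(level)
            traits.append(trait)
            kinds.append(kind)
            units.append(unit)

        for kind in ("alpha", "b"):
            for j, tr in enumerate(self.trait_names):
                add(f"global_{kind}[{tr}]", "global", tr, kind, "global")
                for s, lab in enumerate(self.species_labels):
                    add(f"species_{kind}[{lab},{tr}]", "species", tr, kind, lab)
                for t, lab in enumerate(self.tree_labels):
                    add(f"tree_{kind}[{lab},{tr}]", "tree", tr, kind, lab)
        for kind in ("sd_tree_alpha", "sd_tree_b", "sd_species_alpha", "sd_species_b"):
            for tr in self.trait_names:
                add(f"{kind}[{tr}]", kind.split("_")[1], tr, "sd", kind)
        for i, ti in enumerate(self.trait_names):
            for j, tj in enumerate(self.trait_names):
                if j >= i:
                    add(f"Sigma[{ti},{tj}]", "residual", f"{ti}/{tj}", "Sigma", "Sigma")
        if self.log_rho is not None:
            for i in range(self.log_rho.shape[2]):
                add(f"log_rho[{i}]", "latent", "diameter", "log_rho", str(i))
        return pd.DataFrame(
            {"name": names, "level": levels, "trait": traits, "kind": kinds,
             "unit": units}
        )

    def flat(self, include_latents: bool = False) -> tuple[list[str], np.ndarray]:
        """Flat (chains, draws, params) array matching :meth:`registry` order."""
        cols, names = [], []
        reg = self.registry()
        for kind in ("alpha", "b"):
            for j, tr in enumerate(self.trait_names):
                cols.append(getattr(self, f"global_{kind}")[..., j])
                cols.extend(
                    getattr(self, f"species_{kind}")[..., s, j]
                    for s in range(len(self.species_labels))
                )
                cols.extend(
                    getattr(self, f"tree_{kind}")[..., t, j]
                    for t in range(len(self.tree_labels))
                )
        for kind in ("sd_tree_alpha", "sd_tree_b", "sd_species_alpha", "sd_species_b"):
            cols.extend(getattr(self, kind)[..., j] for j in range(N_TRAITS))
        for i in range(N_TRAITS):
            for j in range(i, N_TRAITS):
                cols.append(self.Sigma[..., i, j])
        names = list(reg["name"])
        if self.log_rho is not None and include_latents:
            cols.extend(self.log_rho[..., i] for i in range(self.log_rho.shape[2]))
        elif self.log_rho is not None:
            names = [n for n in names if not n.startswith("log_rho[")]
        return names, np.stack(cols, axis=-1)


def run_mcmc(
    data: ObservationTable,
    model_config: ModelConfig | None = None,
    sampler_config: SamplerConfig | None = None,
    initial: ParameterState | None = None,
) -> PosteriorSamples:
    """Draw from the joint posterior; fully reproducible from the seed."""
    if data.n_obs == 0:
        raise ValueError("observation table is empty")
    mc = model_config or ModelConfig()
    sc = sampler_config or SamplerConfig()
    prep = _Prep(data)
    seeds = np.random.SeedSequence(sc.seed).spawn(sc.n_chains)

    K = sc.n_kept
    shape = lambda *tail: np.empty((sc.n_chains, K) + tail)
    out = {
        "global_alpha": shape(N_TRAITS), "global_b": shape(N_TRAITS),
        "species_alpha": shape(prep.S, N_TRAITS), "species_b": shape(prep.S, N_TRAITS),
        "tree_alpha": shape(prep.T, N_TRAITS), "tree_b": shape(prep.T, N_TRAITS),
        "sd_tree_alpha": shape(N_TRAITS), "sd_tree_b": shape(N_TRAITS),
        "sd_species_alpha": shape(N_TRAITS), "sd_species_b": shape(N_TRAITS),
        "Sigma": shape(N_TRAITS, N_TRAITS),
        "log_rho": shape(prep.n) if sc.store_latents else None,
    }
    acceptance = {}

    for c in range(sc.n_chains):
        rng = np.random.default_rng(seeds[c])
        chain = _Chain(prep, mc, sc, rng, init=initial)
        k = 0
        for it in range(sc.n_iterations):
            chain.iterate(adapting=it < sc.burn_in)
            if it >= sc.burn_in and (it - sc.burn_in) % sc.thin == 0:
                st = chain.state
                for name in (
                    "global_alpha", "global_b", "species_alpha", "species_b",
                    "tree_alpha", "tree_b", "sd_tree_alpha", "sd_tree_b",
                    "sd_species_alpha", "sd_species_b", "Sigma",
                ):
                    out[name][c, k] = getattr(st, name)
                if sc.store_latents:
                    out["log_rho"][c, k] = st.log_rho
                k += 1
        iters = max(chain.post_acc["iters"], 1)
        acceptance[f"chain_{c}"] = {
            key: chain.post_acc[key] / iters
            for key in ("latents", "sd_tree", "sd_species")
        }
        log.info("chain %d finished: %s", c, acceptance[f"chain_{c}"])

    return PosteriorSamples(
        trait_names=tuple(TRAITS),
        species_labels=tuple(data.species_labels),
        tree_labels=tuple(data.tree_labels),
        tree_species=prep.tree_species.copy(),
        acceptance=acceptance,
        sampler_config=sc.to_dict(),
        model_config=mc.to_dict(),
        **out,
    )


def summarize_level(
    samples: PosteriorSamples, level: str, trait: str, kind: str = "b"
) -> pd.DataFrame:
    """Posterior mean, median and equal-tailed 95% interval per unit.

    Quantiles are interpolated from the pooled post-burn-in draws of all
    chains; one row per unit at the requested hierarchy level.
    """
    draws = samples.draws(level, trait, kind)  # (C, K[, units])
    pooled = draws.reshape(-1, *draws.shape[2:])
    if pooled.ndim == 1:
        pooled = pooled[:, None]
    qs = np.quantile(pooled, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "unit": list(samples.unit_labels(level)),
            "mean": pooled.mean(axis=0),
            "median": qs[1],
            "q2_5": qs[0],
            "q97_5": qs[2],
        }
    )
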