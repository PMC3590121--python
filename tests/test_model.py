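"""Log-density components against independent textbook formulas."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import multigammaln

import treescale as ts
from treescale.model import (
    ModelConfig,
    ParameterState,
    log_hierarchy,
    log_likelihood,
    log_measurement,
    log_posterior,
)
from treescale.preprocess import ObservationTable

LOG2PI = math.log(2 * math.pi)


def random_instance(seed=0, n=12, T=3, S=2):
    rng = np.random.default_rng(seed)
    tree_species = np.sort(rng.integers(0, S, T))
    tree_species[0] = 0
    tree_species[-1] = S - 1
    tree_idx = np.sort(rng.integers(0, T, n))
    species_idx = tree_species[tree_idx]
    diam = rng.uniform(2.0, 30.0, n)
    table = ObservationTable(
        diameter=diam,
        log_traits=rng.standard_normal((n, 4)),
        species_idx=species_idx,
        tree_idx=tree_idx,
        species_labels=tuple(f"s{i}" for i in range(S)),
        tree_labels=tuple(f"t{i}" for i in range(T)),
        tree_species=tree_species,
    )
    A = rng.standard_normal((4, 4)) * 0.3
    Sigma = A @ A.T + np.eye(4)
    state = ParameterState(
        log_rho=np.log(table.diameter) + 0.02 * rng.standard_normal(n),
        tree_alpha=rng.standard_normal((T, 4)),
        tree_b=rng.standard_normal((T, 4)),
        species_alpha=rng.standard_normal((S, 4)),
        species_b=rng.standard_normal((S, 4)),
        global_alpha=rng.standard_normal(4),
        global_b=rng.standard_normal(4) * 0.5,
        sd_tree_alpha=rng.uniform(0.2, 1.0, 4),
        sd_tree_b=rng.uniform(0.2, 1.0, 4),
        sd_species_alpha=rng.uniform(0.2, 1.0, 4),
        sd_species_b=rng.uniform(0.2, 1.0, 4),
        Sigma=Sigma,
        tree_species=table.tree_species,
    )
    return state, table


class TestLikelihood:
    def test_zero_residual_identity_sigma(self):
        state, table = random_instance(seed=1, n=1, T=1, S=1)
        state.Sigma = np.eye(4)
        mu = state.tree_alpha[0] + state.tree_b[0] * state.log_rho[0]
        table.log_traits[0] = mu
        assert log_likelihood(state, table) == pytest.approx(-2 * LOG2PI)

    def test_doubling_sigma_determinant_term(self):
        state, table = random_instance(seed=1, n=1, T=1, S=1)
        state.Sigma = np.eye(4)
        mu = state.tree_alpha[0] + state.tree_b[0] * state.log_rho[0]
        table.log_traits[0] = mu
        base = log_likelihood(state, table)
        state.Sigma = 2 * np.eye(4)
        assert log_likelihood(state, table) == pytest.approx(base - 2 * math.log(2))

    def test_matches_explicit_mvn_formula(self):
        state, table = random_instance(seed=7)
        mu = state.tree_alpha[table.tree_idx] + state.tree_b[
            table.tree_idx
        ] * state.log_rho[:, None]
        Sinv = np.linalg.inv(state.Sigma)
        _, logdet = np.linalg.slogdet(state.Sigma)
        expected = 0.0
        for i in range(table.n_obs):
            r = table.log_traits[i] - mu[i]
            expected += -0.5 * (4 * LOG2PI + logdet + r @ Sinv @ r)
        assert log_likelihood(state, table) == pytest.approx(expected, rel=1e-9)

    def test_non_spd_sigma(self):
        state, table = random_instance(seed=3)
        state.Sigma = -np.eye(4)
        assert log_likelihood(state, table) == -np.inf

    def test_row_order_invariance(self):
        state, table = random_instance(seed=5)
        cfg = ModelConfig()
        perm = np.random.default_rng(0).permutation(table.n_obs)
        shuffled = ObservationTable(
            diameter=table.diameter[perm],
            log_traits=table.log_traits[perm],
            species_idx=table.species_idx[perm],
            tree_idx=table.tree_idx[perm],
            species_labels=table.species_labels,
            tree_labels=table.tree_labels,
            tree_species=table.tree_species,
        )
        # canonicalization restores grouping; latents follow the same rows
        order = np.lexsort((table.tree_idx[perm], table.species_idx[perm]))
        state2 = state.copy()
        state2.log_rho = state.log_rho[perm][order]
        assert log_posterior(state, table, cfg) == pytest.approx(
            log_posterior(state2, shuffled, cfg), rel=1e-12
        )


class TestMeasurement:
    def test_mode_at_observed_diameter(self):
        state, table = random_instance(seed=2)
        cfg = ModelConfig(sigma_rho=0.05)
        state.log_rho = np.log(table.diameter).copy()
        at_mode = log_measurement(state, table, cfg)
        state.log_rho = state.log_rho + 0.01
        assert at_mode > log_measurement(state, table, cfg)

    def test_outside_support_is_minus_inf(self):
        state, table = random_instance(seed=2)
        cfg = ModelConfig()
        state.log_rho[0] = cfg.log_rho_bounds[1] + 1.0
        assert log_measurement(state, table, cfg) == -np.inf

    def test_matches_lognormal_plus_uniform_pdfs(self):
        state, table = random_instance(seed=8)
        cfg = ModelConfig(sigma_rho=0.07)
        lo, hi = cfg.log_rho_bounds
        expected = sum(
            stats.lognorm.logpdf(d, s=cfg.sigma_rho, scale=math.exp(lr))
            + stats.uniform.logpdf(lr, loc=lo, scale=hi - lo)
            for d, lr in zip(table.diameter, state.log_rho)
        )
        assert log_measurement(state, table, cfg) == pytest.approx(expected, rel=1e-9)


class TestHierarchy:
    def test_centered_unit_sd_contribution(self):
        state, _ = random_instance(seed=4, T=2, S=1)
        state.species_alpha = np.tile(state.global_alpha, (1, 1))
        state.species_b = np.tile(state.global_b, (1, 1))
        state.tree_alpha = state.species_alpha[state.tree_species].copy()
        state.tree_b = state.species_b[state.tree_species].copy()
        for f in ("sd_tree_alpha", "sd_tree_b", "sd_species_alpha", "sd_species_b"):
            setattr(state, f, np.ones(4))
        n_terms = 2 * 4 * 2 + 1 * 4 * 2  # trees x traits x {alpha,b} + species
        assert log_hierarchy(state) == pytest.approx(-0.5 * LOG2PI * n_terms)

    def test_one_sd_displacement_costs_half(self):
        state, _ = random_instance(seed=4, T=2, S=1)
        for f in ("sd_tree_alpha", "sd_tree_b", "sd_species_alpha", "sd_species_b"):
            setattr(state, f, np.ones(4))
        base = log_hierarchy(state)
        state.tree_b[0, 0] += 1.0  # exactly one sd away
        moved = log_hierarchy(state)
        delta_expected = -0.5 * (
            (state.tree_b[0, 0] - state.species_b[state.tree_species[0], 0]) ** 2
            - (state.tree_b[0, 0] - 1.0 - state.species_b[state.tree_species[0], 0]) ** 2
        )
        assert moved - base == pytest.approx(delta_expected, rel=1e-9)

    def test_matches_scalar_normal_pdfs(self):
        state, _ = random_instance(seed=9)
        sp = state.tree_species
        expected = (
            stats.norm.logpdf(state.tree_alpha, state.species_alpha[sp],
                              state.sd_tree_alpha).sum()
            + stats.norm.logpdf(state.tree_b, state.species_b[sp],
                                state.sd_tree_b).sum()
            + stats.norm.logpdf(state.species_alpha, state.global_alpha,
                                state.sd_species_alpha).sum()
            + stats.norm.logpdf(state.species_b, state.global_b,
                                state.sd_species_b).sum()
        )
        assert log_hierarchy(state) == pytest.approx(expected, rel=1e-9)

    def test_zero_sd_mismatch(self):
        state, _ = random_instance(seed=9)
        state.sd_tree_b = np.array([0.0, 1, 1, 1])
        assert log_hierarchy(state) == -np.inf


class TestPosterior:
    def test_out_of_bounds_hyperparameter(self):
        state, table = random_instance(seed=6)
        cfg = ModelConfig()
        state.global_b = np.array([6.0, 0, 0, 0])  # outside [-5, 5]
        assert log_posterior(state, table, cfg) == -np.inf

    def test_additivity_of_components(self):
        state, table = random_instance(seed=6)
        cfg = ModelConfig()
        precision = np.linalg.inv(state.Sigma)
        wishart = stats.wishart.logpdf(precision, df=cfg.wishart_df,
                                       scale=cfg.wishart_scale)
        total = (
            log_likelihood(state, table)
            + log_measurement(state, table, cfg)
            + log_hierarchy(state)
            + wishart
        )
        assert log_posterior(state, table, cfg) == pytest.approx(total, rel=1e-12)

    def test_wishart_term_matches_direct_formula(self):
        # density of Wishart(df=5, I) at a sampled SPD matrix, from scratch
        rng = np.random.default_rng(11)
        A = rng.standard_normal((4, 4)) * 0.4
        X = A @ A.T + np.eye(4)
        df, p = 5.0, 4
        sign, logdetX = np.linalg.slogdet(X)
        expected = (
            (df - p - 1) / 2 * logdetX
            - np.trace(X) / 2
            - df * p / 2 * math.log(2)
            - multigammaln(df / 2, p)
        )
        assert stats.wishart.logpdf(X, df=df, scale=np.eye(4)) == pytest.approx(
            expected, rel=1e-9
        )

    def test_reparameterization_identity(self):
        # shifting latents by c and intercepts by -b*c leaves likelihood fixed
        state, table = random_instance(seed=13)
        c = 0.37
        shifted = state.copy()
        shifted.log_rho = state.log_rho + c
        shifted.tree_alpha = state.tree_alpha - state.tree_b * c
        assert log_likelihood(shifted, table) == pytest.approx(
            log_likelihood(state, table), rel=1e-9
        )

    def test_reduces_to_hierarchical_regression_when_latents_fixed(self):
        # with latents pinned at observed log D, posterior differences equal
        # those of the measurement-free hierarchical regression
        state, table = random_instance(seed=14)
        cfg = ModelConfig(sigma_rho=1e-4)
        s1 = state.copy()
        s1.log_rho = np.log(table.diameter).copy()
        s2 = s1.copy()
        s2.tree_b = s1.tree_b + 0.1
        full_delta = log_posterior(s2, table, cfg) - log_posterior(s1, table, cfg)
        reduced_delta = (
            log_likelihood(s2, table) + log_hierarchy(s2)
            - log_likelihood(s1, table) - log_hierarchy(s1)
        )
        assert full_delta == pytest.approx(reduced_delta, rel=1e-9)
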