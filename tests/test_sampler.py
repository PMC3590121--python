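"""Sampler blocks: conjugacy, detailed balance, determinism, summaries."""

import numpy as np
import pytest

import treescale as ts
from treescale.model import ModelConfig, log_posterior
from treescale.sampler import (
    SamplerConfig,
    SamplerError,
    _Chain,
    _Prep,
    conjugate_update_precision,
    initial_state,
    run_mcmc,
    summarize_level,
)
from conftest import make_toy_samples


@pytest.fixture(scope="module")
def tiny_table():
    cfg = ts.GeneratorConfig(
        n_species=2, trees_per_species=(2, 2), branches_per_tree=(9, 9, 9, 9),
        dry_wet_ratios=(0.5, 0.6), seed=3,
    )
    records, truth = ts.generate_dataset(cfg)
    return ts.to_observation_table(records, truth)


class TestConfig:
    def test_default_protocol_matches_study(self):
        cfg = SamplerConfig()
        assert (cfg.n_chains, cfg.n_iterations, cfg.burn_in, cfg.thin) == (
            3, 1_000_000, 200_000, 10,
        )

    def test_invalid_burn_in(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, burn_in=100)


class TestDeterminism:
    def test_same_seed_bit_identical(self, tiny_table):
        sc = SamplerConfig.desk_scale(seed=5, n_iterations=400, burn_in=100)
        s1 = run_mcmc(tiny_table, sampler_config=sc)
        s2 = run_mcmc(tiny_table, sampler_config=sc)
        np.testing.assert_array_equal(s1.global_b, s2.global_b)
        np.testing.assert_array_equal(s1.Sigma, s2.Sigma)
        np.testing.assert_array_equal(s1.log_rho, s2.log_rho)

    def test_relabelled_species_same_draws(self, tiny_table):
        relabelled = ts.ObservationTable(
            diameter=tiny_table.diameter,
            log_traits=tiny_table.log_traits,
            species_idx=tiny_table.species_idx,
            tree_idx=tiny_table.tree_idx,
            species_labels=("north", "south"),
            tree_labels=tiny_table.tree_labels,
            tree_species=tiny_table.tree_species,
        )
        sc = SamplerConfig.desk_scale(seed=5, n_iterations=300, burn_in=100)
        s1 = run_mcmc(tiny_table, sampler_config=sc)
        s2 = run_mcmc(relabelled, sampler_config=sc)
        np.testing.assert_array_equal(s1.species_b, s2.species_b)
        np.testing.assert_array_equal(s1.global_b, s2.global_b)
        assert s2.species_labels == ("north", "south")


class TestConjugateBlocks:
    def test_tree_block_matches_closed_form(self, tiny_table):
        """Repeated draws of one tree's (alpha, b) given everything else
        match the analytic conjugate-normal conditional."""
        mc = ModelConfig()
        prep = _Prep(tiny_table)
        rng = np.random.default_rng(0)
        chain = _Chain(prep, mc, SamplerConfig.desk_scale(seed=0), rng)
        st = chain.state
        draws = []
        for _ in range(4000):
            chain.update_trees()
            draws.append((st.tree_alpha[0].copy(), st.tree_b[0].copy()))
        alpha_draws = np.array([d[0] for d in draws])
        b_draws = np.array([d[1] for d in draws])

        # closed form for tree 0
        lo = prep.tree_starts[0]
        hi = lo + prep.tree_counts[0]
        x = st.log_rho[lo:hi]
        Y = prep.Y[lo:hi]
        X = np.column_stack([np.ones_like(x), x])
        Sinv = chain.Sinv
        prec = np.kron(Sinv, X.T @ X)
        prior_prec = np.zeros(8)
        prior_prec[0::2] = 1 / st.sd_tree_alpha**2
        prior_prec[1::2] = 1 / st.sd_tree_b**2
        prec[np.arange(8), np.arange(8)] += prior_prec
        prior_mean = np.empty(8)
        sp = prep.tree_species[0]
        prior_mean[0::2] = st.species_alpha[sp]
        prior_mean[1::2] = st.species_b[sp]
        eta = (X.T @ Y @ Sinv).T.ravel() + prior_prec * prior_mean
        mean = np.linalg.solve(prec, eta)
        mcse = np.sqrt(np.diag(np.linalg.inv(prec)) / len(draws))
        emp = np.empty(8)
        emp[0::2] = alpha_draws.mean(axis=0)
        emp[1::2] = b_draws.mean(axis=0)
        assert np.all(np.abs(emp - mean) < 4 * mcse + 1e-12)

    def test_precision_prior_draw_moments(self):
        rng = np.random.default_rng(1)
        scale = np.diag([1.0, 2.0, 0.5, 1.5])
        draws = np.array([
            conjugate_update_precision(np.empty((0, 4)), 5.0, scale, rng)
            for _ in range(4000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), 5.0 * scale, rtol=0.1,
                                   atol=0.15)

    def test_precision_draw_always_spd(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            R = rng.standard_normal((rng.integers(0, 30), 4))
            P = conjugate_update_precision(R, 5.0, np.eye(4), rng)
            np.testing.assert_allclose(P, P.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(P) > 0)

    def test_singular_scale_rejected(self):
        with pytest.raises(ValueError):
            conjugate_update_precision(
                np.empty((0, 4)), 5.0, np.zeros((4, 4)), np.random.default_rng(0)
            )


class TestDetailedBalance:
    def test_sd_target_matches_log_posterior_difference(self, tiny_table):
        mc = ModelConfig()
        prep = _Prep(tiny_table)
        chain = _Chain(prep, mc, SamplerConfig.desk_scale(seed=1),
                       np.random.default_rng(1))
        st = chain.state
        ss = ((st.tree_b - st.species_b[prep.tree_species]) ** 2).sum(axis=0)
        s2 = st.copy()
        s2.sd_tree_b = st.sd_tree_b * 1.3
        lp_delta = log_posterior(s2, tiny_table, mc) - log_posterior(
            st, tiny_table, mc
        )
        target_delta = (
            chain._sd_log_target(s2.sd_tree_b, ss, prep.T, mc.sd_bounds[1])
            - chain._sd_log_target(st.sd_tree_b, ss, prep.T, mc.sd_bounds[1])
        ).sum()
        assert lp_delta == pytest.approx(target_delta, rel=1e-9)

    def test_latent_target_matches_log_posterior_difference(self, tiny_table):
        mc = ModelConfig()
        prep = _Prep(tiny_table)
        chain = _Chain(prep, mc, SamplerConfig.desk_scale(seed=1),
                       np.random.default_rng(1))
        st = chain.state
        s2 = st.copy()
        s2.log_rho = st.log_rho + 0.01
        lp_delta = log_posterior(s2, tiny_table, mc) - log_posterior(
            st, tiny_table, mc
        )
        s_meas = mc.sigma_rho**2
        d_meas = (
            (prep.log_d - st.log_rho) ** 2 - (prep.log_d - s2.log_rho) ** 2
        ).sum() / (2 * s_meas)
        a = st.tree_alpha[prep.tidx]
        b = st.tree_b[prep.tidx]
        r_old = prep.Y - a - b * st.log_rho[:, None]
        r_new = prep.Y - a - b * s2.log_rho[:, None]
        d_lik = -0.5 * (
            np.einsum("ij,ij->", r_new @ chain.Sinv, r_new)
            - np.einsum("ij,ij->", r_old @ chain.Sinv, r_old)
        )
        assert lp_delta == pytest.approx(d_meas + d_lik, rel=1e-9)


class TestRunMcmc:
    def test_empty_data_rejected(self):
        empty = ts.ObservationTable(
            diameter=np.empty(0),
            log_traits=np.empty((0, 4)),
            species_idx=np.empty(0, dtype=int),
            tree_idx=np.empty(0, dtype=int),
            species_labels=(),
            tree_labels=(),
            tree_species=np.empty(0, dtype=int),
        )
        with pytest.raises(ValueError, match="empty"):
            run_mcmc(empty)

    def test_nonfinite_initial_state_raises(self, tiny_table):
        bad = initial_state(_Prep(tiny_table), ModelConfig())
        bad.Sigma = -np.eye(4)
        with pytest.raises(SamplerError, match="non-finite"):
            run_mcmc(
                tiny_table,
                sampler_config=SamplerConfig.desk_scale(seed=0, n_iterations=50,
                                                        burn_in=10),
                initial=bad,
            )

    def test_kept_draw_count(self, tiny_table):
        sc = SamplerConfig.desk_scale(seed=2, n_iterations=500, burn_in=100,
                                      thin=3)
        s = run_mcmc(tiny_table, sampler_config=sc)
        assert s.n_draws == sc.n_kept == 134
        assert np.all(np.isfinite(s.global_b))


class TestSummaries:
    def test_constant_draws(self):
        samples = make_toy_samples(global_b=np.full((2, 200, 4), 1.7))
        s = summarize_level(samples, "global", "length")
        row = s.iloc[0]
        for col in ("mean", "median", "q2_5", "q97_5"):
            assert row[col] == pytest.approx(1.7, rel=1e-12)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        samples = make_toy_samples(
            global_b=rng.standard_normal((2, 50_000, 4)), n_draws=50_000
        )
        s = summarize_level(samples, "global", "ag_mass").iloc[0]
        assert abs(s["q2_5"] + 1.96) < 0.03
        assert abs(s["q97_5"] - 1.96) < 0.03
        assert abs(s["mean"] - s["median"]) < 0.02

    def test_unknown_level_or_trait(self, short_fit):
        with pytest.raises(KeyError):
            summarize_level(short_fit, "forest", "length")
        with pytest.raises(KeyError):
            summarize_level(short_fit, "global", "bark")

    def test_bounds_ordered_everywhere(self, short_fit):
        for level in ("tree", "species", "global"):
            s = summarize_level(short_fit, level, "stem_mass")
            assert np.all(s["q2_5"] <= s["median"])
            assert np.all(s["median"] <= s["q97_5"])

    def test_registry_covers_flat_columns(self, short_fit):
        names, arr = short_fit.flat()
        reg = short_fit.registry()
        assert arr.shape[-1] == len(names)
        assert set(names) <= set(reg["name"])
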