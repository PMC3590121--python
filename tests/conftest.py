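import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import treescale as ts
from treescale.sampler import SamplerConfig, run_mcmc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_data():
    """Study-design simulation: records, truth and exact observation table."""
    records, truth = ts.study_fixture(seed=0)
    table = ts.to_observation_table(records, truth)
    return records, truth, table


@pytest.fixture(scope="session")
def short_fit(fixture_data):
    """A quick but real fit of the study fixture, shared across tests."""
    _, _, table = fixture_data
    cfg = SamplerConfig.desk_scale(seed=11, n_iterations=1500, burn_in=500)
    return run_mcmc(table, sampler_config=cfg)


def make_toy_samples(
    global_b=None,
    species_b=None,
    n_chains=2,
    n_draws=200,
    species_labels=("spA", "spB", "spC"),
    tree_labels=("t0", "t1"),
    seed=0,
):
    """Minimal PosteriorSamples with given draws, zeros elsewhere."""
    from treescale.preprocess import N_TRAITS
    from treescale.sampler import PosteriorSamples

    rng = np.random.default_rng(seed)
    C, K = n_chains, n_draws
    S, T = len(species_labels), len(tree_labels)
    if global_b is None:
        global_b = rng.standard_normal((C, K, N_TRAITS))
    if species_b is None:
        species_b = rng.standard_normal((C, K, S, N_TRAITS))
    eye = np.broadcast_to(np.eye(N_TRAITS), (C, K, N_TRAITS, N_TRAITS)).copy()
    z = lambda *tail: np.zeros((C, K) + tail)
    return PosteriorSamples(
        trait_names=ts.TRAITS,
        species_labels=tuple(species_labels),
        tree_labels=tuple(tree_labels),
        tree_species=np.zeros(T, dtype=int),
        global_alpha=z(N_TRAITS),
        global_b=np.asarray(global_b, dtype=float),
        species_alpha=z(S, N_TRAITS),
        species_b=np.asarray(species_b, dtype=float),
        tree_alpha=z(T, N_TRAITS),
        tree_b=z(T, N_TRAITS),
        sd_tree_alpha=z(N_TRAITS) + 1,
        sd_tree_b=z(N_TRAITS) + 1,
        sd_species_alpha=z(N_TRAITS) + 1,
        sd_species_b=z(N_TRAITS) + 1,
        Sigma=eye,
        log_rho=None,
    )
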