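"""Shared fixtures: a small seeded simulation used across module tests."""

import numpy as np
import pytest

from divscan import synthetic_data as sd

SMALL_SEED = 20260925


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    """Two 3 Mb contigs, the full 11-population layout, one 1 Mb sweep."""
    return sd.default_config(
        SMALL_SEED,
        contigs=[("chr1", 3_000_000), ("chr2", 3_000_000)],
        sweep_regions=[("chr1", 600_000, 1_600_000)],
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(table, truth, tracks, popmap) for the small seeded simulation."""
    freqs = sd.simulate_frequencies(small_config)
    tracks = sd.simulate_depth_tracks(small_config)
    table, truth = sd.simulate_genotypes(freqs, small_config, tracks)
    return table, truth, tracks, small_config.population_map()


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """A tiny on-disk bundle (2 x 200 kb) for I/O round-trip tests."""
    cfg = sd.default_config(
        7, contigs=[("chr1", 200_000), ("chr2", 200_000)],
        sweep_regions=[("chr1", 50_000, 150_000)])
    outdir = tmp_path_factory.mktemp("bundle")
    return sd.emit_fixture_bundle(cfg, outdir), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(SMALL_SEED)
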