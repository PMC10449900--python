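"""Shared fixtures: a small but fully featured simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from dropwgs.config import RunConfig, SimConfig, stage_rng
from dropwgs.sim import simulate_genome


def small_sim_config(seed: int = 11, **overrides) -> SimConfig:
    """A fast study configuration exercising every feature."""
    defaults = dict(
        seed=seed,
        genome_length=300_000,
        mito_length=5_000,
        n_tr_loci=12,
        germline_snv_rate=5e-4,
        sv_counts={"DEL": 6, "INS": 6, "DUP": 2, "INV": 2},
        somatic_snvs_per_clone=8,
        n_droplets=2_000,
        mito_copies_per_cell=5,
        fp_sv_rates={"INV": 4.0, "INS": 0.5, "DUP": 0.3, "DEL": 0.2},
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def run_config(tmp_path, sim_config) -> RunConfig:
    return RunConfig(
        seed=sim_config.seed,
        outdir=str(tmp_path / "out"),
        sim=sim_config,
        reads_per_cell=60,
        mito_depth=60.0,
    )


@pytest.fixture(scope="session")
def amplified(sim_config, genome):
    """Fragments and amplicons for one cell (dMDA mode)."""
    from dropwgs.sim import amplify, fragment_and_encapsulate
    from dropwgs.sim.encapsulate import cell_rng

    cell = "cell_A1"
    frags = fragment_and_encapsulate(genome, cell, sim_config)
    amps = amplify(frags, sim_config, cell_rng(sim_config, "amplify", cell))
    return cell, frags, amps


def binom_ci(p: float, n: int, z: float = 1.96) -> float:
    """Half-width of the normal-approximation binomial CI."""
    return z * np.sqrt(p * (1.0 - p) / n)


def seeded(seed: int, *key: int) -> np.random.Generator:
    """Independent child generator for test-local randomness."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


__all__ = ["small_sim_config", "binom_ci", "seeded", "stage_rng"]
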