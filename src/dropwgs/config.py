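"""Configuration objects for the simulator and the pipeline.

A single master seed drives everything; each stage derives its own child
generator through :func:`stage_rng` so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

# fixed offsets for per-stage child seeds
STAGE_KEYS = {
    "genome": 1,
    "fragment": 2,
    "amplify": 3,
    "reads": 4,
    "callsets": 5,
    "pileups": 6,
    "downsample": 7,
}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage], index))
    )


@dataclass
class GainModel:
    mode: str = "dmda"  # "mda" | "dmda"
    mean_copies: float = 10.0
    mda_log_sigma: float = 2.0
    dmda_log_sigma: float = 0.5
    dmda_cap_copies: int = 20

    def validate(self) -> None:
        if self.mode not in ("mda", "dmda"):
            raise ValueError(f"gain mode must be mda|dmda, got {self.mode!r}")
        if self.dmda_cap_copies < 1:
            raise ValueError("dmda_cap_copies must be >= 1")
        if self.mean_copies <= 0 or self.mda_log_sigma < 0 or self.dmda_log_sigma < 0:
            raise ValueError("gain parameters must be positive")


@dataclass
class ChimeraRates:
    inversion_per_amplicon: float = 0.20
    duplication_per_amplicon: float = 0.10
    intermolecular_per_droplet: float = 0.02
    inv_min_arm: int = 0  # minimum fold-back arm length (bp)
    dup_min_len: int = 200  # tandem-duplication window bounds (bp)
    dup_max_len: int = 2000

    def validate(self) -> None:
        for name in (
            "inversion_per_amplicon",
            "duplication_per_amplicon",
            "intermolecular_per_droplet",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"chimera rate {name}={v} outside [0, 1]")
        if not 0 < self.dup_min_len <= self.dup_max_len:
            raise ValueError("duplication window bounds must satisfy 0 < min <= max")


@dataclass
class SimConfig:
    """Study conditions of the synthetic dMDA/MDA experiment.

    Defaults reproduce the experimental design being emulated: a 10 Mb
    diploid nuclear genome plus a 16.5 kb circular mitochondrial contig, two
    T-cell-like clones differing by a set of somatic SNVs and one
    heteroplasmic mitochondrial site, ~9 kb fragments encapsulated in 50,000
    droplets, HiFi-grade reads at 1% error, and call sets with heavy allelic
    dropout.
    """

    seed: int = 0
    genome_length: int = 10_000_000
    mito_length: int = 16_500
    n_tr_loci: int = 100
    tr_unit_sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    germline_snv_rate: float = 1e-3
    sv_counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 40, "INS": 40, "DUP": 10, "INV": 10}
    )
    # per-type mixture of event-length modes: ALU-like ~300 bp, LINE-like ~6 kb
    sv_alu_fraction: float = 0.7
    sv_alu_length: tuple[float, float] = (300.0, 20.0)  # (mode, sd)
    sv_line_length: tuple[float, float] = (6000.0, 300.0)
    somatic_snvs_per_clone: int = 30
    heteroplasmy_frequency: float = 0.5  # alternate-allele fraction in clone B
    fragment_length_mean: float = 9000.0
    fragment_length_sd: float = 1500.0
    min_fragment_length: int = 500
    n_droplets: int = 50_000
    mito_copies_per_cell: int = 50
    gain_model: GainModel = field(default_factory=GainModel)
    chimera_rates: ChimeraRates = field(default_factory=ChimeraRates)
    read_error_rate: float = 0.01
    read_qv: int = 20
    dropout_rate: float = 0.8
    fp_snv_rate: float = 3.26e-5  # Poisson intensity per reference base
    # expected false-SV count per cell per type (inversion-dominated)
    fp_sv_rates: dict[str, float] = field(
        default_factory=lambda: {"INV": 16.3, "INS": 1.8, "DUP": 1.0, "DEL": 0.92}
    )
    fp_sv_precise_prob: float = 0.2
    true_sv_precise_prob: float = 0.9
    cells_per_clone: int = 3
    clones: tuple[str, ...] = ("A", "B")

    def validate(self) -> None:
        rates = {
            "germline_snv_rate": self.germline_snv_rate,
            "heteroplasmy_frequency": self.heteroplasmy_frequency,
            "read_error_rate": self.read_error_rate,
            "dropout_rate": self.dropout_rate,
            "sv_alu_fraction": self.sv_alu_fraction,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.heteroplasmy_frequency < 1.0:
            raise ValueError("heteroplasmy_frequency must lie in (0, 1)")
        counts = {
            "genome_length": self.genome_length,
            "mito_length": self.mito_length,
            "n_tr_loci": self.n_tr_loci,
            "somatic_snvs_per_clone": self.somatic_snvs_per_clone,
            "n_droplets": self.n_droplets,
            "cells_per_clone": self.cells_per_clone,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for t, c in self.sv_counts.items():
            if t not in ("DEL", "INS", "DUP", "INV"):
                raise ValueError(f"unknown SV type {t!r} in sv_counts")
            if c < 0:
                raise ValueError(f"sv_counts[{t}] must be >= 0")
        for t, r in self.fp_sv_rates.items():
            if r < 0:
                raise ValueError(f"fp_sv_rates[{t}] must be >= 0")
        if self.fp_snv_rate < 0:
            raise ValueError("fp_snv_rate must be >= 0")
        if any(not 1 <= u <= 10 for u in self.tr_unit_sizes):
            raise ValueError("tr_unit_sizes must lie in 1..10")
        self.gain_model.validate()
        self.chimera_rates.validate()

    @property
    def cell_ids(self) -> list[str]:
        return [
            f"cell_{clone}{i + 1}"
            for clone in self.clones
            for i in range(self.cells_per_clone)
        ]

    def clone_of(self, cell_id: str) -> str:
        for clone in self.clones:
            if cell_id.startswith(f"cell_{clone}"):
                return clone
        raise KeyError(f"cell id {cell_id!r} does not map to a clone")


# ---------------------------------------------------------------------------
# pipeline run configuration (YAML)
# ---------------------------------------------------------------------------

_NESTED = {"gain_model": GainModel, "chimera_rates": ChimeraRates}


def _coerce(dc_type: type, raw: dict[str, Any], context: str):
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in fields:
            raise ValueError(f"unknown key {context}{key}")
        f = fields[key]
        if key in _NESTED:
            if not isinstance(value, dict):
                raise TypeError(f"{context}{key} must be a mapping")
            value = _coerce(_NESTED[key], value, f"{context}{key}.")
        elif f.type.startswith("tuple"):
            value = tuple(value)
        elif f.type in ("int", "float") and not isinstance(value, (int, float)):
            raise TypeError(f"{context}{key} must be numeric, got {type(value).__name__}")
        elif f.type == "int":
            if isinstance(value, float) and not value.is_integer():
                raise TypeError(f"{context}{key} must be an integer")
            value = int(value)
        kwargs[key] = value
    return dc_type(**kwargs)


@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    seed: int = 0
    outdir: str = "dropwgs_out"
    stages: tuple[str, ...] = (
        "simulate",
        "filter-chimeras",
        "coverage",
        "eval-snv",
        "eval-sv",
        "somatic-snv",
        "somatic-sv",
        "heteroplasmy",
        "genotype-tr",
    )
    sim: SimConfig = field(default_factory=SimConfig)
    min_identity: float = 0.90
    min_hit_len: int = 100
    kmer_size: int = 15
    bin_size: int = 5000
    high_cov_threshold: float = 200.0
    sv_max_dist: int = 200
    sv_min_overlap: float = 0.10
    het_min_cov: int = 10
    het_min_freq: float = 0.30
    het_background: float = 0.05
    tr_flank: int = 100
    tr_tolerance: int = 0
    reads_per_cell: int = 500
    mito_depth: float = 100.0
    tr_bulk_cov: float = 30.0
    tr_cell_cov: float = 20.0
    tr_allele_dropout: float = 0.3


def parse_run_config(text: str) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys rejected."""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise TypeError("run config must be a YAML mapping")
    if "sim" in raw:
        raw = dict(raw)
        raw["sim"] = _coerce(SimConfig, dict(raw["sim"]), "sim.")
    cfg = _coerce(RunConfig, raw, "")
    if isinstance(cfg.sim, dict):  # pragma: no cover - defensive
        cfg.sim = _coerce(SimConfig, cfg.sim, "sim.")
    cfg.sim.seed = cfg.sim.seed or cfg.seed
    cfg.sim.validate()
    return cfg


def dump_run_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(_to_plain(dataclasses.asdict(cfg)), sort_keys=True)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj
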