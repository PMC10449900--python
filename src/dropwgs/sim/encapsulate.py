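"""Fragmentation of single-cell DNA and droplet encapsulation.

Each haplotype is cut into fragments whose lengths follow a truncated normal
distribution (~9 kb); in droplet mode every fragment is independently thrown
into one of ~50,000 droplets, so most occupied droplets hold a single
molecule. Mitochondrial molecules are fragmented per copy from a random
origin rotation; fragments spanning the origin wrap (end > contig length).
"""

from __future__ import annotations

import zlib

import numpy as np

from dropwgs.config import SimConfig, stage_rng
from dropwgs.models import Fragment
from dropwgs.sim.genome import MITO, NUCLEAR, SimGenome


def cell_rng(config: SimConfig, stage: str, cell_id: str) -> np.random.Generator:
    return stage_rng(config.seed, stage, zlib.crc32(cell_id.encode()) & 0x7FFFFFFF)


def _cut_lengths(rng, total: int, mean: float, sd: float, minlen: int) -> np.ndarray:
    """Fragment lengths that tile ``total`` exactly (no gaps, no overlaps)."""
    if total <= 0:
        return np.zeros(0, dtype=np.int64)
    n_guess = max(8, int(total / mean * 2) + 8)
    lengths: list[int] = []
    acc = 0
    while acc < total:
        draw = np.maximum(
            np.round(rng.normal(mean, sd, size=n_guess)).astype(np.int64), minlen
        )
        for ln in draw.tolist():
            lengths.append(ln)
            acc += ln
            if acc >= total:
                break
    lengths[-1] -= acc - total  # trim the final fragment to fit
    if lengths[-1] <= 0:
        prev = lengths.pop(-2) if len(lengths) > 1 else 0
        lengths[-1] += prev
    return np.asarray(lengths, dtype=np.int64)


def fragment_and_encapsulate(
    genome: SimGenome,
    cell_id: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Fragment both haplotypes (plus mitochondrial copies) of one cell and
    assign droplets (``gain_model.mode == 'dmda'``) or none (bulk-tube MDA)."""
    clone = config.clone_of(cell_id)
    rng = rng or cell_rng(config, "fragment", cell_id)
    droplets = config.gain_model.mode == "dmda"
    fragments: list[Fragment] = []

    for hap in ("1", "2"):
        hap_len = len(genome.haplotype(NUCLEAR, hap, clone).seq)
        start = 0
        for ln in _cut_lengths(
            rng, hap_len, config.fragment_length_mean,
            config.fragment_length_sd, config.min_fragment_length,
        ).tolist():
            fragments.append(Fragment(cell_id, NUCLEAR, start, start + ln, hap))
            start += ln

    mito_len = len(genome.contigs.get(MITO, ""))
    if mito_len:
        freq = 0.0
        if genome.heteroplasmy_site and genome.heteroplasmy_site[5] == clone:
            freq = genome.heteroplasmy_site[4]
        for _ in range(config.mito_copies_per_cell):
            has_alt = bool(rng.random() < freq)
            rot = int(rng.integers(0, mito_len))
            start = rot
            for ln in _cut_lengths(
                rng, mito_len, config.fragment_length_mean,
                config.fragment_length_sd, config.min_fragment_length,
            ).tolist():
                s = start % mito_len
                fragments.append(
                    Fragment(cell_id, MITO, s, s + ln, "mito", mito_alt=has_alt)
                )
                start += ln

    if droplets:
        ids = rng.integers(0, config.n_droplets, size=len(fragments))
        for frag, d in zip(fragments, ids.tolist()):
            frag.droplet_id = d
    return fragments
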