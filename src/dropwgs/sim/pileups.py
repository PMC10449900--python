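"""Mitochondrial pileup simulation for heteroplasmy analysis.

Pileups are base-count matrices (positions x ACGT). Depth is Poisson per
position; substitution errors scatter reads over the three non-reference
bases; cells of the clone carrying the heteroplasmic site draw alternate
reads binomially at the configured frequency. The bulk sample never carries
the heteroplasmic allele (clonal origin only).
"""

from __future__ import annotations

import numpy as np

from dropwgs.config import SimConfig
from dropwgs.sim.genome import MITO, SimGenome

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


def simulate_mito_pileups(
    genome: SimGenome,
    config: SimConfig,
    rng: np.random.Generator,
    mean_depth: float = 100.0,
    samples: list[str] | None = None,
) -> dict[str, np.ndarray]:
    seq = genome.contigs[MITO]
    L = len(seq)
    ref_idx = np.array([_IDX[b] for b in seq], dtype=np.int64)
    e_sub = 0.8 * config.read_error_rate  # substitution share of the error rate
    het = genome.heteroplasmy_site
    if samples is None:
        samples = ["bulk"] + config.cell_ids

    pileups: dict[str, np.ndarray] = {}
    for sample in samples:
        depth = rng.poisson(mean_depth, size=L)
        counts = np.zeros((L, 4), dtype=np.int64)
        err = rng.binomial(depth, e_sub)
        counts[np.arange(L), ref_idx] = depth - err
        # split errors over the three non-reference bases
        a = rng.binomial(err, 1.0 / 3.0)
        b = rng.binomial(err - a, 0.5)
        c = err - a - b
        others = np.array(
            [[j for j in range(4) if j != r] for r in range(4)], dtype=np.int64
        )[ref_idx]
        rows = np.arange(L)
        counts[rows, others[:, 0]] += a
        counts[rows, others[:, 1]] += b
        counts[rows, others[:, 2]] += c

        if het is not None and sample != "bulk":
            _, pos, ref, alt, freq, clone = het
            if config.clone_of(sample) == clone:
                d = int(depth[pos])
                n_alt = int(rng.binomial(d, freq))
                counts[pos] = 0
                counts[pos, _IDX[alt]] = n_alt
                counts[pos, _IDX[ref]] = d - n_alt
        pileups[sample] = counts
    return pileups
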