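"""Per-locus tandem-repeat read support, sampled from the planted truth.

Rather than realizing and re-aligning full reads at every repeat locus, the
simulator draws the quantity the genotyper consumes directly: per-read
signed length differences. Each spanning read picks one haplotype allele;
whole alleles drop out with probability ``allele_dropout`` (amplification
dropout); a small fraction of reads carry an off-by-one-unit measurement
error, forming the noise clusters the confidence filter screens.
"""

from __future__ import annotations

import numpy as np

from dropwgs.config import SimConfig
from dropwgs.sim.genome import SimGenome


def simulate_tr_read_diffs(
    genome: SimGenome,
    config: SimConfig,
    rng: np.random.Generator,
    mean_cov: float = 25.0,
    allele_dropout: float = 0.0,
    noise_rate: float = 0.02,
    extra_cov: float = 0.0,
) -> dict[str, tuple[list[int], int]]:
    """Map locus name -> (per-read length differences, total coverage).

    ``extra_cov`` adds non-spanning reads to the total coverage only.
    """
    out: dict[str, tuple[list[int], int]] = {}
    for locus in genome.tr_loci:
        alleles = [d for d in locus.hap_diffs if rng.random() >= allele_dropout]
        n = int(rng.poisson(mean_cov))
        diffs: list[int] = []
        if alleles:
            picks = rng.integers(0, len(alleles), size=n)
            for p in picks.tolist():
                d = alleles[p]
                if rng.random() < noise_rate:
                    d += int(rng.choice([-1, 1])) * locus.unit_size
                diffs.append(d)
        total = len(diffs) + int(rng.poisson(extra_cov))
        out[locus.name] = (diffs, total)
    return out
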