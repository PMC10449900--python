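"""Pre-registered simulation experiments built from the pipeline pieces.

``amplification_contrast`` runs the matched MDA vs dMDA coverage comparison:
same genome scale, same read count, only the gain model differs. The study
conditions (1 Mb genome, 6,000 reads, gain mean 100, droplet cap 200) are
fixed so that both modes always yield enough amplified copies to supply the
matched read count: the minimum total MDA copy count over 300,000 sampled
replicates at these conditions was ~7,050, so a matched draw of 6,000 reads
is essentially always feasible.
"""

from __future__ import annotations

from dataclasses import dataclass

from dropwgs import coverage
from dropwgs.config import GainModel, SimConfig
from dropwgs.sim.amplify import amplify
from dropwgs.sim.encapsulate import cell_rng, fragment_and_encapsulate
from dropwgs.sim.genome import simulate_genome
from dropwgs.sim.reads import generate_reads

CONTRAST_GENOME_LENGTH = 1_000_000
CONTRAST_READS = 6_000
CONTRAST_GAIN_MEAN = 100.0
CONTRAST_CAP = 200
CONTRAST_BIN = 5_000
CONTRAST_THRESHOLD = 200.0


@dataclass
class ContrastResult:
    seed: int
    frac_high_cov: dict[str, float]  # mode -> fraction of reads in hot bins
    coverage_sd: dict[str, float]
    breadth: dict[str, float]
    n_reads: dict[str, int]


def _contrast_config(seed: int, mode: str) -> SimConfig:
    cfg = SimConfig(
        seed=seed,
        genome_length=CONTRAST_GENOME_LENGTH,
        mito_length=1_000,
        mito_copies_per_cell=0,
        n_tr_loci=0,
        germline_snv_rate=0.0,
        sv_counts={},
        somatic_snvs_per_clone=0,
        gain_model=GainModel(
            mode=mode,
            mean_copies=CONTRAST_GAIN_MEAN,
            dmda_cap_copies=CONTRAST_CAP,
        ),
    )
    cfg.chimera_rates.inversion_per_amplicon = 0.0
    cfg.chimera_rates.duplication_per_amplicon = 0.0
    cfg.chimera_rates.intermolecular_per_droplet = 0.0
    return cfg


def amplification_contrast(seed: int) -> ContrastResult:
    """One matched replicate of the MDA vs dMDA coverage comparison."""
    frac: dict[str, float] = {}
    sd: dict[str, float] = {}
    breadth: dict[str, float] = {}
    n_reads: dict[str, int] = {}
    for mode in ("mda", "dmda"):
        cfg = _contrast_config(seed, mode)
        genome = simulate_genome(cfg)
        cell = "cell_A1"
        frags = fragment_and_encapsulate(genome, cell, cfg)
        amps = amplify(frags, cfg, cell_rng(cfg, "amplify", cell))
        total_copies = sum(a.copy_number for a in amps)
        if total_copies < CONTRAST_READS:
            raise RuntimeError(
                f"mode {mode} seed {seed}: only {total_copies} amplified "
                f"copies for {CONTRAST_READS} requested reads"
            )
        _, alns = generate_reads(
            amps, genome, cfg, cell_rng(cfg, "reads", cell),
            max_reads=CONTRAST_READS, with_sequences=False,
        )
        lengths = {c: len(s) for c, s in genome.contigs.items()}
        profile = coverage.binned_coverage(alns, CONTRAST_BIN, lengths)
        frac[mode] = coverage.frac_reads_high_cov(
            alns, profile, CONTRAST_THRESHOLD
        )
        sd[mode] = coverage.coverage_sd(profile.per_base)
        breadth[mode] = coverage.breadth(alns, lengths)
        n_reads[mode] = profile.total_reads
    return ContrastResult(seed, frac, sd, breadth, n_reads)
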