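"""Per-sample call-set emission with configurable dropout and false calls.

The bulk call set is the full germline truth; each single-cell call set is
germline plus that cell's clone-specific somatic variants, with every record
independently dropped at ``dropout_rate`` (allelic dropout) and false calls
added on top: false SNVs at a per-base Poisson intensity and false SVs at
per-type Poisson means that are inversion-heavy by default, mimicking the
false-SV spectrum of amplified single cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from dropwgs.config import SimConfig
from dropwgs.models import VariantCall
from dropwgs.sim.genome import NUCLEAR, SimGenome
from dropwgs.util import mutate_base

BULK = "bulk"


@dataclass
class TruthSet:
    """Expected per-sample calls plus per-read chimera truth."""

    per_sample_variants: dict[str, list[VariantCall]]
    chimera_truth: dict[str, str] = field(default_factory=dict)

    def sample_keys(self, sample_id: str) -> set[tuple]:
        return {v.site_key() for v in self.per_sample_variants[sample_id]}


def build_truth(genome: SimGenome, config: SimConfig) -> TruthSet:
    germline = genome.haplotype_variants
    per_sample = {BULK: [replace(v, sample_id=BULK) for v in germline]}
    for cell in config.cell_ids:
        clone = config.clone_of(cell)
        calls = germline + genome.clone_somatic.get(clone, [])
        per_sample[cell] = [replace(v, sample_id=cell) for v in calls]
    return TruthSet(per_sample)


def _false_snvs(genome, config, rng, sample_id, taken: set[int]) -> list[VariantCall]:
    seq = genome.contigs[NUCLEAR]
    n = rng.poisson(len(seq) * config.fp_snv_rate)
    out = []
    for pos in rng.integers(0, len(seq), size=n).tolist():
        if pos in taken:
            continue
        taken.add(pos)
        ref = seq[pos]
        out.append(
            VariantCall(NUCLEAR, pos, pos + 1, ref, mutate_base(rng, ref), "SNV",
                        sample_id=sample_id)
        )
    return out


def _false_svs(genome, config, rng, sample_id) -> list[VariantCall]:
    L = len(genome.contigs[NUCLEAR])
    out = []
    for svtype, mean in config.fp_sv_rates.items():
        for _ in range(int(rng.poisson(mean))):
            length = int(rng.integers(50, 5000))
            start = int(rng.integers(0, L - length))
            end = start if svtype == "INS" else start + length
            svlen = -length if svtype == "DEL" else length
            out.append(
                VariantCall(
                    NUCLEAR, start, end, "N", f"<{svtype}>", svtype, svlen=svlen,
                    precise=bool(rng.random() < config.fp_sv_precise_prob),
                    sample_id=sample_id,
                )
            )
    return out


def emit_callsets(
    genome: SimGenome,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, list[VariantCall]]:
    """Emit bulk plus per-cell call sets under the configured error model."""
    callsets: dict[str, list[VariantCall]] = {
        BULK: list(truth.per_sample_variants[BULK])
    }
    for cell in config.cell_ids:
        expected = truth.per_sample_variants[cell]
        keep = rng.random(len(expected)) >= config.dropout_rate
        calls = [v for v, k in zip(expected, keep.tolist()) if k]
        taken = {v.start for v in expected if v.svtype == "SNV"}
        calls += _false_snvs(genome, config, rng, cell, taken)
        calls += _false_svs(genome, config, rng, cell)
        calls.sort(key=lambda v: (v.contig, v.start, v.alt))
        callsets[cell] = calls
    return callsets
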