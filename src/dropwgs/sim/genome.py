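"""Diploid genome simulation with planted variants, repeats and a circular
mitochondrial contig.

The nuclear contig carries germline SNVs and SVs assigned to haplotype 1 or
2, tandem-repeat loci with per-haplotype length alleles, and per-clone
somatic SNVs. Insertions are modelled as copies of a reference source
interval (mobile-element-like: ALU-like ~300 bp, LINE-like ~6 kb), so every
simulated read base has reference provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dropwgs.config import SimConfig, stage_rng
from dropwgs.models import RepeatLocus, VariantCall
from dropwgs.util import mutate_base, random_seq, revcomp

NUCLEAR = "chr1"
MITO = "chrM"

_PLACEMENT_TRIES = 2000


class PlacementError(ValueError):
    """Genome too short to place a requested feature without overlap."""


@dataclass
class Haplotype:
    """One realized haplotype sequence plus its reference block map."""

    contig: str
    seq: str
    # (hap_start, hap_end, ref_start, ref_end, strand); hap and ref spans equal
    blocks: list[tuple[int, int, int, int, str]]

    def project(self, start: int, end: int) -> list[tuple[str, int, int, str]]:
        """Map a haplotype interval to ordered reference segments."""
        segments: list[tuple[str, int, int, str]] = []
        for hs, he, rs, re_, strand in self.blocks:
            lo, hi = max(start, hs), min(end, he)
            if lo >= hi:
                continue
            if strand == "+":
                seg = (self.contig, rs + (lo - hs), rs + (hi - hs), "+")
            else:
                seg = (self.contig, re_ - (hi - hs), re_ - (lo - hs), "-")
            # merge with previous segment when collinear
            if segments:
                pc, ps, pe, pstr = segments[-1]
                if pstr == seg[3] == "+" and pe == seg[1]:
                    segments[-1] = (pc, ps, seg[2], "+")
                    continue
                if pstr == seg[3] == "-" and ps == seg[2]:
                    segments[-1] = (pc, seg[1], pe, "-")
                    continue
            segments.append(seg)
        return segments


@dataclass
class SimGenome:
    """Reference contigs plus all planted truth."""

    contigs: dict[str, str]
    circular: set[str]
    haplotype_variants: list[VariantCall]
    tr_loci: list[RepeatLocus]
    clone_somatic: dict[str, list[VariantCall]]
    # (contig, 0-based position, ref, alt, frequency, clone_id)
    heteroplasmy_site: tuple | None
    ins_sources: dict[tuple, tuple[int, int]] = field(default_factory=dict)
    _hap_cache: dict = field(default_factory=dict, repr=False)

    def haplotype(self, contig: str, hap: str, clone: str | None = None) -> Haplotype:
        """Realized haplotype sequence (germline + clone somatic variants)."""
        key = (contig, hap, clone)
        if key not in self._hap_cache:
            self._hap_cache[key] = self._build(contig, hap, clone)
        return self._hap_cache[key]

    def repeat_mask(self) -> list[tuple[str, int, int]]:
        """BED-style intervals of the highly repetitive (TR) regions."""
        return [(t.contig, t.start, t.end) for t in self.tr_loci]

    # -- haplotype realization -------------------------------------------
    def _build(self, contig: str, hap: str, clone: str | None) -> Haplotype:
        ref = self.contigs[contig]
        if hap == "mito" or contig in self.circular:
            return Haplotype(contig, ref, [(0, len(ref), 0, len(ref), "+")])
        hap_no = int(hap)
        variants = [
            v
            for v in self.haplotype_variants
            if v.contig == contig and v.haplotype == hap_no
        ]
        if clone is not None:
            variants += [
                v
                for v in self.clone_somatic.get(clone, ())
                if v.contig == contig and v.haplotype == hap_no
            ]
        snvs = [v for v in variants if v.svtype == "SNV"]
        events: list[tuple[int, int, str, tuple]] = []
        for v in variants:
            if v.svtype == "SNV":
                continue
            if v.svtype == "INS":
                src = self.ins_sources[(v.contig, v.start, v.svlen)]
                events.append((v.start, v.start, "INS", (src,)))
            else:
                events.append((v.start, v.end, v.svtype, ()))
        # tandem-repeat alleles: expansion = extra copy of the locus tail,
        # contraction = deletion at the locus end
        for t in self.tr_loci:
            if t.contig != contig:
                continue
            diff = t.hap_diffs[hap_no - 1]
            if diff > 0:
                srcs = _tile_source(t, diff)
                events.append((t.end, t.end, "INS", (srcs,)))
            elif diff < 0:
                events.append((t.end + diff, t.end, "DEL", ()))
        events.sort(key=lambda e: (e[0], e[1]))
        return _apply_events(contig, ref, events, snvs)


def _tile_source(t: RepeatLocus, diff: int) -> list[tuple[int, int]]:
    """Reference intervals inside a TR locus whose copy realizes an expansion."""
    srcs: list[tuple[int, int]] = []
    remaining = diff
    locus_len = t.end - t.start
    while remaining > 0:
        take = min(remaining, locus_len)
        srcs.append((t.end - take, t.end))
        remaining -= take
    return srcs


def _apply_events(contig, ref, events, snvs) -> Haplotype:
    parts: list[str] = []
    blocks: list[tuple[int, int, int, int, str]] = []
    hpos = 0

    def emit(rs: int, re_: int, strand: str = "+") -> None:
        nonlocal hpos
        seq = ref[rs:re_] if strand == "+" else revcomp(ref[rs:re_])
        parts.append(seq)
        blocks.append((hpos, hpos + len(seq), rs, re_, strand))
        hpos += len(seq)

    cursor = 0
    for start, end, kind, payload in events:
        if start < cursor:
            raise ValueError(f"overlapping planted events at {contig}:{start}")
        if start > cursor:
            emit(cursor, start)
        if kind == "DEL":
            pass
        elif kind == "INS":
            src = payload[0]
            for s, e in src if isinstance(src, list) else [src]:
                emit(s, e)
        elif kind == "DUP":
            emit(start, end)
            emit(start, end)
        elif kind == "INV":
            emit(start, end, "-")
        else:  # pragma: no cover
            raise ValueError(f"unknown event kind {kind}")
        cursor = end
    if cursor < len(ref):
        emit(cursor, len(ref))

    seq_arr = np.frombuffer("".join(parts).encode(), dtype=np.uint8).copy()
    # SNVs never overlap SV/TR intervals, so each maps into one '+' block
    for v in snvs:
        for hs, he, rs, re_, strand in blocks:
            if strand == "+" and rs <= v.start < re_:
                seq_arr[hs + (v.start - rs)] = ord(v.alt)
                break
    return Haplotype(contig, seq_arr.tobytes().decode(), blocks)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig) -> SimGenome:
    """Generate the diploid reference plus all planted truth annotations."""
    config.validate()
    rng = stage_rng(config.seed, "genome")
    L = config.genome_length
    seq = np.frombuffer(random_seq(rng, L).encode(), dtype=np.uint8).copy()
    blocked = np.zeros(L, dtype=bool)

    tr_loci = _plant_tr_loci(rng, config, seq, blocked)
    variants, ins_sources = _plant_svs(rng, config, seq, blocked)
    clone_somatic = {
        clone: _plant_snvs(
            rng, config, seq, blocked, config.somatic_snvs_per_clone, sample_id=clone
        )
        for clone in config.clones
    }
    n_germ = rng.binomial(L, config.germline_snv_rate) if config.germline_snv_rate else 0
    variants += _plant_snvs(rng, config, seq, blocked, n_germ)
    variants.sort(key=lambda v: (v.contig, v.start))

    mito = random_seq(rng, config.mito_length)
    het_pos = int(rng.integers(100, config.mito_length - 100))
    het_ref = mito[het_pos]
    het_alt = mutate_base(rng, het_ref)
    het = (MITO, het_pos, het_ref, het_alt, config.heteroplasmy_frequency,
           config.clones[-1])

    return SimGenome(
        contigs={NUCLEAR: seq.tobytes().decode(), MITO: mito},
        circular={MITO},
        haplotype_variants=variants,
        tr_loci=tr_loci,
        clone_somatic=clone_somatic,
        heteroplasmy_site=het,
        ins_sources=ins_sources,
    )


def _reserve(rng, blocked, span, margin, what) -> int:
    """Find a start for an interval of ``span`` clear of blocked bases."""
    limit = len(blocked) - span - margin
    if limit <= margin:
        raise PlacementError(f"genome too short to place {what}")
    for _ in range(_PLACEMENT_TRIES):
        start = int(rng.integers(margin, limit))
        if not blocked[start - margin : start + span + margin].any():
            blocked[max(0, start - margin) : start + span + margin] = True
            return start
    raise PlacementError(f"could not place {what} without overlap")


def _plant_tr_loci(rng, config, seq, blocked) -> list[RepeatLocus]:
    loci = []
    unit_sizes = np.asarray(config.tr_unit_sizes)
    for i in range(config.n_tr_loci):
        unit = random_seq(rng, int(rng.choice(unit_sizes)))
        copies = int(rng.integers(10, 31))
        span = len(unit) * copies
        # 200 bp buffer keeps every SV breakpoint >= 200 bp away
        start = _reserve(rng, blocked, span, 200, f"TR locus {i}")
        seq[start : start + span] = np.frombuffer(
            (unit * copies).encode(), dtype=np.uint8
        )
        diffs = []
        for _ in range(2):
            if rng.random() < 0.5:
                diffs.append(0)
                continue
            units = int(rng.integers(1, 6))
            if rng.random() < 0.5 and units <= copies - 2:
                diffs.append(-units * len(unit))
            else:
                diffs.append(units * len(unit))
        loci.append(
            RepeatLocus(NUCLEAR, start, start + span, unit, copies, tuple(diffs))
        )
    loci.sort(key=lambda t: t.start)
    return loci


def _sv_length(rng, config) -> int:
    if rng.random() < config.sv_alu_fraction:
        mode, sd = config.sv_alu_length
    else:
        mode, sd = config.sv_line_length
    return max(50, int(round(rng.normal(mode, sd))))


def _plant_svs(rng, config, seq, blocked):
    variants: list[VariantCall] = []
    ins_sources: dict[tuple, tuple[int, int]] = {}
    for svtype in ("DEL", "INS", "DUP", "INV"):
        for i in range(config.sv_counts.get(svtype, 0)):
            length = _sv_length(rng, config)
            precise = bool(rng.random() < config.true_sv_precise_prob)
            hap = int(rng.integers(1, 3))
            if svtype == "INS":
                start = _reserve(rng, blocked, 1, 10, f"INS {i}")
                src_start = int(rng.integers(0, len(seq) - length))
                v = VariantCall(
                    NUCLEAR, start, start, "N", "<INS>", "INS",
                    svlen=length, precise=precise, haplotype=hap,
                )
                ins_sources[(NUCLEAR, start, length)] = (src_start, src_start + length)
            else:
                start = _reserve(rng, blocked, length, 10, f"{svtype} {i}")
                svlen = -length if svtype == "DEL" else length
                v = VariantCall(
                    NUCLEAR, start, start + length, "N", f"<{svtype}>", svtype,
                    svlen=svlen, precise=precise, haplotype=hap,
                )
            variants.append(v)
    return variants, ins_sources


def _plant_snvs(rng, config, seq, blocked, n, sample_id="") -> list[VariantCall]:
    if n == 0:
        return []
    free = np.flatnonzero(~blocked)
    if len(free) < n:
        raise PlacementError(f"genome too short to place {n} SNVs")
    positions = np.sort(rng.choice(free, size=n, replace=False))
    blocked[positions] = True
    out = []
    for pos in positions.tolist():
        ref = chr(seq[pos])
        out.append(
            VariantCall(
                NUCLEAR, pos, pos + 1, ref, mutate_base(rng, ref), "SNV",
                sample_id=sample_id, haplotype=int(rng.integers(1, 3)),
            )
        )
    return out
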