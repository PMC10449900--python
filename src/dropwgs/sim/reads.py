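"""Read generation from amplified molecules, with truth provenance.

Each amplified copy yields one read covering the whole molecule (fragments
are already read-sized, ~9 kb). Chimera events reshape the molecule before
sequencing errors are applied; the ordered ``truth_segments`` record the
reference provenance of every read portion, with strand '-' for inverted
segments and repeated intervals for duplicated ones.
"""

from __future__ import annotations

import numpy as np

from dropwgs.config import SimConfig
from dropwgs.models import AlignmentRecord, Amplicon, ChimeraEvent, Fragment, ReadRecord
from dropwgs.sim.genome import MITO, SimGenome
from dropwgs.util import apply_read_errors, revcomp

# a molecule is an ordered list of pieces (key, start, end, strand) in
# haplotype coordinates; key = (contig, haplotype, mito_alt)
Piece = tuple[tuple, int, int, str]


def _pieces_of(frag: Fragment, mito_len: int) -> list[Piece]:
    key = (frag.contig, frag.haplotype, frag.mito_alt)
    if frag.contig == MITO and frag.end > mito_len:  # circular wrap
        return [(key, frag.start, mito_len, "+"), (key, 0, frag.end - mito_len, "+")]
    return [(key, frag.start, frag.end, "+")]


def _length(pieces: list[Piece]) -> int:
    return sum(e - s for _, s, e, _ in pieces)


def _cut(pieces: list[Piece], a: int, b: int) -> list[Piece]:
    out: list[Piece] = []
    off = 0
    for key, s, e, strand in pieces:
        ln = e - s
        lo, hi = max(a, off), min(b, off + ln)
        if lo < hi:
            i, j = lo - off, hi - off
            if strand == "+":
                out.append((key, s + i, s + j, "+"))
            else:
                out.append((key, e - j, e - i, "-"))
        off += ln
    return out


def _rc(pieces: list[Piece]) -> list[Piece]:
    return [
        (key, s, e, "-" if strand == "+" else "+")
        for key, s, e, strand in reversed(pieces)
    ]


def _apply_event(
    pieces: list[Piece], event: ChimeraEvent | None, mito_len: int
) -> list[Piece]:
    if event is None:
        return pieces
    n = _length(pieces)
    if event.kind == "INVERSION":
        pre = _cut(pieces, 0, min(event.breakpoint, n))
        return pre + _rc(pre)
    if event.kind == "DUPLICATION":
        return _cut(pieces, 0, event.dup_end) + _cut(pieces, event.dup_start, n)
    if event.kind == "INTERMOLECULAR":
        partner = _pieces_of(event.partner, mito_len)
        return _cut(pieces, 0, min(event.breakpoint, n)) + _cut(
            partner, event.partner_breakpoint, _length(partner)
        )
    raise ValueError(f"unknown chimera kind {event.kind}")  # pragma: no cover


class _HapCache:
    def __init__(self, genome: SimGenome, config: SimConfig):
        self.genome = genome
        self.config = config
        self._cache: dict = {}

    def get(self, key: tuple, cell_id: str):
        contig, hap, mito_alt = key
        clone = self.config.clone_of(cell_id)
        ck = (contig, hap, mito_alt, clone if contig != MITO else None)
        if ck not in self._cache:
            haplo = self.genome.haplotype(contig, hap, clone)
            seq = haplo.seq
            if mito_alt and self.genome.heteroplasmy_site:
                _, pos, _, alt, _, _ = self.genome.heteroplasmy_site
                seq = seq[:pos] + alt + seq[pos + 1 :]
            self._cache[ck] = (seq, haplo)
        return self._cache[ck]


def generate_reads(
    amplicons: list[Amplicon],
    genome: SimGenome,
    config: SimConfig,
    rng: np.random.Generator,
    max_reads: int | None = None,
    with_sequences: bool = True,
) -> tuple[list[ReadRecord], list[AlignmentRecord]]:
    """Sample reads (one per amplified copy, optionally subsampled to
    ``max_reads``) and emit truth alignments for every read segment."""
    mito_len = len(genome.contigs.get(MITO, ""))
    haps = _HapCache(genome, config)

    counts = np.asarray([a.copy_number for a in amplicons], dtype=np.int64)
    amp_idx = np.repeat(np.arange(len(amplicons)), counts)
    copy_idx = np.concatenate(
        [np.arange(c) for c in counts.tolist()] or [np.zeros(0, np.int64)]
    )
    if max_reads is not None and max_reads < len(amp_idx):
        sel = np.sort(rng.choice(len(amp_idx), size=max_reads, replace=False))
        amp_idx, copy_idx = amp_idx[sel], copy_idx[sel]

    events = {
        (ai, ev.copy_index): ev
        for ai, a in enumerate(amplicons)
        for ev in a.chimera_events
    }

    reads: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    for serial, (ai, ci) in enumerate(zip(amp_idx.tolist(), copy_idx.tolist())):
        amp = amplicons[ai]
        frag = amp.fragment
        event = events.get((ai, ci))
        pieces = _apply_event(_pieces_of(frag, mito_len), event, mito_len)
        read_id = f"{frag.cell_id}_r{serial}"

        # reference truth segments, ordered along the read
        segments: list[tuple[str, int, int, str]] = []
        for key, s, e, strand in pieces:
            _, haplo = haps.get(key, frag.cell_id)
            projected = haplo.project(s, e)
            if strand == "-":
                projected = [
                    (c, rs, re_, "-" if st == "+" else "+")
                    for c, rs, re_, st in reversed(projected)
                ]
            segments.extend(projected)

        sequence = ""
        if with_sequences:
            chunks = []
            for key, s, e, strand in pieces:
                seq, _ = haps.get(key, frag.cell_id)
                chunk = seq[s:e]
                chunks.append(chunk if strand == "+" else revcomp(chunk))
            sequence, _ = apply_read_errors(
                "".join(chunks), config.read_error_rate, rng
            )

        chimera_type = event.kind if event else "NONE"
        pre_error_len = sum(re_ - rs for _, rs, re_, _ in segments)
        reads.append(
            ReadRecord(
                read_id,
                sequence,
                segments,
                is_chimeric=event is not None,
                chimera_type=chimera_type,
                cell_id=frag.cell_id,
            )
        )
        offset = 0
        for contig, rs, re_, strand in segments:
            seg_len = re_ - rs
            alignments.append(
                AlignmentRecord(
                    read_id, pre_error_len, offset, offset + seg_len,
                    strand, contig, rs, re_,
                )
            )
            offset += seg_len
    return reads, alignments
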