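"""Read self-alignment screen for intramolecular chimeras.

Amplification artifacts show up as a read carrying a second copy of part of
its own sequence: a fold-back inversion (reverse-complement copy) or a
tandem duplication (forward off-diagonal copy). The screen re-implements a
BLAST-against-self search as k-mer seeding, diagonal-band chaining and
banded-alignment validation: any non-trivial self-hit with identity above
the threshold (default 90%) marks the read as chimeric.

Seeds on the exact forward main diagonal (the read matching itself in
place) are excluded by construction; a reverse-complement self-hit is never
trivial and signals a fold-back.
"""

from __future__ import annotations

from collections import defaultdict

import edlib

from dropwgs.models import AlignmentRecord, ChimeraReport, ReadRecord, SelfHit
from dropwgs.util import revcomp

DEFAULT_K = 15
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_HIT_LEN = 100
DEFAULT_BAND = 50
_MAX_KMER_OCC = 10  # seed masking for low-complexity/repeat k-mers
_MAX_SEED_GAP = 500  # chain break threshold along the read


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _cluster_seeds(
    seeds: list[tuple[int, int]], k: int, band: int
) -> list[tuple[int, int, int, int]]:
    """Chain seed pairs (i, j) by diagonal band and read proximity.

    Returns extents (a_start, a_end, b_start, b_end).
    """
    if not seeds:
        return []
    # position-major chaining: a small indel inside the copied segment shifts
    # later seeds to a neighbouring diagonal, so each seed may extend any open
    # chain whose last seed lies within the diagonal band and the read gap
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    for s in seeds:
        for cl in clusters:
            prev = cl[-1]
            if (
                abs((s[1] - s[0]) - (prev[1] - prev[0])) <= band
                and 0 <= s[0] - prev[0] <= _MAX_SEED_GAP
                and s[1] >= prev[1] - band
            ):
                cl.append(s)
                break
        else:
            clusters.append([s])
    out = []
    for cl in clusters:
        a0 = min(i for i, _ in cl)
        a1 = max(i for i, _ in cl) + k
        b0 = min(j for _, j in cl)
        b1 = max(j for _, j in cl) + k
        out.append((a0, a1, b0, b1))
    return out


def _identity(x: str, y: str) -> float:
    """Global-alignment identity (matching columns / alignment columns)."""
    res = edlib.align(x, y, mode="NW", task="path")
    dist = res["editDistance"]
    cols = 0
    num = ""
    for ch in res["cigar"] or "":
        if ch.isdigit():
            num += ch
        else:
            cols += int(num)
            num = ""
    cols = cols or max(len(x), len(y))
    return 1.0 - dist / cols if cols else 0.0


def self_align(
    seq: str,
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    band: int = DEFAULT_BAND,
) -> list[SelfHit]:
    """All non-trivial self-hits of a read, forward and reverse-complement."""
    if not 11 <= k <= 31:
        raise ValueError("k must lie in [11, 31]")
    n = len(seq)
    if n < 2 * min_hit_len:
        return []

    index = _kmer_index(seq, k)
    hits: list[SelfHit] = []

    # forward off-diagonal seeds (i < j excludes the trivial self-match)
    fwd_seeds = [
        (i, j)
        for positions in index.values()
        if 1 < len(positions) <= _MAX_KMER_OCC
        for ai, i in enumerate(positions)
        for j in positions[ai + 1 :]
        if j - i >= k
    ]
    for a0, a1, b0, b1 in _cluster_seeds(fwd_seeds, k, band):
        if min(a1 - a0, b1 - b0) < min_hit_len:
            continue
        ident = _identity(seq[a0:a1], seq[b0:b1])
        if ident >= min_identity:
            hits.append(
                SelfHit(a0, a1, b0, b1, "forward", ident, max(a1 - a0, b1 - b0))
            )

    # reverse-complement seeds; mirror symmetry removed via i + j <= n - k
    rcs = revcomp(seq)
    rc_seeds = []
    for i in range(n - k + 1):
        kmer = rcs[i : i + k]
        positions = index.get(kmer)
        if positions and len(positions) <= _MAX_KMER_OCC:
            for p in positions:
                if p + i <= n - k:
                    rc_seeds.append((p, i))
    for a0, a1, b0, b1 in _cluster_seeds(rc_seeds, k, band):
        if min(a1 - a0, b1 - b0) < min_hit_len:
            continue
        ident = _identity(seq[a0:a1], rcs[b0:b1])
        if ident < min_identity:
            continue
        # map the rc-space interval back onto the read
        bs, be = n - b1, n - b0
        a, b = ((a0, a1), (bs, be)) if a0 <= bs else ((bs, be), (a0, a1))
        hits.append(SelfHit(a[0], a[1], b[0], b[1], "rc", ident, max(a1 - a0, b1 - b0)))

    return _dedupe(hits)


def _dedupe(hits: list[SelfHit]) -> list[SelfHit]:
    out: list[SelfHit] = []
    for h in sorted(hits, key=lambda h: (-h.length, h.a_start)):
        dup = any(
            o.orientation == h.orientation
            and abs(o.a_start - h.a_start) < 100
            and abs(o.b_start - h.b_start) < 100
            for o in out
        )
        if not dup:
            out.append(h)
    return out


def classify(hits: list[SelfHit]) -> tuple[str, list[int]]:
    """Verdict plus junction positions (midpoint between the paired intervals)."""
    if not hits:
        return "CLEAN", []
    kinds = {h.orientation for h in hits}
    if kinds == {"rc"}:
        verdict = "INVERSION"
    elif kinds == {"forward"}:
        verdict = "DUPLICATION"
    else:
        verdict = "COMPLEX"
    junctions = sorted((h.a_end + h.b_start) // 2 for h in hits)
    return verdict, junctions


def analyze_read(
    read: ReadRecord | str,
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
) -> ChimeraReport:
    seq = read if isinstance(read, str) else read.sequence
    read_id = "read" if isinstance(read, str) else read.read_id
    hits = self_align(seq, k=k, min_identity=min_identity, min_hit_len=min_hit_len)
    verdict, junctions = classify(hits)
    return ChimeraReport(read_id, len(seq), hits, verdict, junctions)


def filter_reads(
    reads: list[ReadRecord],
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
) -> tuple[list[ReadRecord], list[ReadRecord], dict]:
    """Remove reads with any non-CLEAN verdict; returns (passed, removed, stats)."""
    passed: list[ReadRecord] = []
    removed: list[ReadRecord] = []
    reports: list[ChimeraReport] = []
    counts = {"CLEAN": 0, "INVERSION": 0, "DUPLICATION": 0, "COMPLEX": 0}
    for read in reads:
        report = analyze_read(read, k=k, min_identity=min_identity,
                              min_hit_len=min_hit_len)
        reports.append(report)
        counts[report.verdict] += 1
        (passed if report.verdict == "CLEAN" else removed).append(read)
    stats = {
        "n_total": len(reads),
        "n_passed": len(passed),
        "n_removed": len(removed),
        "pass_fraction": len(passed) / len(reads) if reads else 1.0,
        "verdicts": counts,
        "reports": reports,
    }
    return passed, removed, stats


def split_read(
    read: ReadRecord,
    report: ChimeraReport,
    trim: int = 50,
    min_subread: int = 500,
) -> list[ReadRecord]:
    """Cut a chimeric read at its junctions into non-chimeric subreads."""
    if report.verdict == "CLEAN":
        raise ValueError("cannot split a CLEAN read")
    n = len(read.sequence)
    for j in report.junctions:
        if not 0 < j < n:
            raise ValueError(f"junction {j} outside read bounds (0, {n})")
    cuts = [0] + sorted(report.junctions) + [n]
    subreads = []
    intervals = []
    for idx in range(len(cuts) - 1):
        lo = cuts[idx] + (trim if idx > 0 else 0)
        hi = cuts[idx + 1] - (trim if idx < len(cuts) - 2 else 0)
        if hi - lo < min_subread:
            continue
        intervals.append((lo, hi))
        subreads.append(
            ReadRecord(
                f"{read.read_id}/{idx + 1}", read.sequence[lo:hi], [],
                cell_id=read.cell_id,
            )
        )
    report.subread_intervals = intervals
    return subreads


def aligned_n50(alignments) -> int:
    """N50 of aligned-segment lengths: the length L such that segments of
    length >= L cover at least half the aligned bases."""
    lengths = sorted(
        (a.aligned_length if isinstance(a, AlignmentRecord) else int(a))
        for a in alignments
    )
    if not lengths:
        raise ValueError("aligned_n50 of an empty alignment set is undefined")
    half = sum(lengths) / 2.0
    acc = 0
    for ln in reversed(lengths):
        acc += ln
        if acc >= half:
            return ln
    return lengths[0]  # pragma: no cover
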