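"""Tandem-repeat genotyping from spanning long reads.

The measured quantity per read is the signed repeat-length difference vs
the reference: the sum of insertion lengths minus deletion lengths within
the locus plus a flank window. Summing all indel operations makes the
measurement invariant to how the aligner distributes the indels — an
expansion split into two separate insertions still yields its full length.

Per-locus genotypes come from 1-D single-linkage clustering of the per-read
differences; a four-rule confidence filter then mirrors how high-confidence
bulk loci are selected: (i) allele support (5 per allele het / 10 hom),
(ii) no extra allele cluster with more than two reads, (iii) at least 90%
of spanning reads on the called allele(s), (iv) total coverage at most 50x.
"""

from __future__ import annotations

import numpy as np

from dropwgs.models import RepeatLocus, TRGenotype

DEFAULT_FLANK = 100
MIN_ALLELE_READS = 4  # smaller clusters are treated as noise ("other alleles")

_REF_CONSUMING = {"M", "=", "X", "D", "N"}
_READ_CONSUMING = {"M", "=", "X", "I", "S"}


def read_repeat_length(
    ref_start: int,
    cigar: list[tuple[str, int]],
    locus: RepeatLocus,
    flank: int = DEFAULT_FLANK,
) -> int | None:
    """Signed repeat-length difference measured by one alignment.

    Returns None when the alignment does not fully span
    ``[locus.start - flank, locus.end + flank]`` (non-informative read).
    """
    win_lo = locus.start - flank
    win_hi = locus.end + flank
    ref_end = ref_start + sum(ln for op, ln in cigar if op in _REF_CONSUMING)
    if ref_start > win_lo or ref_end < win_hi:
        return None
    diff = 0
    pos = ref_start
    for op, ln in cigar:
        if op == "I":
            if win_lo <= pos <= win_hi:
                diff += ln
        elif op == "D":
            overlap = min(pos + ln, win_hi) - max(pos, win_lo)
            if overlap > 0:
                diff -= overlap
        if op in _REF_CONSUMING:
            pos += ln
    return diff


def _single_linkage_1d(diffs: list[int], tol: int) -> list[list[int]]:
    """Clusters of values whose sorted neighbour gaps are all <= tol."""
    if not diffs:
        return []
    values = sorted(diffs)
    clusters = [[values[0]]]
    for v in values[1:]:
        if v - clusters[-1][-1] <= tol:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters


def genotype_locus(
    diffs: list[int],
    locus: RepeatLocus,
    total_coverage: int | None = None,
    tol: int | None = None,
    min_allele_reads: int = MIN_ALLELE_READS,
) -> TRGenotype:
    """Cluster per-read length differences into one or two allele calls.

    ``total_coverage`` is the number of reads overlapping the locus
    (spanning or not); it defaults to the number of spanning reads.
    """
    tol = tol if tol is not None else max(2, locus.unit_size)
    total = total_coverage if total_coverage is not None else len(diffs)
    clusters = _single_linkage_1d(diffs, tol)
    order = sorted(range(len(clusters)),
                   key=lambda i: (-len(clusters[i]), clusters[i][0]))
    allele_idx = [i for i in order if len(clusters[i]) >= min_allele_reads][:2]
    alleles = [int(np.median(clusters[i])) for i in allele_idx]
    counts = [len(clusters[i]) for i in allele_idx]
    if len(alleles) == 2 and abs(alleles[0] - alleles[1]) <= tol:
        merged = clusters[allele_idx[0]] + clusters[allele_idx[1]]
        alleles, counts = [int(np.median(merged))], [len(merged)]
        allele_idx = allele_idx[:1]
    if len(alleles) == 2 and alleles[0] > alleles[1]:
        alleles.reverse()
        counts.reverse()
    others = [len(c) for i, c in enumerate(clusters) if i not in allele_idx]
    n_persistent = sum(1 for c in clusters if len(c) > 2)
    status = "UNGENOTYPED" if (not alleles or n_persistent > 2) else "UNFILTERED"
    return TRGenotype(locus, list(diffs), alleles, counts, others, total, status)


def confidence_filter(genotype: TRGenotype) -> str:
    """Apply the four confidence rules; PASS or FAIL(first violated rule)."""
    g = genotype
    if not g.alleles or g.status == "UNGENOTYPED":
        g.status = "UNGENOTYPED"
        return g.status
    if g.is_het:
        if min(g.allele_counts) < 5:
            g.status = "FAIL(i)"
            return g.status
    elif g.allele_counts[0] < 10:
        g.status = "FAIL(i)"
        return g.status
    if any(c > 2 for c in g.other_cluster_sizes):
        g.status = "FAIL(ii)"
        return g.status
    spanning = sum(g.allele_counts) + g.other_allele_reads
    if spanning and sum(g.allele_counts) / spanning < 0.90:
        g.status = "FAIL(iii)"
        return g.status
    if g.total_coverage > 50:
        g.status = "FAIL(iv)"
        return g.status
    g.status = "PASS"
    return g.status


def concordance(
    cell_genotypes: dict[str, TRGenotype],
    bulk_genotypes: dict[str, TRGenotype],
    tol: int = 0,
) -> dict[str, int]:
    """Allele-level agreement of single-cell genotypes with bulk PASS loci.

    ``correct``: cell alleles matching a bulk allele length (within tol);
    ``discordant``: cell alleles with no matching bulk allele;
    ``ungenotyped``: bulk alleles not recovered (locus missing, UNGENOTYPED,
    or allele dropped).
    """
    counts = {"correct": 0, "discordant": 0, "ungenotyped": 0}
    for name, bulk in bulk_genotypes.items():
        if bulk.status != "PASS":
            continue
        cell = cell_genotypes.get(name)
        if cell is None or not cell.alleles or cell.status == "UNGENOTYPED":
            counts["ungenotyped"] += len(bulk.alleles)
            continue
        remaining = list(bulk.alleles)
        for a in cell.alleles:
            match = next((b for b in remaining if abs(a - b) <= tol), None)
            if match is not None:
                counts["correct"] += 1
                remaining.remove(match)
            else:
                counts["discordant"] += 1
        counts["ungenotyped"] += len(remaining)
    return counts
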