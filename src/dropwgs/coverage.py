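"""Coverage-uniformity metrics over truth or real alignments.

Depth counts aligned reference bases per position (pileup semantics);
per-bin depth is the aligned-base count in the bin divided by the true bin
length, so the final partial bin of a contig is not inflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dropwgs.models import AlignmentRecord


@dataclass
class CoverageProfile:
    bin_size: int
    depths: dict[str, np.ndarray]  # contig -> mean depth per bin
    contig_lengths: dict[str, int]
    total_aligned_bases: int = 0
    total_reads: int = 0
    per_base: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def per_base_depth(
    alignments: list[AlignmentRecord], contig_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Exact per-base depth from interval arithmetic (difference arrays)."""
    diffs = {c: np.zeros(ln + 1, dtype=np.int64) for c, ln in contig_lengths.items()}
    for a in alignments:
        d = diffs.get(a.contig)
        if d is None:
            raise KeyError(f"alignment on unknown contig {a.contig!r}")
        d[a.ref_start] += 1
        d[min(a.ref_end, len(d) - 1)] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def binned_coverage(
    alignments: list[AlignmentRecord],
    bin_size: int,
    contig_lengths: dict[str, int],
) -> CoverageProfile:
    """Mean depth per ``bin_size`` window across every contig."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    per_base = per_base_depth(alignments, contig_lengths)
    depths: dict[str, np.ndarray] = {}
    for contig, depth in per_base.items():
        n = len(depth)
        edges = np.arange(0, n, bin_size)
        sums = np.add.reduceat(depth, edges) if n else np.zeros(0)
        lengths = np.minimum(edges + bin_size, n) - edges
        depths[contig] = sums / lengths
    total_bases = sum(int(d.sum()) for d in per_base.values())
    n_reads = len({a.read_id for a in alignments})
    return CoverageProfile(
        bin_size, depths, dict(contig_lengths), total_bases, n_reads, per_base
    )


def frac_reads_high_cov(
    alignments: list[AlignmentRecord],
    profile: CoverageProfile,
    threshold: float = 200.0,
) -> float:
    """Fraction of reads whose alignment overlaps at least one bin with
    depth >= threshold (membership, not base apportionment)."""
    if not alignments:
        return 0.0
    hot = {c: d >= threshold for c, d in profile.depths.items()}
    bs = profile.bin_size
    rows = []
    for a in alignments:
        h = hot[a.contig]
        b0 = a.ref_start // bs
        b1 = (max(a.ref_end, a.ref_start + 1) - 1) // bs
        rows.append((a.read_id, bool(h[b0 : b1 + 1].any())))
    df = pd.DataFrame(rows, columns=["read_id", "hit"])
    per_read = df.groupby("read_id")["hit"].any()
    return float(per_read.mean())


def breadth(
    alignments: list[AlignmentRecord], contig_lengths: dict[str, int]
) -> float:
    """Fraction of reference bases covered by at least one read."""
    total = sum(contig_lengths.values())
    if total == 0:
        return 0.0
    per_base = per_base_depth(alignments, contig_lengths)
    covered = sum(int((d > 0).sum()) for d in per_base.values())
    return covered / total


def coverage_sd(depths) -> float:
    """Population standard deviation of per-base depth.

    Accepts a per-contig dict of per-base depth arrays or a single array.
    """
    if isinstance(depths, dict):
        arr = np.concatenate([np.asarray(d, dtype=float) for d in depths.values()])
    else:
        arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise ValueError("coverage_sd of empty depth vector is undefined")
    return float(arr.std())


def downsample(items: list, n: int, seed: int) -> list:
    """Uniform sample of ``n`` items without replacement, deterministic."""
    if n > len(items):
        raise ValueError(f"cannot downsample {len(items)} items to {n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(items), size=n, replace=False))
    return [items[i] for i in idx.tolist()]
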