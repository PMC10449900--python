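"""Truth-set evaluation of SNVs and SVs, multi-sample SV merging, and
clone-aware somatic variant filters.

SNV matching is allele identity (contig, position, ref, alt) against the
bulk truth set. SV merging is single-linkage clustering: two calls link iff
they share a type and contig, their starts lie within ``max_dist`` (200 bp)
and their intervals overlap reciprocally by at least ``min_overlap`` (10%);
insertions substitute a length ratio for interval overlap. The somatic
filters are pure presence/absence set logic across clones, with a non-call
(e.g. from allelic dropout) counting as absence.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from collections import defaultdict
from dataclasses import replace

import numpy as np
import pandas as pd

from dropwgs.models import SV_TYPES, VariantCall, EvalResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization and SNV intersection
# ---------------------------------------------------------------------------


def trim_alleles(v: VariantCall) -> VariantCall:
    """Minimal representation: drop shared suffix/prefix bases (keep >=1)."""
    if v.is_sv:
        return v
    ref, alt, start = v.ref, v.alt, v.start
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    if (ref, alt, start) == (v.ref, v.alt, v.start):
        return v
    svtype = "SNV" if len(ref) == 1 == len(alt) else "INDEL"
    return replace(v, start=start, end=start + len(ref), ref=ref, alt=alt,
                   svtype=svtype)


def left_align(v: VariantCall, reference: str) -> VariantCall:
    """Left-shift a simple insertion/deletion against the reference."""
    v = trim_alleles(v)
    if v.svtype != "INDEL" or (len(v.ref) > 1 and len(v.alt) > 1):
        return v
    ref, alt, start = v.ref, v.alt, v.start
    while start > 0:
        longer = ref if len(ref) > len(alt) else alt
        if longer[-1] != reference[start - 1]:
            break
        start -= 1
        base = reference[start]
        ref = base + ref[:-1]
        alt = base + alt[:-1]
    if start == v.start:
        return v
    return replace(v, start=start, end=start + len(v.ref), ref=ref, alt=alt)


def _checked_snvs(calls: list[VariantCall]) -> list[VariantCall]:
    out = []
    for v in calls:
        if v.is_sv:
            continue
        t = trim_alleles(v)
        if t is not v:
            warnings.warn(
                f"unnormalized variant at {v.contig}:{v.pos} auto-normalized",
                stacklevel=3,
            )
        out.append(t)
    return out


def intersect_snvs(
    cell: list[VariantCall], bulk: list[VariantCall]
) -> list[VariantCall]:
    """Cell calls matching a bulk call by allele identity (the TP set)."""
    bulk_keys = {v.site_key() for v in _checked_snvs(bulk)}
    return [v for v in _checked_snvs(cell) if v.site_key() in bulk_keys]


def evaluate_snvs(cell: list[VariantCall], bulk: list[VariantCall]) -> EvalResult:
    """Precision/sensitivity of a cell call set against the bulk truth set."""
    cell_n = _checked_snvs(cell)
    bulk_keys = {v.site_key() for v in _checked_snvs(bulk)}
    cell_keys = {v.site_key() for v in cell_n}
    tp = len(cell_keys & bulk_keys)
    return EvalResult(tp=tp, fp=len(cell_keys - bulk_keys),
                      fn=len(bulk_keys - cell_keys))


# ---------------------------------------------------------------------------
# somatic SNV filter
# ---------------------------------------------------------------------------


class RepeatMask:
    """Sorted interval mask; any overlap of a position excludes the variant."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for contig, start, end in intervals:
            by_contig[contig].append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for contig, ivs in by_contig.items():
            ivs.sort()
            self._starts[contig] = [s for s, _ in ivs]
            self._ends[contig] = [e for _, e in ivs]

    def covers(self, contig: str, pos: int) -> bool:
        starts = self._starts.get(contig)
        if not starts:
            return False
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[contig][i]


def somatic_snv_filter(
    cells_by_clone: dict[str, list[list[VariantCall]]],
    bulk: list[VariantCall],
    repeat_mask: RepeatMask | list[tuple[str, int, int]] | None = None,
) -> list[tuple[VariantCall, str]]:
    """Candidate somatic SNVs: called in >=2 cells of one clone, absent from
    bulk and from every cell of the other clone(s), not an indel, and not in
    a repetitive region."""
    mask = (
        repeat_mask
        if isinstance(repeat_mask, RepeatMask)
        else RepeatMask(repeat_mask or [])
    )
    bulk_keys = {v.site_key() for v in bulk if not v.is_sv}
    clone_cell_keys = {
        clone: [{v.site_key() for v in cell if not v.is_sv} for cell in cells]
        for clone, cells in cells_by_clone.items()
    }
    candidates: list[tuple[VariantCall, str]] = []
    for clone, cells in cells_by_clone.items():
        if len(cells) < 2:
            warnings.warn(f"clone {clone!r} has <2 cells; skipped")
            continue
        counts: dict[tuple, int] = defaultdict(int)
        first: dict[tuple, VariantCall] = {}
        for cell_keys, cell in zip(clone_cell_keys[clone], cells):
            for key in cell_keys:
                counts[key] += 1
            for v in cell:
                if not v.is_sv:
                    first.setdefault(v.site_key(), v)
        other_keys: set[tuple] = set()
        for other, key_sets in clone_cell_keys.items():
            if other != clone:
                for ks in key_sets:
                    other_keys |= ks
        for key, n in counts.items():
            if n < 2 or key in bulk_keys or key in other_keys:
                continue
            v = first[key]
            if v.svtype != "SNV":  # indels excluded
                continue
            if mask.covers(v.contig, v.start):
                continue
            candidates.append((v, clone))
    candidates.sort(key=lambda t: (t[0].contig, t[0].start, t[0].alt))
    return candidates


# ---------------------------------------------------------------------------
# SV merging and evaluation
# ---------------------------------------------------------------------------


def _sv_link(a: VariantCall, b: VariantCall, max_dist: int, min_overlap: float) -> bool:
    if a.svtype != b.svtype or a.contig != b.contig:
        return False
    if abs(a.start - b.start) > max_dist:
        return False
    if a.svtype == "INS":
        la, lb = abs(a.svlen), abs(b.svlen)
        return min(la, lb) / max(la, lb) >= min_overlap if max(la, lb) else False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov / (a.end - a.start) >= min_overlap and ov / (b.end - b.start) >= min_overlap


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_svs(
    sv_sets: list[list[VariantCall]],
    max_dist: int = 200,
    min_overlap: float = 0.10,
) -> pd.DataFrame:
    """Single-linkage multi-sample SV merge.

    Returns one row per merged event with per-sample presence flags
    (columns ``in_<sample>``), the representative coordinates (minimum
    start, maximum end, median |svlen|) and a PRECISE flag (all members
    precise).
    """
    calls = [v for s in sv_sets for v in s if v.is_sv]
    samples = sorted({v.sample_id for v in calls})
    order = sorted(range(len(calls)), key=lambda i: (calls[i].svtype,
                                                     calls[i].contig,
                                                     calls[i].start))
    uf = _UnionFind(len(calls))
    for oi, i in enumerate(order):
        for j in order[oi + 1 :]:
            if calls[j].svtype != calls[i].svtype or calls[j].contig != calls[i].contig:
                break
            if calls[j].start - calls[i].start > max_dist:
                break
            if _sv_link(calls[i], calls[j], max_dist, min_overlap):
                uf.union(i, j)

    clusters: dict[int, list[VariantCall]] = defaultdict(list)
    cluster_members: dict[int, list[int]] = defaultdict(list)
    for i, v in enumerate(calls):
        root = uf.find(i)
        clusters[root].append(v)
        cluster_members[root].append(i)

    rows = []
    for root in sorted(clusters, key=lambda r: (clusters[r][0].contig,
                                                min(v.start for v in clusters[r]),
                                                clusters[r][0].svtype)):
        members = clusters[root]
        row = {
            "contig": members[0].contig,
            "start": min(v.start for v in members),
            "end": max(v.end for v in members),
            "svtype": members[0].svtype,
            "svlen": int(np.median([abs(v.svlen) for v in members])),
            "precise": all(v.precise for v in members),
            "n_samples": len({v.sample_id for v in members}),
            "members": tuple(sorted(cluster_members[root])),
        }
        present = {v.sample_id for v in members}
        for s in samples:
            row[f"in_{s}"] = s in present
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["contig", "start", "svtype"], ignore_index=True) if len(df) else df


def sv_true_positives(
    cell_svs: list[VariantCall],
    bulk_svs: list[VariantCall],
    max_dist: int = 200,
    min_overlap: float = 0.10,
    cell_sample: str | None = None,
    bulk_sample: str = "bulk",
) -> EvalResult:
    """Per-type precision/sensitivity of cell SVs against bulk SVs.

    A cell call is a true positive iff it merges with a bulk call; the
    sensitivity denominator is the full bulk call set of that type.
    """
    cell_sample = cell_sample or (cell_svs[0].sample_id if cell_svs else "cell")
    merged = merge_svs([cell_svs, bulk_svs], max_dist, min_overlap)
    per_type: dict[str, EvalResult] = {}
    tp = fp = fn = 0
    for svtype in SV_TYPES:
        n_cell = sum(1 for v in cell_svs if v.svtype == svtype)
        n_bulk = sum(1 for v in bulk_svs if v.svtype == svtype)
        if len(merged):
            sub = merged[merged["svtype"] == svtype]
            both = sub[sub[f"in_{cell_sample}"] & sub.get(f"in_{bulk_sample}", False)]
            # count matched calls, not clusters; in merge_svs' member indices
            # the cell calls precede the bulk calls
            n_cell_calls = len([v for v in cell_svs if v.is_sv])
            matched_cell = matched_bulk = 0
            for members in both["members"]:
                matched_cell += sum(1 for m in members if m < n_cell_calls)
                matched_bulk += sum(1 for m in members if m >= n_cell_calls)
        else:
            matched_cell = matched_bulk = 0
        t = EvalResult(tp=matched_cell, fp=n_cell - matched_cell,
                       fn=n_bulk - matched_bulk)
        per_type[svtype] = t
        tp += t.tp
        fp += t.fp
        fn += t.fn
    result = EvalResult(tp=tp, fp=fp, fn=fn)
    result.per_type = per_type
    return result


def somatic_sv_filter(
    merged: pd.DataFrame,
    clone_samples: dict[str, list[str]],
    bulk_sample: str = "bulk",
) -> pd.DataFrame:
    """PRECISE merged events present in >=2 cells of one clone, absent from
    every cell of the other clone(s) and from bulk."""
    if not len(merged):
        return merged
    keep_rows = []
    for _, row in merged.iterrows():
        if not row["precise"]:
            continue
        bulk_col = f"in_{bulk_sample}"
        if bulk_col in row.index and row[bulk_col]:
            continue
        for clone, cells in clone_samples.items():
            n_here = sum(bool(row.get(f"in_{c}", False)) for c in cells)
            n_other = sum(
                bool(row.get(f"in_{c}", False))
                for oc, ocells in clone_samples.items()
                if oc != clone
                for c in ocells
            )
            if n_here >= 2 and n_other == 0:
                r = row.copy()
                r["clone"] = clone
                keep_rows.append(r)
                break
    return pd.DataFrame(keep_rows).reset_index(drop=True)
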