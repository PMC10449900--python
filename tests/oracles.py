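"""Independent reference implementations used only by the tests.

These are deliberately written with a different algorithmic approach from the
package code (full dynamic programming, brute-force loops, transitive
closure) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Smith-Waterman self-comparison oracle for chimera detection
# ---------------------------------------------------------------------------
# Scoring: match +1, mismatch/gap -9.  A local alignment has positive score
# iff its identity (matches / alignment columns) exceeds 0.9, so a score
# threshold well above the random-noise ceiling (longest chance exact match
# in a <=2 kb read is ~11 bp) decides "secondary self-hit at >90% identity"
# without any seeding or banding.

MATCH = 1
PENALTY = -9
ORACLE_MIN_SCORE = 50


@njit(cache=True)
def _sw(a, b, diag_exclude):
    """Best local alignment of int8 arrays a vs b.

    Cells with |i - j| < diag_exclude are forced to zero (used to remove the
    trivial main-diagonal self-match); pass 0 to disable.

    Returns (score, a_start, a_end, b_start, b_end) with half-open ends.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    D = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if diag_exclude > 0:
                d = i - j
                if -diag_exclude < d < diag_exclude:
                    continue
            s = MATCH if a[i - 1] == b[j - 1] else PENALTY
            sc = H[i - 1, j - 1] + s
            d_ = 1
            up = H[i - 1, j] + PENALTY
            if up > sc:
                sc = up
                d_ = 2
            left = H[i, j - 1] + PENALTY
            if left > sc:
                sc = left
                d_ = 3
            if sc <= 0:
                continue
            H[i, j] = sc
            D[i, j] = d_
            if sc > best:
                best = sc
                bi = i
                bj = j
    # traceback for start coordinates
    i, j = bi, bj
    while D[i, j] != 0:
        d_ = D[i, j]
        if d_ == 1:
            i -= 1
            j -= 1
        elif d_ == 2:
            i -= 1
        else:
            j -= 1
    return best, i, bi, j, bj


_ENC = np.zeros(128, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def sw_self_verdict(seq: str, min_score: int = ORACLE_MIN_SCORE,
                    diag_exclude: int = 50):
    """(verdict, junctions) by exhaustive local self-comparison.

    Forward: seq vs seq with the main diagonal band removed.
    Reverse-complement: seq vs revcomp(seq), unrestricted.
    """
    codes = _encode(seq)
    rc_codes = _encode(_revcomp(seq))
    n = len(seq)

    junctions = []
    fscore, fa0, fa1, fb0, fb1 = _sw(codes, codes, diag_exclude)
    fwd = fscore >= min_score
    if fwd:
        (a0, a1), (b0, b1) = sorted([(fa0, fa1), (fb0, fb1)])
        junctions.append((a1 + b0) // 2)

    rscore, ra0, ra1, rb0, rb1 = _sw(codes, rc_codes, 0)
    rc = rscore >= min_score
    if rc:
        # map the rc-space interval back onto the read
        bs, be = n - rb1, n - rb0
        (a0, a1), (b0, b1) = sorted([(ra0, ra1), (bs, be)])
        junctions.append((a1 + b0) // 2)

    if fwd and rc:
        verdict = "COMPLEX"
    elif rc:
        verdict = "INVERSION"
    elif fwd:
        verdict = "DUPLICATION"
    else:
        verdict = "CLEAN"
    return verdict, sorted(junctions)


# ---------------------------------------------------------------------------
# brute-force per-base coverage
# ---------------------------------------------------------------------------


def brute_force_depth(alignments, contig_lengths):
    """Per-base depth by incrementing every covered position in a loop."""
    depth = {c: np.zeros(ln, dtype=np.int64) for c, ln in contig_lengths.items()}
    for a in alignments:
        for pos in range(a.ref_start, min(a.ref_end, contig_lengths[a.contig])):
            depth[a.contig][pos] += 1
    return depth


# ---------------------------------------------------------------------------
# transitive-closure SV merge oracle
# ---------------------------------------------------------------------------


def sv_link_oracle(a, b, max_dist=200, min_overlap=0.10):
    """Plain restatement of the pairwise linkage rule."""
    if a.svtype != b.svtype or a.contig != b.contig:
        return False
    if abs(a.start - b.start) > max_dist:
        return False
    if a.svtype == "INS":
        la, lb = abs(a.svlen), abs(b.svlen)
        if max(la, lb) == 0:
            return False
        return min(la, lb) / max(la, lb) >= min_overlap
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return False
    return (overlap / (a.end - a.start) >= min_overlap
            and overlap / (b.end - b.start) >= min_overlap)


def merge_clusters_oracle(calls, max_dist=200, min_overlap=0.10):
    """Partition of call indices by transitive closure over all O(n^2) pairs."""
    n = len(calls)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if sv_link_oracle(calls[i], calls[j], max_dist, min_overlap):
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack = [i]
        seen[i] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(frozenset(comp))
    return frozenset(clusters)


# ---------------------------------------------------------------------------
# brute-force 1-D single linkage
# ---------------------------------------------------------------------------


def single_linkage_oracle(values, tol):
    """Transitive closure of |x - y| <= tol over all pairs."""
    n = len(values)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if abs(values[i] - values[j]) <= tol:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack = [i]
        seen[i] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(values[u])
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(tuple(sorted(comp)))
    return sorted(clusters)


# ---------------------------------------------------------------------------
# TR confidence-rule oracle
# ---------------------------------------------------------------------------


def tr_rules(genotype):
    """Truth value of each confidence rule, evaluated directly."""
    g = genotype
    if len(g.alleles) == 2:
        rule_i = min(g.allele_counts) >= 5
    else:
        rule_i = g.allele_counts[0] >= 10
    rule_ii = all(c <= 2 for c in g.other_cluster_sizes)
    spanning = sum(g.allele_counts) + sum(g.other_cluster_sizes)
    rule_iii = (sum(g.allele_counts) / spanning >= 0.90) if spanning else True
    rule_iv = g.total_coverage <= 50
    return (rule_i, rule_ii, rule_iii, rule_iv)


def tr_filter_oracle(genotype):
    """PASS or FAIL(first violated rule), straight from the rule list."""
    names = ("i", "ii", "iii", "iv")
    for ok, name in zip(tr_rules(genotype), names):
        if not ok:
            return f"FAIL({name})"
    return "PASS"


# ---------------------------------------------------------------------------
# somatic SNV set-logic oracle
# ---------------------------------------------------------------------------


def somatic_snv_oracle(cells_by_clone, bulk, mask_intervals):
    """Direct predicate evaluation over every variant seen in any cell."""
    bulk_keys = {v.site_key() for v in bulk if not v.is_sv}
    out = []
    for clone, cells in cells_by_clone.items():
        if len(cells) < 2:
            continue
        seen = {}
        for cell in cells:
            for v in cell:
                if not v.is_sv:
                    seen.setdefault(v.site_key(), v)
        for key, v in seen.items():
            n_here = sum(
                1 for cell in cells if key in {w.site_key() for w in cell}
            )
            n_other = sum(
                1
                for oc, ocells in cells_by_clone.items()
                if oc != clone
                for cell in ocells
                if key in {w.site_key() for w in cell if not w.is_sv}
            )
            masked = any(
                c == v.contig and s <= v.start < e for c, s, e in mask_intervals
            )
            if (n_here >= 2 and key not in bulk_keys and n_other == 0
                    and v.svtype == "SNV" and not masked):
                out.append((v, clone))
    return sorted(out, key=lambda t: (t[0].contig, t[0].start, t[0].alt))
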