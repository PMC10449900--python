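"""Mitochondrial heteroplasmy detection from per-sample pileups.

A heteroplasmic site is reported when every cell of one clone shows the
same alternate allele at a frequency above ``min_freq`` while all other
samples (cells of other clones and bulk) stay below a small background
threshold. Sites where a required sample lacks coverage are marked
UNTESTABLE rather than absent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASES = "ACGT"


def heteroplasmy_scan(
    pileups: dict[str, np.ndarray],
    ref_seq: str,
    clone_samples: dict[str, list[str]],
    bulk_sample: str = "bulk",
    min_cov: int = 10,
    min_freq: float = 0.30,
    background: float = 0.05,
) -> pd.DataFrame:
    """Scan base-count pileups (positions x ACGT) for clone-confined sites.

    Returns a table with one row per (position, alt, clone) candidate and
    per-sample frequencies; ``status`` is PASS or UNTESTABLE.
    """
    samples = list(pileups)
    L = len(ref_seq)
    ref_idx = np.array([BASES.index(b) for b in ref_seq], dtype=np.int64)
    cov = {s: pileups[s].sum(axis=1) for s in samples}
    freq = {
        s: pileups[s] / np.maximum(cov[s], 1)[:, None] for s in samples
    }

    rows = []
    pos_grid = np.arange(L)
    for clone, cells in clone_samples.items():
        others = [s for s in samples if s not in cells]  # other clones + bulk
        for b in range(4):
            non_ref = ref_idx != b
            cand = non_ref.copy()
            for c in cells:
                cand &= (cov[c] >= min_cov) & (freq[c][:, b] >= min_freq)
            if not cand.any():
                continue
            ok = np.ones(L, dtype=bool)
            untestable = np.zeros(L, dtype=bool)
            for o in others:
                low_cov = cov[o] < min_cov
                untestable |= low_cov
                ok &= freq[o][:, b] < background
            for pos in pos_grid[cand].tolist():
                status = "UNTESTABLE" if untestable[pos] else (
                    "PASS" if ok[pos] else None
                )
                if status is None:
                    continue
                row = {
                    "pos": pos,
                    "ref": ref_seq[pos],
                    "alt": BASES[b],
                    "clone": clone,
                    "status": status,
                }
                for s in samples:
                    row[f"freq_{s}"] = float(freq[s][pos, b])
                    row[f"cov_{s}"] = int(cov[s][pos])
                rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["pos", "alt", "clone"], ignore_index=True)
    return df
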