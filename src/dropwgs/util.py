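"""Small sequence helpers used throughout the simulator."""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random nucleotide sequence of length ``n``."""
    return rng.choice(_BASES, size=n).tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutate_base(rng: np.random.Generator, base: str) -> str:
    """A uniformly chosen base different from ``base``."""
    choices = [b for b in "ACGT" if b != base.upper()]
    return choices[rng.integers(0, 3)]


def apply_read_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Apply sequencing errors at per-base ``rate``; returns (sequence, n_errors).

    Error events are 80% substitutions, 10% single-base insertions and 10%
    single-base deletions, crudely matching the small-indel-dominated error
    profile of consensus long reads.
    """
    n = len(seq)
    if rate <= 0.0 or n == 0:
        return seq, 0
    n_err = rng.binomial(n, rate)
    if n_err == 0:
        return seq, 0
    positions = np.sort(rng.choice(n, size=n_err, replace=False))
    kinds = rng.choice(3, size=n_err, p=[0.8, 0.1, 0.1])  # 0 sub, 1 ins, 2 del
    out: list[str] = []
    prev = 0
    for pos, kind in zip(positions.tolist(), kinds.tolist()):
        out.append(seq[prev:pos])
        if kind == 0:
            out.append(mutate_base(rng, seq[pos]))
            prev = pos + 1
        elif kind == 1:
            out.append("ACGT"[rng.integers(0, 4)])
            prev = pos  # insertion before pos; original base kept
        else:
            prev = pos + 1  # deletion
    out.append(seq[prev:])
    return "".join(out), int(n_err)
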