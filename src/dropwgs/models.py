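"""Core record types shared across the simulator and the analysis stages.

Coordinates are 0-based half-open everywhere in memory; conversion to the
1-based conventions of VCF and PAF happens only in :mod:`dropwgs.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


SV_TYPES = ("DEL", "INS", "DUP", "INV")


@dataclass(frozen=True)
class VariantCall:
    """A normalized SNV/indel or structural-variant record.

    ``start``/``end`` delimit the affected reference interval: a single base
    for an SNV, the deleted/duplicated/inverted interval for a DEL/DUP/INV,
    and a zero-length interval at the insertion point for an INS.
    """

    contig: str
    start: int
    end: int
    ref: str
    alt: str
    svtype: str  # SNV | INDEL | DEL | INS | DUP | INV
    svlen: int = 0
    precise: bool = True
    sample_id: str = ""
    haplotype: int = 0  # 0 = unphased/unknown, 1 or 2 for planted germline

    @property
    def pos(self) -> int:
        """1-based position, as printed in VCF."""
        return self.start + 1

    @property
    def is_sv(self) -> bool:
        return self.svtype in SV_TYPES

    def site_key(self) -> tuple:
        """Identity used for SNV/indel set intersection (allele identity)."""
        return (self.contig, self.start, self.ref, self.alt)

    def __post_init__(self):
        if self.svtype == "SNV" and not (len(self.ref) == 1 == len(self.alt)):
            raise ValueError(f"SNV must have single-base alleles: {self.ref}>{self.alt}")
        if self.svtype in SV_TYPES and self.svlen == 0:
            raise ValueError(f"SV record of type {self.svtype} requires nonzero svlen")


@dataclass(frozen=True)
class RepeatLocus:
    """A tandem-repeat locus on the reference."""

    contig: str
    start: int
    end: int
    unit: str
    ref_copies: int
    # signed length difference of each haplotype allele vs the reference (bp)
    hap_diffs: tuple[int, int] = (0, 0)

    @property
    def unit_size(self) -> int:
        return len(self.unit)

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.unit}"


@dataclass
class Fragment:
    """A genomic fragment from one cell, possibly assigned to a droplet.

    Coordinates live on the haplotype sequence (which tiles exactly); the
    reference projection is recovered through the genome's block map. For the
    circular mitochondrial contig ``end`` may exceed the contig length,
    meaning the fragment wraps past the origin.
    """

    cell_id: str
    contig: str
    start: int
    end: int
    haplotype: str  # "1" | "2" | "mito"
    droplet_id: int | None = None
    mito_alt: bool = False  # carries the heteroplasmic alternate allele

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChimeraEvent:
    """A chimera formed on one amplified copy of a fragment."""

    kind: str  # INVERSION | DUPLICATION | INTERMOLECULAR
    copy_index: int
    breakpoint: int = 0  # position within the molecule (kind-specific)
    dup_start: int = 0
    dup_end: int = 0
    partner: Fragment | None = None
    partner_breakpoint: int = 0


@dataclass
class Amplicon:
    """One fragment together with its amplification outcome."""

    fragment: Fragment
    copy_number: int
    chimera_events: list[ChimeraEvent] = field(default_factory=list)


@dataclass
class ReadRecord:
    """A simulated long read with its truth provenance.

    ``truth_segments`` is an ordered list of ``(contig, start, end, strand)``
    reference intervals; their lengths sum to the read length before
    sequencing errors are applied.
    """

    read_id: str
    sequence: str
    truth_segments: list[tuple[str, int, int, str]]
    is_chimeric: bool = False
    chimera_type: str = "NONE"  # NONE|INVERSION|DUPLICATION|INTERMOLECULAR|COMPLEX
    cell_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned segment of a read on the reference."""

    read_id: str
    read_length: int
    read_start: int
    read_end: int
    strand: str  # '+' | '-'
    contig: str
    ref_start: int
    ref_end: int
    identity: float = 1.0

    @property
    def aligned_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class SelfHit:
    """A non-trivial alignment of a read against itself."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # "forward" | "rc"
    identity: float
    length: int

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.orientation == "forward" and (self.a_start, self.a_end) == (
            self.b_start,
            self.b_end,
        ):
            raise ValueError("trivial full forward self-match is excluded")


@dataclass
class ChimeraReport:
    read_id: str
    read_length: int
    hits: list[SelfHit]
    verdict: str  # CLEAN | INVERSION | DUPLICATION | COMPLEX
    junctions: list[int]
    subread_intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class EvalResult:
    """Precision/sensitivity bookkeeping against a bulk truth set."""

    tp: int
    fp: int
    fn: int
    per_type: dict[str, "EvalResult"] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0


@dataclass
class TRGenotype:
    """Per-locus repeat genotype from spanning-read length differences."""

    locus: RepeatLocus
    diffs: list[int]
    alleles: list[int]  # 1 (hom) or 2 (het) cluster medians, ascending
    allele_counts: list[int]
    other_cluster_sizes: list[int]
    total_coverage: int
    status: str = "UNGENOTYPED"  # PASS | FAIL(rule) | UNGENOTYPED

    @property
    def other_allele_reads(self) -> int:
        return sum(self.other_cluster_sizes)

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2
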