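"""File-format boundaries: FASTA/FASTQ via Biopython, VCF via pysam, PAF and
BED as the plain TSV line formats they are.

All coordinates are converted between the package's 0-based half-open
convention and the 1-based conventions of VCF here and only here.
"""

from __future__ import annotations

import os
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dropwgs.models import AlignmentRecord, ReadRecord, RepeatLocus, VariantCall


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[ReadRecord], path: str | Path, qv: int = 20) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{chr(qv + 33) * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq), [])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_paf(
    alignments: list[AlignmentRecord],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    """Standard 12 mandatory PAF columns; matches = aligned length (truth)."""
    with open(path, "w") as fh:
        for a in alignments:
            alen = a.ref_end - a.ref_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.read_id, a.read_length, a.read_start, a.read_end,
                        a.strand, a.contig, contig_lengths[a.contig],
                        a.ref_start, a.ref_end, alen, alen, 60,
                    )
                )
                + "\n"
            )


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            nmatch, alen = int(f[9]), int(f[10])
            out.append(
                AlignmentRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4], f[5],
                    int(f[7]), int(f[8]),
                    identity=nmatch / alen if alen else 0.0,
                )
            )
    return out


def write_bed(
    intervals: list[tuple], path: str | Path
) -> None:
    """BED3 or BED4 (optional 4th column, e.g. the repeat unit)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            row = (f[0], int(f[1]), int(f[2]), *f[3:])
            out.append(row)
    return out


def write_tr_bed(loci: list[RepeatLocus], path: str | Path) -> None:
    write_bed([(t.contig, t.start, t.end, t.unit) for t in loci], path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _vcf_header(contig_lengths: dict[str, int], sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Signed length of structural variant")
    header.info.add("PRECISE", 0, "Flag", "Breakpoints are base-pair resolved")
    header.info.add("IMPRECISE", 0, "Flag", "Breakpoints are not base-pair resolved")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    return header


def write_vcf(
    calls: list[VariantCall],
    path: str | Path,
    contig_lengths: dict[str, int],
    sample_id: str,
) -> None:
    header = _vcf_header(contig_lengths, sample_id)
    calls = sorted(calls, key=lambda v: (v.contig, v.start, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in calls:
            if v.is_sv:
                rec = vcf.new_record(
                    contig=v.contig, start=v.start,
                    stop=max(v.end, v.start + 1), alleles=("N", v.alt),
                )
                rec.info["SVTYPE"] = v.svtype
                rec.info["SVLEN"] = v.svlen
                rec.info["PRECISE" if v.precise else "IMPRECISE"] = True
            else:
                rec = vcf.new_record(
                    contig=v.contig, start=v.start, alleles=(v.ref, v.alt)
                )
            rec.samples[sample_id]["GT"] = (0, 1)
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples), "")
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else ""
            svtype = rec.info.get("SVTYPE")
            if svtype:
                svlen = int(rec.info["SVLEN"])
                end = rec.start if svtype == "INS" else rec.start + abs(svlen)
                out.append(
                    VariantCall(
                        rec.contig, rec.start, end, "N", alt, svtype,
                        svlen=svlen, precise="PRECISE" in rec.info,
                        sample_id=sample,
                    )
                )
            else:
                ref = rec.ref
                svtype = "SNV" if len(ref) == 1 == len(alt) else "INDEL"
                out.append(
                    VariantCall(
                        rec.contig, rec.start, rec.start + len(ref), ref, alt,
                        svtype, sample_id=sample,
                    )
                )
    return out


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
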