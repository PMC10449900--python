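"""End-to-end orchestration: simulate -> chimera filter -> coverage ->
variant evaluation -> somatic filters -> heteroplasmy -> TR genotyping.

Stages run in dependency order; each writes its artifacts under the output
directory and contributes a section to a machine-readable summary
(``summary.json``). Re-running with an identical configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from dropwgs import chimera, coverage, io, mito, tr, variants
from dropwgs.config import RunConfig, stage_rng
from dropwgs.sim.genome import MITO, simulate_genome
from dropwgs.sim.encapsulate import cell_rng, fragment_and_encapsulate
from dropwgs.sim.amplify import amplify
from dropwgs.sim.reads import generate_reads
from dropwgs.sim.callsets import BULK, build_truth, emit_callsets
from dropwgs.sim.pileups import simulate_mito_pileups
from dropwgs.sim.trreads import simulate_tr_read_diffs

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate",
    "filter-chimeras",
    "coverage",
    "eval-snv",
    "eval-sv",
    "somatic-snv",
    "somatic-sv",
    "heteroplasmy",
    "genotype-tr",
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the summary."""
    enabled = [s for s in STAGE_ORDER if s in cfg.stages]
    downstream = [s for s in enabled if s != "simulate"]
    if downstream and "simulate" not in enabled:
        raise RuntimeError(
            f"stage {downstream[0]!r} requires upstream artifacts from 'simulate'"
        )
    outdir = io.ensure_dir(cfg.outdir)
    sim = cfg.sim
    summary: dict = {"seed": cfg.seed, "stages": enabled}

    genome = simulate_genome(sim)
    contig_lengths = {c: len(s) for c, s in genome.contigs.items()}
    truth = build_truth(genome, sim)

    reads_by_cell: dict[str, list] = {}
    alns_by_cell: dict[str, list] = {}
    callsets: dict[str, list] = {}

    if "simulate" in enabled:
        logger.info("[simulate] genome %s bp + %s bp mito",
                    sim.genome_length, sim.mito_length)
        io.write_fasta(genome.contigs, outdir / "reference.fa")
        io.write_tr_bed(genome.tr_loci, outdir / "tr_loci.bed")
        io.write_bed(genome.repeat_mask(), outdir / "repeat_mask.bed")
        for cell in sim.cell_ids:
            frags = fragment_and_encapsulate(genome, cell, sim)
            amps = amplify(frags, sim, cell_rng(sim, "amplify", cell))
            reads, alns = generate_reads(
                amps, genome, sim, cell_rng(sim, "reads", cell),
                max_reads=cfg.reads_per_cell,
            )
            reads_by_cell[cell] = reads
            alns_by_cell[cell] = alns
            io.write_fastq(reads, outdir / f"{cell}.fastq", qv=sim.read_qv)
            io.write_paf(alns, outdir / f"{cell}.truth.paf", contig_lengths)
        callsets = emit_callsets(genome, truth, sim,
                                 stage_rng(sim.seed, "callsets"))
        for sample, calls in callsets.items():
            io.write_vcf(calls, outdir / f"{sample}.vcf", contig_lengths, sample)
        summary["simulate"] = {
            "n_cells": len(sim.cell_ids),
            "n_germline_variants": len(genome.haplotype_variants),
            "n_tr_loci": len(genome.tr_loci),
            "n_somatic_per_clone": {
                c: len(v) for c, v in sorted(genome.clone_somatic.items())
            },
            "reads_per_cell": {c: len(reads_by_cell[c]) for c in sim.cell_ids},
        }

    if "filter-chimeras" in enabled:
        logger.info("[filter-chimeras] screening %d cells", len(reads_by_cell))
        section = {}
        for cell, reads in reads_by_cell.items():
            passed, removed, stats = chimera.filter_reads(
                reads, k=cfg.kmer_size, min_identity=cfg.min_identity,
                min_hit_len=cfg.min_hit_len,
            )
            io.write_fastq(passed, outdir / f"{cell}.clean.fastq", qv=sim.read_qv)
            io.write_fastq(removed, outdir / f"{cell}.removed.fastq", qv=sim.read_qv)
            _write_report(stats["reports"], outdir / f"{cell}.chimera_report.tsv")
            section[cell] = {
                "pass_fraction": stats["pass_fraction"],
                "verdicts": stats["verdicts"],
            }
        summary["filter_chimeras"] = section

    if "coverage" in enabled:
        section = {}
        for cell, alns in alns_by_cell.items():
            profile = coverage.binned_coverage(alns, cfg.bin_size, contig_lengths)
            section[cell] = {
                "breadth": coverage.breadth(alns, contig_lengths),
                "coverage_sd": coverage.coverage_sd(profile.per_base),
                "frac_reads_high_cov": coverage.frac_reads_high_cov(
                    alns, profile, cfg.high_cov_threshold
                ),
                "aligned_n50": chimera.aligned_n50(alns) if alns else 0,
            }
        summary["coverage"] = section

    snvs = {s: [v for v in calls if not v.is_sv] for s, calls in callsets.items()}
    svs = {s: [v for v in calls if v.is_sv] for s, calls in callsets.items()}

    if "eval-snv" in enabled:
        section = {}
        for cell in sim.cell_ids:
            res = variants.evaluate_snvs(snvs[cell], snvs[BULK])
            section[cell] = {
                "tp": res.tp, "fp": res.fp, "fn": res.fn,
                "precision": res.precision, "sensitivity": res.sensitivity,
            }
        summary["eval_snv"] = section

    if "eval-sv" in enabled:
        section = {}
        for cell in sim.cell_ids:
            res = variants.sv_true_positives(
                svs[cell], svs[BULK], cfg.sv_max_dist, cfg.sv_min_overlap,
                cell_sample=cell,
            )
            section[cell] = {
                "precision": res.precision,
                "sensitivity": res.sensitivity,
                "per_type": {
                    t: {"precision": r.precision, "sensitivity": r.sensitivity}
                    for t, r in res.per_type.items()
                },
            }
        summary["eval_sv"] = section

    clone_cells = {
        clone: [c for c in sim.cell_ids if sim.clone_of(c) == clone]
        for clone in sim.clones
    }

    if "somatic-snv" in enabled:
        cells_by_clone = {
            clone: [snvs[c] for c in cells] for clone, cells in clone_cells.items()
        }
        candidates = variants.somatic_snv_filter(
            cells_by_clone, snvs[BULK], genome.repeat_mask()
        )
        _write_candidates(candidates, outdir / "somatic_snvs.tsv")
        summary["somatic_snv"] = {
            "n_candidates": len(candidates),
            "per_clone": {
                clone: sum(1 for _, c in candidates if c == clone)
                for clone in sim.clones
            },
        }

    if "somatic-sv" in enabled:
        merged = variants.merge_svs(
            [svs[s] for s in [BULK, *sim.cell_ids]],
            cfg.sv_max_dist, cfg.sv_min_overlap,
        )
        som = variants.somatic_sv_filter(merged, clone_cells, bulk_sample=BULK)
        if len(som):
            som.drop(columns=["members"]).to_csv(
                outdir / "somatic_svs.tsv", sep="\t", index=False
            )
        else:
            (outdir / "somatic_svs.tsv").write_text("")
        summary["somatic_sv"] = {
            "n_merged_events": int(len(merged)),
            "n_candidates": int(len(som)),
        }

    if "heteroplasmy" in enabled:
        pileups = simulate_mito_pileups(
            genome, sim, stage_rng(sim.seed, "pileups"), mean_depth=cfg.mito_depth
        )
        table = mito.heteroplasmy_scan(
            pileups, genome.contigs[MITO], clone_cells, bulk_sample=BULK,
            min_cov=cfg.het_min_cov, min_freq=cfg.het_min_freq,
            background=cfg.het_background,
        )
        table.to_csv(outdir / "heteroplasmy.tsv", sep="\t", index=False)
        passing = table[table["status"] == "PASS"] if len(table) else table
        summary["heteroplasmy"] = {
            "n_sites": int(len(passing)),
            "sites": [
                {"pos": int(r["pos"]), "alt": r["alt"], "clone": r["clone"]}
                for _, r in passing.iterrows()
            ],
        }

    if "genotype-tr" in enabled:
        rng = stage_rng(sim.seed, "pileups", 1)
        bulk_diffs = simulate_tr_read_diffs(
            genome, sim, rng, mean_cov=cfg.tr_bulk_cov, allele_dropout=0.0
        )
        bulk_gt = _genotype_all(genome, bulk_diffs, cfg)
        section = {"bulk_pass_loci": sum(g.status == "PASS" for g in bulk_gt.values())}
        for cell in sim.cell_ids:
            diffs = simulate_tr_read_diffs(
                genome, sim, cell_rng(sim, "pileups", cell),
                mean_cov=cfg.tr_cell_cov, allele_dropout=cfg.tr_allele_dropout,
            )
            cell_gt = _genotype_all(genome, diffs, cfg)
            section[cell] = tr.concordance(cell_gt, bulk_gt, tol=cfg.tr_tolerance)
        summary["tr"] = section

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _genotype_all(genome, diffs_by_locus, cfg: RunConfig):
    out = {}
    for locus in genome.tr_loci:
        diffs, total = diffs_by_locus[locus.name]
        g = tr.genotype_locus(diffs, locus, total_coverage=total)
        tr.confidence_filter(g)
        out[locus.name] = g
    return out


def _write_report(reports, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tverdict\tn_junctions\tjunction_positions\n")
        for r in reports:
            pos = ",".join(str(j) for j in r.junctions)
            fh.write(f"{r.read_id}\t{r.verdict}\t{len(r.junctions)}\t{pos}\n")


def _write_candidates(candidates, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tclone\n")
        for v, clone in candidates:
            fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{clone}\n")
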