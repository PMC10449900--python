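# Methods

Models, parameter choices, numerical conventions and known limitations of the
`dropwgs` simulator and analysis pipeline.

## Coordinate and seeding conventions

All coordinates are 0-based, half-open internally; 1-based coordinates appear
only at file boundaries (`io.py`: VCF POS, PAF, BED follow their format
conventions). A single master seed drives everything: each stage derives an
independent child generator via `numpy.random.SeedSequence(seed,
spawn_key=(stage, index))` (`config.stage_rng`), and per-cell generators key
the index by `crc32(cell_id)` so per-cell output is independent of the order
in which cells are processed. Two runs with the same configuration are
byte-identical, including `summary.json`.

## Genome simulation (`sim/genome.py`)

A diploid nuclear contig (default 10 Mb) plus a circular mitochondrial contig
(16.5 kb). Planted features, all placed without overlap:

* **Germline SNVs** at rate 1e-3 per base, each assigned to one haplotype.
* **Germline SVs** — deletions, insertions, duplications, inversions (default
  40/40/10/10) with a two-mode length mixture: 70% ALU-like (normal around
  300 bp) and 30% LINE-like (normal around 6 kb). Insertions copy a reference
  source interval (mobile-element-like) so that every read base retains
  reference provenance; this is what makes exact truth alignments possible
  for insertion-spanning reads.
* **Tandem repeat loci** (default 100; unit sizes 1–6 bp) kept ≥200 bp from
  SV breakpoints, with per-haplotype repeat-length differences planted for
  genotyping truth. TR loci form the repeat mask used by the somatic filter.
* **Two somatic clones** (A, B) of three cells each, with 30 clone-private
  somatic SNVs per clone, plus one heteroplasmic mitochondrial site carried
  by clone B at alternate-allele fraction 0.5.

Each haplotype is represented as a block map (reference-interval and
insertion blocks), which supports exact projection of haplotype intervals to
reference intervals and back.

## Fragmentation, droplets and amplification (`sim/encapsulate.py`, `sim/amplify.py`)

Haplotypes are cut into fragments with normal length (mean 9 kb, sd 1.5 kb,
min 500 bp) that tile each haplotype exactly; mitochondrial copies enter as
circularly wrapped fragments. Fragments are assigned to droplets uniformly
(Poisson occupancy across 50,000 droplets) in dMDA mode; bulk MDA is one
common reaction.

Amplification gain per fragment is lognormal with `mu = ln(mean) − sigma²/2`
so the mean is the configured `mean_copies`:

* **MDA**: `sigma = 2`, unclipped — a heavy upper tail in which a few
  fragments capture most of the reaction.
* **dMDA**: `sigma = 0.5`, clipped to ≥1 copy, and the total copy number per
  droplet is capped (`dmda_cap_copies`), modelling reagent exhaustion inside
  a picoliter compartment.

Chimera formation happens per amplified copy: fold-back inversions (the
molecule continues as the reverse complement of its own prefix), tandem
duplications (a 200–2000 bp window repeated), and, in droplets with multiple
fragments, intermolecular joins with a droplet partner. Default rates are
0.20/0.10 per amplicon and 0.02 per droplet.

## Read generation (`sim/reads.py`)

One read per amplified copy, optionally subsampled without replacement to a
target count. The molecule is assembled as an ordered list of haplotype
pieces (chimera events reshape this list), projected to reference
truth-segments, then sequencing errors are applied at 1% per base (80%
substitutions, 10% 1-bp insertions, 10% 1-bp deletions — crudely matching a
consensus long-read error profile). Truth segments and PAF truth alignments
use **pre-error** coordinates; read-segment offsets therefore drift by up to
the number of indel errors relative to the error-bearing sequence. Fold-back
segments carry strand `−` with mirrored intervals.

## Chimera screen (`chimera.py`)

A BLAST-against-self search: k-mer seeding (k = 15; k-mers occurring more
than 10 times are masked), position-major chaining in diagonal bands (band
50, maximum seed gap 500 — a seed may extend any open chain within the band,
which keeps one alignment intact when a 1-bp indel shifts later seeds to a
neighbouring diagonal), and validation of each chained extent by global
alignment (edlib); identity is matching columns over alignment columns. A
hit needs identity ≥0.90 over ≥100 bp. Forward off-diagonal self-hits yield
verdict `DUPLICATION`, reverse-complement hits `INVERSION`, both `COMPLEX`;
the junction estimate is the midpoint `(a_end + b_start) // 2` between the
paired intervals. The trivial main-diagonal match and the mirror symmetry of
reverse-complement hits are excluded by construction. `split_read` cuts a
flagged read at its junctions with 50 bp trims; `filter_reads` removes any
non-CLEAN read.

Note the screen flags *intramolecular* chimeras only; intermolecular joins
between distant fragments share no self-similarity and are invisible to it —
in the simulator's accounting they stay in the reads and degrade SV
precision, as they do in real data. A read spanning the circular
mitochondrial origin is collinear, not chimeric.

## Coverage metrics (`coverage.py`)

Binned coverage (default 5 kb bins) from truth alignments: per-bin mean depth
with the final partial bin normalized by its true length. `coverage_sd` is
the per-base standard deviation of depth; `breadth` is the fraction of
reference bases covered ≥1×; `frac_reads_high_cov` is the fraction of reads
whose midpoint bin has depth ≥ the threshold (the "≥200×" convention — a bin
at exactly the threshold counts as high-coverage). Downsampling is uniform
without replacement.

The pre-registered MDA vs dMDA comparison (`study.amplification_contrast`)
fixes 1 Mb genome, 6,000 matched reads, gain mean 100, dMDA cap 200; at
these conditions the minimum total MDA copy count over 300,000 sampled
replicates was ~7,050, so the matched draw never fails, and the mean depth
(~54×) keeps the 200× bin threshold reachable for MDA hotspots.

## Variant call sets and evaluation (`sim/callsets.py`, `variants.py`)

The bulk call set is the full germline truth. Each cell's call set starts
from germline plus its clone's somatic SNVs, then loses each variant
independently with the allelic-dropout probability (default 0.8), and gains
false positives: SNVs as a Poisson process per reference base and false SVs
as per-type Poisson counts per cell, inversion-dominated (defaults
16.3/1.8/1.0/0.92 for INV/INS/DUP/DEL), mostly IMPRECISE (80%), while true
SVs are mostly PRECISE (90%).

Evaluation normalizes indels (allele trimming plus left-alignment to a
canonical representation) and matches by site key. The somatic SNV filter
keeps a variant if it appears in ≥2 cells of one clone, in no cell of the
other clone, is absent from bulk, is not an indel, and lies outside the
repeat mask. SV merging is single-linkage (union-find) within the same type
and contig, requiring breakpoint distance ≤200 bp and reciprocal overlap
≥10% (length ratio for insertions); a merged event is PRECISE if any member
is, and its SVLEN is the member median. Somatic SV candidates must be
PRECISE, absent from bulk, and confined to one clone.

## Tandem-repeat genotyping (`tr.py`)

`read_repeat_length` sums insertion minus deletion lengths within the locus
window ±100 bp flank from a read's CIGAR; the read must span the window,
otherwise it contributes nothing. Per-locus read values are clustered by 1-D
single linkage with tolerance `max(2, unit)`; a cluster becomes a candidate
allele only with ≥4 supporting reads (smaller clusters count as "other"
reads); more than two persistent (>2-read) clusters → `UNGENOTYPED`. The
confidence filter applies four rules in order: (i) every allele ≥5 reads,
(ii) ≤2 reads outside the called alleles, (iii) allele reads ≥90% of
spanning reads, (iv) allele reads ≥50% of local coverage; the first violated
rule names the failure. Cell–bulk concordance is allele-level over loci
where the bulk genotype is PASS.

## Heteroplasmy scan (`mito.py`)

Per-sample (L, 4) pileup matrices are simulated binomially from each
sample's mitochondrial allele mix at the configured depth. A site is
reported when every cell of one clone shows the alternate allele at
frequency ≥0.30 with coverage ≥10 and every other sample shows <0.05;
other-samples with insufficient coverage make the site `UNTESTABLE` rather
than PASS. Sites at frequency 1.0 everywhere are germline-like and excluded.

## Numerical choices

* Lognormal gain uses the mean-preserving `mu = ln(mean) − sigma²/2`.
* Depth arrays are int64 per-base accumulators; statistics are computed in
  float64. Binomial confidence intervals in tests use the normal
  approximation `z·sqrt(p(1−p)/n)`.
* JSON summaries are written with sorted keys and fixed indentation so
  byte-identity is a meaningful determinism check.
* Seeds are kept below 2³¹; derived seeds mask to 31 bits.

## Limitations

* Reads are fragment-sized (one read per amplified molecule) — no read-length
  distribution beyond the fragment-length model, no quality-value modelling
  beyond a constant QV.
* There is no alignment step: analysis consumes truth alignments, so mapping
  artifacts (clipping, multi-mapping in repeats, reference bias) are out of
  scope. Coverage metrics are therefore slightly optimistic.
* The error model is uniform along the read and across bases; no homopolymer
  or context effects.
* No GC/amplification-efficiency coupling: gain is i.i.d. per fragment, so
  coverage unevenness is purely gain-driven.
* SNV/SV call sets are emitted directly from truth with dropout and false
  positives rather than called from the reads; read-level evidence enters
  only the chimera screen, coverage, TR genotyping and the mitochondrial
  pileups.
* The somatic-clone model is two fixed clones of three cells; no subclonal
  structure or copy-number change.
* Repeat content is limited to the planted TR loci and element-like SV
  insertions; there is no genome-wide repeat landscape, which makes the
  chimera screen's false-removal rate easier than on a real genome.
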