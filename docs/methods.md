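# Methods

`svscan` implements a dual-reference structural-variant (SV) domestication
scan: indel discovery between two genome assemblies, population-scale SV
genotyping from short reads aligned to both assemblies, an allele-frequency
differentiation test between a wild and a cultivated group, and windowed
sequence-level statistics (π, F_ST, LD decay, PCA). A synthetic-data
generator reproduces the whole study design in miniature so that every stage
can be validated against ground truth.

## The study design being modelled

Two assemblies — here called A (the wild-type reference) and B (the second
assembly) — differ by insertions/deletions of 10 bp to ~20 kb, the large
majority (87.7%) shorter than 100 bp, plus SNPs. A panel of 60 diploid
accessions, 28 wild and 32 cultivated, is resequenced with 150 bp paired-end
reads (~450 bp inserts). Each SV is genotyped per accession as homozygous-A,
homozygous-B, heterozygous or missing, and wild-vs-cultivated allele
frequency differences are tested per SV.

## Synthetic data generator

* **Genomes.** Chromosome sequences are i.i.d. uniform ACGT. SV sizes follow
  a two-component log-uniform mixture: `[10, 99]` bp with probability
  `frac_small = 0.877`, else `[100, 20000]` bp (only the range and the
  <100 bp quantile of the real size spectrum are known, so a maximum-entropy
  choice per component is used). Insertions and deletions are planted 50/50.
  Consecutive SVs are separated by at least `2·read_len + insert_size` so no
  sequencing fragment spans two SVs, keeping the genotyping truth
  unambiguous; an infeasible request raises a capacity error. SNPs are
  planted at `snp_rate` per bp outside SV loci. Genome B is obtained by
  applying all edits to genome A; the PAF alignment emitted (one plus-strand
  block per chromosome with an M/I/D cg CIGAR) is the exact alignment implied
  by the edits, and the truth table records each SV's breakpoints in both
  coordinate systems.
* **Population.** Background loci get independent wild/cultivated allele
  frequencies from the Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F)
  around a uniform ancestral frequency, with `fst_background = 0.05` by
  default — a typical differentiation level for a crop and its wild
  progenitor, and the value the F_ST-recovery checks target. `n_selected_sv`
  SVs instead receive a wild–cultivated frequency gap of at least
  `min_freq_shift` (default 0.6). Genotypes are Binomial(2, group frequency).
* **Reads.** Fragments of fixed insert size are drawn uniformly from each of
  the two haplotypes (assembled from the accession's genotypes); per-base
  substitution errors are injected at `error_rate` (default 1%). Because the
  generator knows each read's haplotype coordinates, it emits *exact* truth
  alignments (SAM with POS/CIGAR/NM) against both assemblies — no external
  aligner is involved, so genotyping accuracy can be measured free of mapping
  confounders. Reads falling entirely within sequence private to the source
  haplotype are flagged unmapped on the other assembly; partial overhangs
  become soft clips. Base qualities are constant; indel sequencing errors,
  PCR duplicates and quality modelling are out of scope.

What the simulator does *not* emulate: repeats and mapping ambiguity, indel
sequencing errors, reference bias from a real aligner, linkage between loci
(sites are exchangeable draws), and population structure beyond the
two-group island model. Passing tests therefore demonstrate correctness of
the algorithms under the stated model, not robustness to alignment artefacts
in real data.

## SV discovery

Within-alignment calls walk the cg CIGAR of each PAF block; every I/D run
with length in `[min_size, max_size]` (defaults 10 bp / 50 kb) becomes a
call with exact breakpoints in both assemblies. Between-alignment calls
consider adjacent blocks on the same (query, reference, strand) with anchors
of at least `min_anchor` bp (default 1000): the net of query gap minus
reference gap is called as an insertion or deletion; overlapping anchors or
gaps above the cap are skipped. Duplicates (same type, breakpoints within
10 bp, sizes within 10%) are collapsed, preferring the within-alignment
call. Coordinates are 0-based half-open internally and 1-based in VCF
output; the insertion breakpoint is placed at the left-most reference
position. The size cap is a filter, set above the largest size the scan is
expected to report.

## Genotyping

A read supports an allele when it *cleanly spans* the SV's breakpoint
window (breakpoint ± `w`, default 20 bp) on that assembly: it is a mapped
primary alignment covering the whole window, with no insertion/deletion op
touching the window, and an overall mismatch fraction NM/aligned-length of
at most 3% — the classification rule of the study design. On the assembly
carrying the extra sequence the window brackets the left breakpoint of that
sequence; on the other assembly it brackets the fused junction, so only
reads from the matching haplotype can span it without an indel. Reads
qualifying on both assemblies (possible in principle for tiny SVs) are
discarded as uninformative. With a = supporting reads on A and b on B:
`a+b < min_depth` (4) → missing; `b/(a+b) ≤ 0.2` → homozygous A; `≥ 0.8` →
homozygous B; else heterozygous. The `w`/`min_depth`/`hom_frac` values are
package defaults (only the 3% rule and the three genotype classes are fixed
by the design) and are configurable. Residual discordance at 20× is
dominated by heterozygotes drawn to a homozygous call by binomial sampling
of spanning reads; it stays under the 5% concordance budget.

Loci are filtered to call rate ≥ 70% and minor allele frequency ≥ 0.03,
thresholds inclusive. (In the source design those thresholds are stated for
the SNP panel; applying them to the SV matrix as well is a deliberate
choice — some such filter is implied by the downstream frequency analyses.)
Discovery-set SVs must additionally be genotypable in at least one
accession, which is how the "filter by short-read mapping" step is realized.

## Selection scan

Per SV, diploid genotypes collapse to B-allele counts (2 per genotyped
accession; missing excluded). The 2×2 table
`[[b_wild, nonB_wild], [b_cult, nonB_cult]]` is tested with a two-sided
Fisher exact test under the minimum-likelihood rule (the convention differs
between implementations, so it is pinned by an exact-enumeration oracle in
the tests); a zero margin returns p = 1. P-values are adjusted by
Benjamini–Hochberg across all tested SVs; `q < 0.05` (strict) flags
selection. Testing alleles rather than accession carriers keeps the unit
consistent with the MAF filter; a 3×2 genotype-table variant would be the
main alternative and is noted as such.

## Windowed statistics

* **π**: per segregating site, (n/(n−1))·2p(1−p) with n the non-missing
  allele count — equal to the exhaustive mean pairwise allele difference —
  summed per non-overlapping 15 kb window and divided by the full window
  length (the common VCFtools convention; windows with all sites missing
  report missing, not zero). The π ratio is wild/cultivated, so diversity
  loss in the cultivated group gives values above 1.
* **F_ST**: Weir–Cockerham (1984) two-population variance components per
  site, aggregated as a ratio of sums (Σa / Σ(a+b+c)) per window and
  genome-wide; sites need ≥2 genotyped accessions per group. Slightly
  negative estimates near zero differentiation are expected and not clipped.
* **Outliers**: the empirical (1−fraction) quantile per metric (top 5%
  default), flagging values ≥ threshold; ties at the threshold all flag, and
  with fewer than 1/fraction windows only the maximum is flagged. This
  replaces a composite-likelihood sweep statistic, which is deliberately out
  of scope.
* **LD decay**: squared Pearson correlation of dosage vectors for
  intra-chromosomal pairs (pairwise-complete, zero-variance pairs skipped),
  binned by distance. For independent sites the expected mean r² is
  ≈ 1/(n−1).
* **PCA**: per-locus mean imputation, centering (optional √(2p(1−p))
  scaling), full SVD with a deterministic sign convention (the
  largest-magnitude coordinate of each PC is made positive).

## Determinism and numerics

All randomness flows from one integer seed through spawned NumPy
`SeedSequence` streams (genome, population, one per accession for reads), so
identical configurations give byte-identical outputs. Genotype-call
thresholds are compared with a 1e-9 epsilon so the inclusive 0.2/0.8
boundaries survive float round-off. PCA uses a full SVD rather than a
randomized solver to keep coordinates reproducible.

## Problem sizes

The validation suite runs at desk scale by design: discovery is checked on
300 planted SVs over 4×400 kb chromosomes; genotyping on a 50 kb chromosome
with 20 SVs and 8 accessions across a 5×/10×/20× depth ladder; the scan
power/null checks on 250 differentiated + 750 background loci and a
1000-locus null panel at the full 28/32 design; F_ST recovery on 5000 SNPs;
and the end-to-end toy pipeline on 2×100 kb chromosomes, 60 SVs and 60
accessions at 10×. These sizes give stable statistics for every check while
keeping the whole suite fast on a single CPU.

## Known limitations

* Genotyping uses spanning-read counting only; a likelihood-based genotyper
  (GL/PL) would extract more information at low depth.
* Under the Balding–Nichols background, drift alone produces some background
  loci with genuinely large frequency gaps; the scan correctly flags them,
  so "false discovery" accounting in end-to-end checks treats only selected
  loci with a true group-frequency gap below 0.1 as false.
* Between-alignment calling handles the minus strand after forward
  normalization of query coordinates but the synthetic truth alignments are
  single-block plus-strand, so that path is exercised by hand-built
  fixtures only.
* The flank distances for upstream/downstream classification (2 kb) are a
  convention; the five-category precedence (exonic > intronic > upstream >
  downstream > intergenic) assigns exactly one category per SV.
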