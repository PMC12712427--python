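# Methods

This note documents the models and procedures implemented in
`diffmark`, the defaults chosen where the procedure admitted more than
one reading, and what the synthetic validation does and does not show.

## Coordinates and formats

All internal coordinates are 0-based, half-open (BED convention);
GFF3's 1-based closed intervals are converted on read (`start−1, end`)
and nowhere else. Coverage is held as sorted, non-overlapping valued
intervals per chromosome; bedGraph gaps are implicit zero coverage.
Track values are real-valued so normalized tracks reuse the same
container. Tables are UTF-8 TSV with floats at 6 significant digits;
round-trips are identity at that precision.

## Sliding-window binning and normalization

The genome is tiled with `bin_size` = 1000 bp bins every `step` =
500 bp. Only full-length bins are kept — a truncated terminal bin would
not be comparable under a fixed absolute threshold. With step <
bin_size, each interior base belongs to bin_size/step bins, so
contiguous changed regions are counted more than once in bin tallies;
summaries state counts of *bins*, not base pairs.

Per-bin signal is Σ value × overlap-length over track records, which
equals per-base coverage accumulation exactly (records spanning bin
edges contribute proportionally). Each sample is normalized as
count / library_total × scale, where library_total is the sample's
total reads as recorded in its manifest (for simulated tracks, the sum
of bedGraph values). Normalization precedes replicate averaging: the
genotype value is the unweighted mean of its replicates' *normalized*
columns (the two orders differ whenever library totals differ, and the
test suite pins the implemented order). The scale default is 1e6
(per-million); because the gain/loss thresholds live on this scale,
both are exposed as configuration, and the demo instead calibrates the
scale from the generator's closed-form expectations (below).

Per-gene signal sums normalized coverage over [start − flank,
end + flank) clipped to the chromosome, then genotype-averages; the
flank default is 500 bp (the width of "adjacent regions" is a free
choice; it is configurable). Metaprofiles average per-bp signal in
`resolution`-bp offset windows over ±flank around anchor interval
midpoints; anchors whose window would leave the chromosome are
excluded and counted rather than zero-padded, which would depress the
profile edges artificially.

## Differential calling

For a contrast A−B, per-bin delta = mean_A − mean_B (positive = more
signal in A). Calls use strict inequalities: gain iff delta >
gain_threshold (default +0.5), loss iff delta < loss_threshold
(default −0.5), boundary values unchanged. With symmetric thresholds
the classification is antisymmetric under swapping the contrast.
Same-call bins that overlap or book-end merge into maximal regions
(mean delta = unweighted mean over member bins); gain and loss regions
never merge. The gain:loss ratio is reported as infinity when no bin
lost signal and NA when nothing changed.

Cross-contrast coupling uses Pearson r on untransformed per-gene
deltas over the shared gene universe; genes missing a value are
dropped and counted. No outlier trimming is ever applied before
computing r — trimming is a plotting option only.

## Repeat-unit discovery and motif density

The dominant-unit finder is a deliberately simple tandem k-mer
heuristic, not a structural-hierarchy decomposition: for each k in
[5, 12], a position where a k-mer is immediately followed by an
identical copy is direct evidence of period-k tandem structure.
Evidence is pooled across rotations via the lexicographically smallest
rotation (canonical unit), making the result phase-independent; ties
break toward smaller k, then lexicographic order. The reported
fraction is the share of the region covered by at least one tandem
pair of the winning unit; below `min_fraction` = 0.2 the region is
flagged as having no dominant unit. This is sufficient to recover a
single dominant unit from an ITR-like array; higher-order repeat
structure is out of scope.

Motif density counts occurrences per fixed non-overlapping 200-bp
window, overlapping matches allowed (a tandem array carries a motif
copy at every phase; non-overlapping counting would undercount rotated
phases). A match belongs to the window containing its start. The
default scans the forward strand only, matching single-query usage;
`strand="both"` adds reverse-complement matches since teloboxes occur
on either strand. A pure k-bp tandem array therefore yields ≈ window/k
counts per window (200/7 ≈ 28.6 for the telobox); the "dense" flag
threshold defaults to 5 counts/window, two orders of magnitude above
the random-background expectation (200/4⁷ ≈ 0.012) and far below the
array signal, so the flag is insensitive to its exact value.

## Set statistics

A gene is marked when any peak overlaps its body by ≥ 1 bp (half-open,
so book-ended peaks do not mark); a configurable flank can widen genes
toward promoters, but the body-only rule is the default because it is
the most conservative reproducible choice. Overlap significance is the
upper-tail hypergeometric P[X ≥ k] with universe N supplied explicitly
— never inferred from a union, because p-values are universe-sensitive.
The tail is evaluated in log space and exponentiated. Fold enrichment
is (k/n_query)/(n_term/N). Multiple testing uses Benjamini–Hochberg
throughout (the adjustment procedure is this package's choice).
Depletion testing is not provided.

## Expression integration

DEG calling applies FDR < 0.01 and |log2FC| > 1, both strict, to
supplied (gene, log2FC, FDR) tables; model fitting is upstream. PCA
log-transforms counts with pseudocount 1 (natural log; the selection
rule below is invariant to the base), centers per gene, and decomposes
by SVD with samples as observations. Component signs are fixed by
making the largest-magnitude loading positive, so outputs are
reproducible snapshots. High-loading selection keeps genes with
|loading| > 3 × SD of that component's loading vector, SD taken about
the vector's mean with the sample (n−1) denominator; SD about zero is
available as an option. A component with zero loading SD is degenerate
and selects nothing, with a warning. The DEG-by-mark cross-tabulation
counts {up, down} × {gain, loss, unchanged} over the genes that have
mark information, with a per-cell hypergeometric enrichment p and BH
adjustment across the six cells.

## Synthetic data: what it emulates

The generator plants a known truth in data with the structure the
analysis assumes:

* **Genome.** Two 300-kb chromosomes of uniform-random sequence; 100
  non-overlapping 2-kb genes on a 5.5-kb pitch starting 200 bp into
  each chromosome (deliberately off the 500-bp bin grid, so planted
  domains produce the partial-overlap bins real data would); one exact
  tandem array of TAGGGTT × 1428 (~10 kb) at a pericentromeric
  position of chromosome 1, with conflicting gene slots skipped.
* **Coverage.** The expected mark level is 0.2 (background), 1.0 over
  marked genes (40 of 100 at baseline), multiplied per genotype over a
  20-gene effect subset (defaults: a gaining genotype at 2.0× that
  also acquires the ITR at full marked level, and a losing genotype at
  0.5×), times 30 reads/bp depth. Reads per 100-bp segment are Poisson
  (the pipeline consumes coverage, not reads, so read-level simulation
  would add cost without adding realism at this granularity); control
  (H3-like) libraries are flat. Each sample's rates are multiplied by
  a log-uniform library-size factor in [0.5, 2] so normalization is a
  load-bearing step. A `noise="none"` mode writes the expectations
  themselves, making every downstream stage exactly invertible to the
  truth.
* **Calibration.** Because the gain/loss thresholds are coupled to the
  normalization scale, the demo sets the scale in closed form so that
  a bin fully inside an effect gene of the 2× genotype has expected
  delta equal to twice the gain threshold: a bin at level ℓ has
  expected normalized value ℓ · bin_size · segment / area(genotype) ·
  scale, where area is the genome integral of the level, so the
  required scale follows directly. Planted truth bins are then the
  classification of the noise-free expected deltas at the same
  thresholds. Library-total normalization also induces a small
  opposite-sign shift at unchanged loci (composition effect, ≈ −0.35
  at marked non-effect genes in the default gain contrast) — real
  total-count normalization has the same property, and the thresholds
  leave it in the unchanged band.
* **Expression.** The count matrix covers a 1000-gene universe whose
  first 100 ids are the annotated genes, with log-normal base means
  around 100, NB dispersion 0.1, 3 replicates per genotype, and the
  effect genes planted at log2FC −2.5 in the gaining genotype
  (mark gain → repression). The universe is larger than the annotated
  gene set so the 3 × SD loading rule faces a realistic null
  dimensionality: with k planted genes among N, selection requires
  roughly √(1/k) > 3√(1/N), which fails for k = 20 at N = 100 but
  holds comfortably at N = 1000. A companion table of (log2FC, FDR)
  values stands in for an upstream differential-expression fit, with
  planted genes at vanishing FDR and null genes at near-zero effect.

Everything is byte-reproducible under a fixed seed (independent
deterministic substreams per purpose), and the sum of each sample's
bedGraph values equals its manifest library total by construction.

**What passing does not show.** The generator omits fragment-length
effects, GC and mappability bias, peak-shape structure, replicate
overdispersion beyond Poisson, antisense transcription and any
realistic gene-length or expression-level confounding. Recovery on
this data validates the arithmetic and the thresholds' behaviour under
noise and library-size variation — not the biological robustness of
the thresholds on real chromatin.

## Problem sizes and determinism

The default demo (2 × 300 kb genome, 1198 bins, 12 coverage tracks,
1000-gene count matrix) runs in a few seconds on one CPU; test-suite
oracles use ≤ 10-kb genomes, exhaustive enumeration up to N = 12 for
the hypergeometric, and 100–200 seeded random instances per property.
These sizes were chosen so recovery statistics are stable while the
whole validation stays desk-scale. All randomness flows from a single
integer seed.

## Known limitations

* The control (H3) tracks are generated and carried in the manifest
  but the default bin pipeline normalizes mark tracks only;
  control-ratio normalization is left to the caller.
* The gain/loss thresholds are absolute on the normalized scale; no
  per-bin significance testing is attempted (by design — the method
  under test is a fixed-threshold classification).
* The repeat-unit finder reports one dominant unit; nested or
  higher-order repeat families are not decomposed.
* Peak calling, alignment, IDR filtering and DE model fitting are all
  upstream and consumed as files.
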