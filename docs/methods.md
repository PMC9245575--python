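# Methods

`tastools` implements the computational pipeline for terminator-assisted
solid-phase (TAS-Seq) single-cell RNA-seq data: barcode-aware non-UMI
counting, knee-plot cell calling, distribution-based error correction
(DBEC) of the expression matrix, hashtag demultiplexing, and the
cross-platform comparison statistics used to benchmark such data against
droplet (10X-style) and plate (Smart-seq2-style) protocols. Everything
runs on synthetic fixtures with ground-truth manifests, so each stage's
guarantees are testable without sequencing data.

## Barcode parsing and non-UMI counting

Bead barcodes are composed of several whitelisted sections at fixed read
offsets (three sections on BD Rhapsody-style beads, with an 8-base UMI
directly before the polyT stretch). Each section is matched exactly
against its whitelist or corrected to a **unique** Hamming-distance-1
neighbour; zero or multiple candidates reject the read. This
unique-neighbour rule is the conservative standard when the platform's
own annotation script is not public; an optional linker-anchored ±1 nt
re-framing pass exists but is off by default because linker sequences
are platform-specific and must come from the user's geometry config.

Counting is deliberately **non-UMI**: 8-base bead UMIs are too short to
yield reliable molecular identities at realistic read depths (UMI
collision), so every primary mapped alignment contributes one count to
its (gene, barcode) cell and reads sharing barcode/gene/UMI count
separately. One read contributes at most one count (primary alignments
only); multimapper policy beyond the aligner's primary choice is out of
scope. Skipped-record tallies (secondary, unmapped, tagless,
off-whitelist) are conserved: matrix total + skipped = records read.

## Knee-plot cell calling

Barcodes are ranked by total read count and the curve
log10(total) vs log10(rank) is analysed:

1. tied totals are collapsed to their average rank (removes zero-width
   steps);
2. the curve is resampled onto a uniform grid in log10(rank) (512
   points by default) — without this, near-vertical steps between
   adjacent high ranks dominate the finite differences;
3. log10(total) is smoothed with a centred running median (window 5,
   symmetric and therefore odd at the edges, so the filter is the
   identity on monotone stretches);
4. the **inflection** is the minimum of dy/dx over the grid (the first
   10 ranks are excluded as in standard barcode-rank implementations),
   mapped back to the steepest raw segment it covers; the landmark is
   the segment's upper end, except when the steepest segment is the
   curve's terminal segment — then the lower end, so a pure
   single-population curve retains every barcode;
5. the **knee** is the minimum of signed curvature in the bounded
   stretch between the preceding slope maximum and the inflection.

Cells are the barcodes with total ≥ the inflection count (inclusive
boundary, keeping the inflection barcode itself; a strict option
exists). Both landmarks are exposed; the inflection is the default
threshold. The inflection is invariant under uniform scaling of totals
(a vertical shift in log space). An earlier variant that searched for
the steepest descent only to the right of a curvature-derived knee
proved fragile — normalized curvature is dominated by tiny-Δx segments
in the deep ambient tail — which is why the bounded ordering above
(steepest descent first, knee second) is used.

## Distribution-based error correction (DBEC)

Counts for a strongly expressed gene are modelled as a mixture of a low
"diffusion background" component (RNA released during cell lysis) and
one or two genuine expression components.

**Selection.** Genes with log2(max count + 1) > 8 are corrected;
everything else is left untouched (weakly expressed genes cannot be
separated reliably).

**Transform.** Nonzero counts are variance-stabilized with a
flow-cytometry-style biexponential display transform: the count axis is
modelled as `w(y) = exp(b·y) − c·exp(−d·y) + (c − 1)` (increasing,
`w(0) = 0`) and data are mapped through `f = α·w⁻¹` — linear-like near
zero, logarithmic for large counts. Parameters (b, c, d) maximize the
normal log-likelihood of the transformed values including the
log-Jacobian term, by bounded multistart L-BFGS; the sample the
optimizer sees is capped at 512 points (an even stride over the sorted
values), which leaves the likelihood shape unchanged and bounds the fit
cost. The likelihood cannot identify the affine scale of the display
axis (it cancels between the profiled variance and the Jacobian), so
the scale is anchored: f(0) = 0 and f(max) = log2(max + 1). Transformed
units are therefore commensurate with the log2 units of the selection
and classification thresholds. Inputs with < 20 observations or < 3
distinct values fall back to log2(x + 1), flagged in the decision
record. Note the transform direction matters: fitting a growing
double-exponential *directly* to counts makes the normality objective
degenerate on bimodal data (it compresses the mode gap); the inverse
(display) direction is both the flow-cytometry convention and the one
that preserves separation.

**Mixture.** A univariate Gaussian mixture with a single shared
variance ("model E") is fitted for K = 1, 2, 3 by EM: K = 1 in closed
form; otherwise a quantile-split initialization plus 4 seeded random
restarts (5 total), tolerance 1e-8 on relative log-likelihood change,
at most 500 iterations, variance floored at 1e-8. The per-iteration
log-likelihood is non-decreasing, as EM guarantees. K is chosen by
minimal BIC with p = 2K free parameters; ties go to the smaller K. BIC
is the selection rule of the mixture framework this procedure is built
on; the component range 1–3 is fixed.

**Classification.** Let m* be the largest component mean. If
m* ≤ 5.5 (shallow-sequenced data) or ≤ 6 (deep), the gene is left
untouched. Otherwise components more than 5 (shallow) or 5.5 (deep)
below m* are background. By default component means are mapped back
through the transform onto the log2(count + 1) scale before comparison
(`threshold_scale="log2"`): the thresholds are calibrated in log2-like
units and the back-mapping makes them exact regardless of the fitted
transform's shape. Comparing on the raw transformed scale — which the
anchoring keeps close to log2 units — is available as
`threshold_scale="transformed"`.

**Zeroing.** Each nonzero cell is assigned to its
maximum-a-posteriori component; cells assigned to a background
component have that gene's count set to 0. Zero counts are never
touched (they are excluded from fitting by default: they carry no
background signal and would swamp the low component; a config flag
includes them). The output is elementwise ≤ the input, and re-running
DBEC on a fully corrected matrix zeroes nothing further (the remaining
signal component is within the difference threshold of itself).
Per-gene fit failures are logged and leave that gene unchanged. A
per-gene child seed derived from (global seed, gene id) makes decisions
independent of gene order and bitwise reproducible.

## Hashtag demultiplexing

The published workflow reports only the outcome of hashtag
demultiplexing, so the rule here is the simple threshold classifier
used across cell-hashing pipelines: per barcode with top-two tag counts
c1 ≥ c2, the call is `negative` if c1 < 10, `singlet:<argmax tag>` if
c1 / max(c2, 1) ≥ 3, else `doublet`; ties resolve to the
lexicographically smallest tag. Both thresholds are config-exposed and
logged, since their original values are unstated.

## QC, normalization and highly variable genes

The matrix filters follow the standard Seurat-object construction:
genes detected in < 5 cells are dropped, then cells with < 500 detected
genes; cells with mitochondrial count fraction strictly over 0.25 are
removed (a fraction of exactly 0.25 is retained). Mito/ribosomal gene
sets are regex/prefix lists in config, not hardcoded species tables.
Normalization is ln(1 + count / cell_total × 1e6).

Highly variable genes use the mean.var.plot recipe: per gene, the mean
and the dispersion ln(variance/mean) of the de-logged normalized
values; 20 equal-width bins of mean; dispersion z-scored within each
bin (sample SD; a single-gene or zero-spread bin gets z = 0);
selection at mean ≥ 0.1 and z ≥ 0.5 (closed lower bounds).
Zero-variance genes are excluded via a relative threshold
(var ≤ mean²·1e-24) because a two-pass variance of a constant row
leaves rounding residue rather than an exact zero.

## Cross-platform statistics

Detection rate per gene is the fraction of cells with count > 0.
Between two platforms A and B, Δ = pct_A − pct_B classifies genes as
A-favored (Δ ≥ 0.10, or detected only in A), B-favored (mirrored), or
common (|Δ| < 0.10); exclusive detection takes precedence over the
threshold. GC-content and transcript-length differences between classes
are tested with two-sided Wilcoxon rank-sum tests, Holm-adjusted within
each variable.

Pseudo-bulk profiles are per-label sums of raw counts rescaled to a
fixed total of 10,000,000. Expression-distribution similarity is the
Kullback–Leibler divergence between histograms of log10(value + 1)
over shared equal-width bins spanning the pooled range (100 bins,
ε = 1e-9 added to every bin before renormalizing; KL(P‖Q) in nats,
asymmetric by definition). Fixed-bin histograms rather than kernel
density keep the quantity deterministic and testable. Composition
agreement between two label-matched subset-fraction vectors is the
Pearson correlation plus the OLS slope/intercept of A on B; unmatched
labels raise rather than being dropped silently.

## Synthetic fixtures

Every generator is a pure function of (parameters, seed); a global seed
fans out through `SeedSequence([seed, crc32(name)])` per generator.
Manifests carry the full ground truth (true barcode per read, true cell
set, per-entry signal/background labels, true regime parameters) and
round-trip through JSON.

* **Barcode reads** — whitelist sections with 0/1/2 planted
  substitutions in chosen proportions, all landing in one section (so a
  2-error read is genuinely beyond Hamming-1 repair of that section).
  Correction-to-truth is guaranteed only for whitelists with pairwise
  Hamming ≥ 3; guaranteed rejection of 2-error reads needs ≥ 5.
* **Rank curve** — log-normal totals with median 10,000 (cells) vs 50
  (ambient), natural-log σ 0.35 for both, a 3,000 / 30,000 split, and a
  ≥ 20× median-ratio guard. These are the regimes under which knee
  calling is exact; heavily overlapping regimes would make exact
  recovery information-theoretically impossible for any threshold rule.
* **DBEC matrix** — 200 genes × 1,000 cells; 50 signal genes carry
  counts 2^N(10, 0.7²) − 1 in 30% of cells and 2^N(2, 0.7²) − 1
  elsewhere; non-signal genes only the low regime. Log-normal-on-log2
  regimes match the mixture-of-Gaussians-after-transform assumption, so
  recovery tests the implementation rather than model misspecification;
  a negative-binomial mode exists for robustness checks.
* **Platform pair** — Bernoulli(p_g) detections times 1 + Poisson(2)
  counts; platform B zeroes nonzero entries at per-gene boost rates;
  annotations draw GC fraction and transcript length per planted class
  (defaults emulate the AT-rich, long-transcript bias of
  terminator-assisted chemistry).

The fixtures emulate distributional regimes, not reads: no sequencing
error profiles, quality strings, alignment artifacts, doublets or
ambient-profile correlation between genes. Passing tests therefore
demonstrate algorithmic correctness under the stated generative
assumptions, not end-to-end performance on real libraries.

## Problem sizes and tolerances

The test suite and the acceptance script run the generators at the
sizes above (DBEC: 10 seeds of 200 × 1,000; EM: 100 seeds of n = 2,000;
cell calling: 20 seeds of 33,000 barcodes; counting/parsing: 10⁴
records each). K = 1 mixture results agree with the closed form to
1e-10; normalization agrees with direct formula evaluation to 1e-12;
pseudo-bulk totals are exact to 1e-6 relative; EM log-likelihood
monotonicity is asserted to a 1e-7 absolute slack for float
accumulation.

## Known limitations

* The biexponential fit assumes the nonzero counts span enough dynamic
  range to identify (b, c, d); very narrow distributions fall back to
  log2.
* DBEC treats genes independently; it does not model a shared ambient
  profile across genes (soup deconvolution is a different method
  family and out of scope).
* The hashtag rule is a fixed-threshold classifier, not a per-tag
  background mixture; with very uneven tag depths a mixture-based
  demultiplexer would be more robust.
* Knee calling assumes a two-regime curve; on curves with genuine
  intermediate populations the inflection is still well-defined but no
  longer separates "cells" from "ambient" in a biologically meaningful
  way.
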