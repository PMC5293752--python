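# Methods

This note records the models, conventions and design choices behind
`melroot`, in the spirit of a statistical methods appendix. Nothing here
states a number the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design being emulated

Three single bulk RNA-seq libraries from rice roots — water control (M0)
and two melatonin doses (M10, M20) — with no biological replicates within a
condition. All downstream choices follow from that constraint: differential
expression is a fold-change rule rather than a replicate-aware test, and
the synthetic generator defines DE truth by planted effects rather than by
any statistic.

## Quantification and DEG calling

FPKM[g, s] = 10⁹ · C[g, s] / (N[s] · L[g]). N defaults to the column sum of
the count matrix but can be overridden, because "total mapped reads" in the
original definition counts genome-wide alignments, which may exceed
gene-assigned fragments.

A gene is up in treatment vs control when (FPKM_t + ε)/(FPKM_c + ε) ≥ f and
down when ≤ 1/f, with f = 2 (the boundary is included: "2-fold **or
higher**") and pseudocount ε = 1 FPKM. ε stabilizes ratios at low
abundance; with ε = 0 a zero-control gene is reported up with infinite
log2FC and an `unstable` flag. An expressed-gene prefilter (FPKM ≥ 1 in at
least one of the two samples, configurable) suppresses calls built entirely
on near-zero counts. Reported percentages use exact rational arithmetic and
half-up rounding to one decimal, matching the printed style (46/51 → 90.2).

## Profile normalization and clustering

Each gene's raw FPKM profile V over the conditions is transformed
w_i = log₂(v_i + 1) and then standardized. The printed form of the
transformation in the source material is typographically corrupted (it
reads as division by a sum); the prose — log₂ transform plus z-score — is
implemented as primary, and the sum-normalized variant is available via
`method="log_sumnorm"` for sensitivity checks. The z-score uses the
**sample** (÷(n−1)) standard deviation: this is the convention under which
the reference three-point profile (1, 3, 7) maps exactly to (−1, 0, 1).
Constant rows would otherwise divide by zero; they map to all-zero vectors
with a warning, keeping silent genes neutral in Euclidean distance.

K-means (scikit-learn, Lloyd's algorithm, best of n_init = 10 restarts,
seeded) partitions the normalized profiles; K is selected by maximizing the
mean silhouette width over K = 2…12 (the searched range is a package
default; ties resolve to the smallest K). Whether a fixed K or the
silhouette choice is preferred is left to the caller — both paths are
exposed.

## Promoter extraction and motif scanning

A promoter is the 1000 bp immediately upstream of the TSS on the gene's
coding strand: bases [t−1000, t−1] for a + strand gene with 1-based TSS t,
and the reverse complement of [t+1, t+1000] for a − strand gene. Windows
hitting a contig edge are clipped and flagged, never given negative
coordinates. Promoters are **not** masked against neighboring gene bodies.
Internally coordinates are 0-based half-open; GFF3 I/O is 1-based closed
and BED output 0-based half-open.

Motifs are IUPAC consensus strings matched exactly under degeneracy;
overlapping occurrences are counted via regex lookahead. Scanning covers
both strands by default (plant *cis*-element catalogs are conventionally
strand-agnostic); a palindromic site therefore counts once per strand.
What feeds enrichment is carrier status (≥1 match), not occurrence count.

## Over-representation testing

One primitive serves GO terms and motif carriers: the upper-tail inclusive
hypergeometric probability p = P(X ≥ k), X ~ Hypergeom(M, K, n), evaluated
through scipy's survival function (log-space internally) and equal to a
one-sided Fisher's exact test on the 2×2 table; k = 0 gives p = 1. The
test suite checks this route exhaustively against integer-arithmetic pmf
summation for every valid table with M ≤ 60, and against
`scipy.stats.fisher_exact` as an independent second route.

The background universe defaults to all annotated genes (the motif scan
covers the entire genome); an expressed-gene universe can be supplied
instead. No multiplicity adjustment is applied by default — mirroring the
raw P < 0.05 reporting convention of the emulated analysis — but
Benjamini–Hochberg is available (`adjust="bh"`) and recommended whenever
many features are tested. GO annotations are used as given, with no
ancestor propagation. TF-family breakdown is a plain set-join against a
user-supplied gene→family table.

## Validation statistics

**qRT-PCR.** ΔCt = mean(Ct_target) − mean(Ct_reference) per gene ×
condition (reference: ACTIN1), relative level 2^(−ΔCt), and the log2 ratio
vs control is −(ΔCt_cond − ΔCt_ctrl); SDs are over replicates (≥ 2
required). Concordance with RNA-seq is OLS with qPCR on the x-axis,
reporting slope, intercept and Pearson r; zero x-variance is an error.

**Gravitropism.** Tip angles after 90° reorientation are binned
[0,30], (30,60], (60,90], (90,∞) degrees — the first bin closed at 0, all
others left-open, which resolves the boundary ambiguity of the printed
"30–60" / "61–90" labels in favor of gap-free coverage. Group comparisons
use Student's pooled two-sample t-test by default (matching the stated
analysis); Welch is behind a flag. Zero-variance degenerate groups are
resolved exactly (equal constants → t = 0, p = 1). Stars follow
* p ≤ 0.05, ** p ≤ 0.01. LSD/Tukey post-hoc machinery is out of scope;
one-vs-control t-tests mirror the figure annotations.

## Synthetic data generator

The generator fabricates every pipeline input with recorded truth.

*Genome and annotation.* Random uniform-base contig; non-overlapping
single-exon gene models packed with 1000 bp kept clear on **both** flanks,
so every promoter is full length and free of foreign gene bodies; strands
random. Infeasible packing raises an error naming the bp deficit.
Identical spec + seed reproduce byte-identical FASTA/GFF3/TSV outputs.

*Counts.* Baseline per-kb abundances are lognormal (meanlog 3, sdlog 1);
expected counts are abundance × exon length, rescaled per condition so
column sums match the library size (10M fragments by default — the
original depth is unstated, so this is a package default) in expectation.
Planted genes multiply their means by 2^effect in affected conditions.
Counts are negative binomial with variance μ + φμ², φ = 0.05 by default —
deliberately low, since single libraries carry no replicate variance.
Planted DE genes draw baseline abundance from the central background range
(20–80 per kb), which keeps their baseline means above ~500 counts at the
default depth without distorting library composition.

*Cluster prototypes.* After per-gene z-scoring, three-sample profiles live
on a circle (the intersection of the sum-zero plane and a sphere), so the
K planted prototypes are placed at equal angles on that circle — the
maximally separated configuration — with amplitude 2 log2 units RMS.

*Motif planting.* Every promoter touched by a plan is first rewritten from
a GC-only alphabet, making any A/T-containing motif unmatchable by chance;
carriers then receive one concrete expansion of the IUPAC string at a
random non-overlapping offset, reverse-complemented into the genome for −
strand genes. This makes printed carrier counts exactly constructible: a
rescan recovers the planted carrier sets exactly. When several motifs are
planted into overlapping gene sets, junction effects could in principle
create cross-motif matches; the shipped study configuration plants
disjoint carrier choices per motif and re-verifies by rescan.

*qPCR and angles.* Ct tables are built so ΔΔCt inverts to the planted log2
ratios exactly at zero noise, with Gaussian cycle noise otherwise; angle
tables are normal draws clipped to [0°, 90°] (curvature after a 90°
rotation is physically bounded).

## The emulated study configuration (`study_dataset`)

One call produces a complete scaled-down study: 2000 genes, three 10M
libraries; 40 genes planted up and 16 down (log2 effect ±2) in both
treatments — a DEG fraction of a few percent with up outnumbering down
roughly 4.7:1, the proportions of the emulated experiment; 8 circular
prototypes × 50 genes; every catalog motif planted in 40% of the true
co-up promoters vs 5% of the rest of the genome; one GO term planted at
80% of the co-up set vs 5% background plus ten random background terms.
The planted effect magnitude is ±2 log2 units (4-fold): at a 2-fold
calling threshold a 2-fold planted effect would sit exactly on the
decision boundary and could never be recovered reliably.

What this generator does **not** emulate: read-level errors, isoform
structure, GC/length biases, batch effects, or correlated co-expression
beyond the planted prototypes. Passing recovery tests therefore show the
pipeline's logic is correct at study-like signal-to-noise, not that the
biological conclusions of any real dataset would reproduce.

## Problem sizes and numerical choices

Recovery suites run 20 simulated studies of 2000 genes; null calibration
uses 2000 draws at M = 2000, K = 100, n = 40 — a configuration chosen
because the discrete hypergeometric can actually attain a level near 0.05
there (exact achieved level 0.0463; with much smaller n or K no rejection
region close to 0.05 exists). The DEG-intersection worked example, which
plants the published 314 co-up / 51 co-down overlap, runs at transcriptome
scale (20,000 genes) with strong (log2 = 3) effects and near-technical
dispersion (φ = 0.005): at that scale the planted overlap is recovered
exactly, whereas in a 2000-gene universe planting 365 strong effects
distorts library composition so heavily that exact recovery is impossible
— the stochastic benchmark at φ = 0.05 is the 2000-gene suite above.
Fraction rounding uses exact rationals with decimal half-up quantization,
so printed percentages are reproduced digit-for-digit.

## Known limitations

* Fold-change calling without replicates cannot separate biological
  variability from treatment effect; the false-call rate reported by the
  recovery suite is specific to the assumed dispersion.
* Silhouette-based K selection is only meaningful when clusters are
  separated in the z-scored geometry; with three samples that geometry is
  one-dimensional (a circle), which caps how many clusters are resolvable.
* Enrichment p-values are raw by default; with dozens of candidate motifs
  or thousands of GO terms, BH adjustment should be switched on.
* The GC-only non-carrier construction is a device for exact ground truth,
  not a model of real promoter composition.
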