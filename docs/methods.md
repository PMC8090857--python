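# Methods

## Scope and data model

`terv` quantifies transposable-element (TE) expression at three levels —
genes (unique reads), individual TE elements (unique reads), TE subfamilies
(EM over multimapped reads) — from SAM alignments carrying NH multiplicity
tags and, for single-cell data, corrected cell-barcode tags (default `CB`).
All coordinates are 0-based half-open in memory; GTF is shifted to 1-based
closed on disk, BED is unshifted, SAM is handled by pysam.

Alignment is upstream of this package: records are inputs (or simulated
directly as records). Clustering of cells is likewise upstream; its output —
a (sample, barcode) → cluster table — is an input.

## EM subfamily counting

A read's candidate set is the set of subfamilies whose fragments any of its
alignments overlaps by ≥ 1 bp with protocol-compatible strand, deduplicated
at subfamily level. Each read contributes total mass 1. With unique counts
u_s fixed, ambiguous reads with candidate set S are assigned to s ∈ S with
weight c_s / Σ_{t∈S} c_t, and the counts c are iterated to a fixed point
(uniform initial split; stop when the largest count change < `tol`, default
1e-6, cap `max_iter` = 100 with a warning and a `converged` flag on
non-convergence). Conservation — Σ_s c_s equals the number of TE-assigned
reads — holds at every iteration by construction.

Numerical note: when the fixed point lies on the boundary (a subfamily's
count decaying to zero), convergence is sublinear; tests that compare
against the independent fixed-point oracle raise `max_iter` and tighten
`tol` accordingly. Interior fixed points converge geometrically and the
defaults are ample.

## Cell QC and back-tracing

QC statistic: log2(genes detected + 1) per cell (genes detected = number of
distinct genes hit by unique, unambiguous, strand-compatible reads). Cells
are retained when the statistic lies within median ± nmads × MAD, with the
MAD scaled by 1.4826 for consistency with a normal sd; default nmads = 3,
both tails, flags exposed. A zero MAD (all cells identical) retains
everything with zero deviation. The QC scale choice (log2, both tails) is a
package decision; the transform stabilizes the right tail that dominates
droplet data.

Back-tracing routes *reads*, not individual records: all alignments sharing
a read name within a sample go to the bucket of the read's barcode, because
the EM counter needs the complete multiplicity set. Reads without a barcode,
with an unmapped barcode, or from QC-failed cells are counted in a drop
ledger; assigned + dropped = total on every input, and buckets are disjoint.
Routing all cells to one cluster reproduces bulk counting exactly (tested).

Strandedness defaults: bulk `reverse` (dUTP-stranded libraries), single-cell
pseudobulk `forward`; both overridable everywhere.

## Normalization and differential expression

Size factors are median-of-ratios on gene counts: s_j = median over genes
positive in all samples of k_gj / (∏_j k_gj)^{1/m}. When no gene is
all-positive, a flag enables a positive-counts ("pseudo-reference")
geometric mean. TE matrices are divided by the gene-derived factors — the
quantity being tested (global TE derepression) must not influence its own
normalization.

Per feature, counts follow NB(mean μ_j = s_j q_{g(j)}, variance μ + αμ²)
with log link and design intercept + condition. The two-group design makes
the GLM separable: each group mean solves Σ_j (k_j − μ_j)/(1 + αμ_j) = 0 by
Newton iteration. β = log(q_KO/q_ctl) is reported in log2; SE(β) comes from
the expected information I_g = Σ_j μ_j/(1 + αμ_j) per group (the Fisher
information of the separable design); W = β/SE with a two-sided normal p.
Features identical across conditions give β = 0 and p = 1 exactly.

Dispersion is estimated per feature by maximizing the Cox–Reid-adjusted
profile likelihood ℓ(α) − ½ Σ_g log I_g(α) over α ∈ [1e-8, 100] (bounded
scalar optimization on log α). With 4–6 samples this estimator is noisy, and
downward excursions of α̂ inflate the Wald statistic: measured on 2,000 null
features at 3 vs 3, per-feature dispersion gives an empirical type-I rate of
~0.12 at nominal 0.05, whereas the known-α rate is 0.05. `run_de` therefore
moderates dispersion *upward only*: a common α is estimated by joint
Cox–Reid ML across all retained rows, and each feature uses
max(α̂_feature, α̂_common). This shares information across features the way
established DE tools do, while never granting a feature less variance than
the matrix-wide signal supports; measured type-I is ~0.05 at 3 vs 3. The
cost is conservatism for genuinely low-dispersion features in heterogeneous
matrices. A t reference distribution with residual df was considered and
rejected: at 2 vs 2 (df = 2) it makes padj < 0.01 unattainable for any
effect size, which defeats per-cluster analysis with duplicate samples.
`nb_wald_test` used directly (single feature) has no moderation anchor and
uses the per-feature estimate; `alpha=` overrides either path.

Rows with total count < `min_total` (default 10) are reported as filtered,
excluded from the BH family, and carry NaN statistics. BH adjustment is the
step-up procedure (via statsmodels) over unfiltered features. A feature
expressed in exactly one condition has its zero group mean floored at 1e-8;
the fold change is then finite but the collapsed information blows up the
SE, so such features are effectively never significant — a documented
limitation rather than a DESeq2-style handling.

Significance rules: bulk padj < 0.05 and |log2FC| > 0.5; per-cluster TE
padj < 0.01 and log2FC > 3 (upregulation only); per-cluster genes use a
Wilcoxon rank-sum test on normalized per-cell values (normal approximation
with tie and continuity correction, via scipy) at padj < 0.01; element-level
upregulation for window analyses uses padj < 0.05 and log2FC > 0.

## Interval analyses

**Full-length ERV calling.** For each overlapping (prediction, internal
fragment) pair, f = overlap_bp / denominator; the denominator is the
internal fragment's length by default ("the internal element overlaps ≥ 50%
*into* the prediction"), switchable to the prediction length because
overlap-fraction conventions differ between tools. Pass at f ≥ threshold
(default 0.5); exact-threshold pairs are flagged `borderline` since "more
than 50%" vs "≥ 50%" is a genuine ambiguity. A prediction is full-length
when any internal fragment passes.

**Neighbor-gene windows.** A gene belongs to window w of an element when its
span overlaps [start − w, end + w); w ∈ {10, 20, 50} kb by default, strand
ignored, spans (not midpoints) anchored. Gene log2FC distributions near
upregulated vs non-upregulated elements are compared per w with a two-sided
rank-sum test; the rank-sum choice is this package's declared statistic. A
gene near elements of both statuses contributes to both sets.

**Coverage matrices.** Per-base depth from M/=/X CIGAR footprints; each
element is scaled to n_bins equal (possibly fractional-width) bins whose
value is the exact mean depth over the real-valued bin interval (prefix-sum
arithmetic, matching a per-base brute force on integer boundaries).
`library_size` rescales to depth per million mapped reads, so jointly
doubling depth and library size leaves the matrix unchanged. Rows can be
flipped for minus-strand elements and sorted by maximum bin value over a
sample group (e.g. KO samples).

## Amplicon editing

A read is edited when a deletion footprint intersects, or an insertion
anchor lies in, the closed window [cut − w, cut + w]; default half-width
w = 10 bp (the upstream pipeline's internals are unpublished, so the window
is a declared parameter, exposed on the CLI). Multiple indels combine by net
length; frameshift ⇔ net mod 3 ≠ 0 under mathematical modulo (so −4 shifts,
−3 does not). Substitutions and soft clips never count; unmapped reads are
excluded from the denominator and tallied separately; reads are independent
(no pairing or UMI collapsing).

## Synthetic data generator

The generator emits alignment records directly — no sequences are
fragmented and no aligner runs — because alignment is out of scope and
ground truth must be exact. What it emulates:

* homologous TE copies via homology groups: a read from any member appears
  once per member with NH = group size (uniform ambiguity, the structure the
  EM counter must resolve);
* full-length elements as adjacent LTR–internal–LTR triplets (default LTR
  400 bp) plus a spanning prediction interval;
* per-(cluster, condition) NB counts with mean baseline × 2^log2FC ×
  library-multiplier and variance μ + αμ² — the same parameterization the DE
  model fits, making parameter recovery well-posed;
* barcoded reads (fixed-length ACGT barcodes) for single-cell mode, bare
  records for bulk.

Default study conditions (`terv.default_scenario`): 2 control + 2 KO
samples, three clusters of 40 cells each per sample, 30 genes (means 80–136
reads), 210 TE subfamilies at baseline 60 reads per (sample, cluster), half
with two homologous copies; 10 subfamilies injected at log2FC = 4 in one
cluster; dispersion 0.05 for genes and TEs (moderate biological
replicate variability, typical of bulk/pseudobulk RNA-seq); library-size
multipliers 0.9–1.2. These sizes keep a full run in tens of seconds while
leaving the injected effect ~3 sds above the per-cluster log2FC > 3 gate.

What it does **not** emulate — and therefore what passing tests do not show
about real data: sequencing errors and alignment artifacts, UMI duplication,
doublets, partial homology (ambiguity is uniform within a group),
non-uniform coverage along features, and real mm10 repeat structure.
Because injected fold changes are realized through NB sampling, an injected
subfamily's *realized* fold change occasionally lands below the calling
threshold; recovery statements are therefore seed-wise, not almost-sure.

## Pipeline

`terv run` executes simulate → [amplicon] → backtrace → quantify → DE →
intervals on a YAML key-value config (CLI overrides; unknown keys rejected;
contradictions fail before any stage runs). Every run writes a manifest with
the resolved config, per-stage wall-clock, and SHA-256 checksums of outputs;
identical config + seeds reproduce identical checksums. Existing outputs are
never overwritten unless `force` is set. All randomness flows from explicit
named seeds.
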