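# Methods

This note documents the models and procedures implemented in `xegmap`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Count model and normalization

Raw counts are modeled as negative binomial: for gene *g* in cell *i* of
type *t*, counts ~ NB with mean μ = profile(t,g) · s_i and dispersion θ
(variance μ + μ²/θ; θ → ∞ recovers Poisson). Size factors s_i are
log-normal. Normalized expression is log2(count / ŝ_i + 1), with ŝ_i
rescaled to unit mean; the transform is exactly invertible given the size
factors, which the tests exploit as a round-trip check.

Two size-factor strategies sit behind one contract: per-cell library size
(default — simple and auditable) and a pooled-deconvolution estimator
(ring-ordered pools of 21…101 cells, one linear equation per pool in the
member cells' factors, least-squares solve). On data where cells differ
only by a known scale the pooled factors track that scale with r > 0.95;
the deconvolution route matters on real data with strong composition
effects, which the default generator does not emulate.

## Highly variable genes

Per replicate: squared coefficient of variation CV² = var/mean² of
normalized expression per gene; robust (Tukey-bisquare) least-squares fit
of CV² = a₁/μ + a₀ over genes with mean > 0.1; per-gene statistic
(n−1)·CV²/trend referred to χ²(n−1); the top 10% of testable genes by
p-value are selected, and the cross-replicate HVG set is the union.
Ribosomal/exogenous/antibody features are excluded before fitting, so an
excluded gene can never be selected regardless of its variance. Whether
p-values are multiplicity-adjusted before the cut is immaterial — the cut
is a rank cut.

## Batch integration

Fast-MNN-style correction: cosine normalization, joint PCA (deterministic
sign: the largest-magnitude loading of each component is forced positive),
then sequential merges. For each merge, mutual k-nearest-neighbor pairs
between the accumulated reference and the incoming batch yield difference
vectors; each incoming cell's correction is the Gaussian-kernel-weighted
average of those vectors. Two choices here were open:

* **Kernel anchor.** Weights use the distance from the cell to the *pair
  midpoint* rather than to the pair's incoming-batch member. For two
  identical batches, every MNN pair (a,b) has a mirror (b,a) with the same
  midpoint, so their opposite difference vectors cancel exactly and the
  net correction is zero — the symmetry the contract demands. For genuinely
  offset batches the two anchors order pairs the same way.
* **Bandwidth.** σ = 3 × mean MNN-pair distance, configurable. Wide enough
  to act as a locally smooth batch correction; populations without atlas
  counterparts keep their offset (verified: the ambiguous-cell offset
  survives correction at any bandwidth tested).

The reference batch's geometry is unchanged beyond the shared projection.
Merge order changes coordinates but not type separation (silhouette within
10% under order reversal on the benchmark).

The SNN graph links cells whose (k+1)-neighborhoods (self included)
intersect, with weight shared/(2(k+1) − shared), and is partitioned by
Louvain with a fixed seed. One caution documented deliberately: modularity
maximization splits even unstructured data into several communities, so "a
single Gaussian blob yields one big cluster" is *not* a property of this
(or any) Louvain pipeline; what holds, and what the tests assert, is that
the best-partition modularity on unstructured data is low compared to
genuinely clustered data.

UMAP is exposed for visualization only and is never consumed by downstream
statistics.

## Atlas label transfer

For each query cell: Euclidean k = 50 nearest atlas neighbors in the joint
corrected space; assigned type = modal neighbor type; confidence = modal
count / k (ties break by smaller mean distance to the tied type's
neighbors, then lexicographically); mean neighbor distance; mean and SD of
neighbor ages. Rejection rules, applied in order — distance tail, then
confidence < 0.5 (strict), then types left with < 10 members, then an
explicit exclusion list.

**Distance-tail rule.** The reference procedure cut "the long tail of the
histogram of average distances" by eye. A fixed upper quantile is not a
faithful proxy: it rejects a fixed share of cells no matter what, and the
populations the visual cut removes (cells unlike any atlas type) routinely
exceed any pre-chosen quantile. The default here is the standard robust
outlier rule, median + 3·1.4826·MAD of the per-dataset distribution,
computed over all samples of a dataset pooled (as the visual cut was);
fixed-quantile and explicit-threshold modes remain available. A structural
fact worth recording: confidence can never reject a cell whose
neighborhood contains only two types — the modal fraction is then ≥ 0.5 by
pigeonhole and exactly 0.5 is retained — so foreign or mixed populations
are caught by the distance rule or not at all.

## Spike-in identification

mCherry⁺ (any expression) ⇒ ES spike-in; Ab_CD15 strictly > threshold AND
membership in the designated cluster ⇒ E14 spike-in; likewise Ab_CD140 for
XEN spike-ins, with eGFP-cluster members failing the CD140 cut annotated
XEN-derived. Precedence when several rules fire: mCherry > CD15 > CD140
(the experiments never overlap them; determinism requires an order).
Designated clusters are chosen by a marker-signature score rather than by
eye, and thresholds are dataset-level configuration (50 and 100 were used
in different experiments), never auto-tuned.

## Differential expression

*Welch route*: per-gene Welch t statistic on log-normalized expression
with Welch–Satterthwaite degrees of freedom; degenerate genes (zero
variance in both groups, equal means) are defined as p = 1.

*NB route*: per-gene negative-binomial regression on raw counts, log link,
design = one indicator per (condition, replicate) subset plus the
mean-centered log total count per cell as a covariate — a covariate, not
an offset, following the source procedure's wording; an offset mode exists
behind a flag. Dispersion is estimated per gene by joint maximum
likelihood (Poisson-initialized BFGS), falling back to a method-of-moments
plug-in with a fixed-dispersion GLM when ML fails; no empirical-Bayes
shrinkage. The tested quantity averages the replicate coefficients on each
side (or all remaining subsets, for one-vs-rest) and is assessed by a Wald
test using the coefficient covariance; non-converged genes are excluded
from the BH family. Benjamini–Hochberg is implemented directly (step-up
with monotonicity enforcement) and cross-checked against an independent
implementation.

Calibration is verified on a single homogeneous population (200 cells per
subset, 2000 genes, θ = 2): gene-level type-I error at α = 0.05 within
binomial error, and planted log2FC = 1.5 recovered with median absolute
error well under 0.2. With a *mixture* of cell types, multinomial
composition differences between samples interact with marker genes and are
genuine condition-level signal the subset-dummy design cannot distinguish from
gene-level DE; that is a property of the design (also of the original),
not of the estimator, and is why the calibration benchmark uses a
homogeneous population.

## Neural sub-clustering and frequency normalization

Neural ectoderm-like cells (configurable type set) are re-integrated with
MNN restricted to a dorsoventral marker panel (d = 5 within a condition,
d = 15 for the joint run, k = 20) and partitioned by k-means with five
centers (k-means++ with fixed seed, 25 restarts). Panel genes are sorted
before use, so results are independent of panel row order. Sub-clusters
are named dorsal/ventral post hoc by the sign of the difference in mean
standardized dorsal vs ventral marker expression.

The shipped panel file `data/dv_markers_synthetic.tsv` is a synthetic
stand-in assembled from dorsal markers named in the experimental
literature (Pax3/6/7, Msx1/2, Ascl1, Zic1, Olig3, Wnt1, Gdf7, Lmx1a) and
canonical ventral genes (Nkx6-1, Nkx2-2/9, Olig2, Shh, Foxa2); a curated
panel for a real analysis should be supplied by the user.

Frequencies: f[s,c] is the within-sample relative frequency of sub-cluster
c; g[s,c] = f[s,c] / Σₛ f[s,c]. Per sub-cluster, g sums to 1 across
samples, which removes sample-size effects exactly: samples of 100 and
10,000 cells with identical composition give g ≈ 0.5 each, within binomial
error.

## Ligand–receptor scoring

Cluster means of normalized expression (normalized rather than raw means —
the upstream tool takes raw counts as *input* but the aggregation here is
defined on expression; a flag switches). Observed score per (pair, source,
target) = mean of ligand mean in source and receptor mean in target; null
from label shuffles with the add-one estimator p = (1 + #{null ≥ obs}) /
(1 + n_perm), valid at finite n_perm; pairs whose ligand or receptor is
expressed in under 10% of its cluster get p = 1. Communication per
(source, target) sums the significant pair scores, optionally restricted
to ligands of interest. Gene-name mapping is a strict 1:1 table; unmapped
genes are dropped with a log entry, colliding targets are an error.

## Synthetic study conditions

The evaluation configuration ("separation profile") fixes the conditions
under which the end-to-end properties are measured: five cell types with
150 disjoint marker genes each at log2 fold-change 4 over a common marker
baseline; NB dispersion θ = 20 (α = 0.05, typical UMI-scale
overdispersion); a 5× depth scale; balanced mean type frequencies so the
atlas covers all types at equal density; 5000 atlas cells and 4 × 700
query cells plus 200 planted 50/50-mixture cells for the label-transfer
benchmark. Each choice neutralizes a specific nuisance that would
otherwise dominate the geometry: at θ ≤ 5 the overdispersion floor makes
within-type noise the same scale as a mixture offset; unequal atlas
density or type-asymmetric marker baselines skew the native distance
distribution that the tail rule is estimated from. Problem sizes for the
statistical benchmarks (2000 genes / 200 cells per subset for DE, 200
pairs × 500 permutations for the LR null, 20 seeds for detection-rate
estimates) were chosen so the full evaluation completes in minutes on one
CPU while keeping binomial error bands tight.

What the generator does *not* emulate — gene–gene correlation beyond type
structure, doublets, ambient RNA, realistic dropout patterns, library
chemistry artifacts — bounds what passing benchmarks show: they validate
the implementations and their statistical calibration under the stated
model, not performance on any particular real dataset.

## Known limitations

* The NB fit is per-gene with no information sharing; on very small groups
  edgeR-style shrinkage would be more powerful.
* The MNN correction can, like all MNN methods, distort populations absent
  from the reference if spurious pairs form; the midpoint kernel and wide
  bandwidth mitigate but do not eliminate this.
* Multi-subunit receptor complexes are out of scope for the LR database.
* The pooled size-factor solver assumes enough cells (> pool size) and
  positive pool ratios; it falls back on nothing — callers should use the
  library-size default for small matrices.
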