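# Methods

`ncbroker` implements a network-driven inference chain that ranks
non-coding RNAs (ncRNAs) as topological *brokers* in cancer-subtype
co-expression networks, together with a synthetic-cohort generator that
makes every stage benchmarkable against known ground truth. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic benchmarks do and do not show.

## 1. Expression preprocessing

Input is a gene × sample matrix of non-negative FPKM-like values with a
normal/tumor group label per sample and a PAM50-style subtype label per
tumor sample.

* **Quantile normalization** forces every sample onto the vector of
  across-sample rank means. Ties receive the mean of the rank-means
  their rank range spans, which makes the transform deterministic and
  idempotent.
* **log2 transform** with pseudocount (default 1.0).
* **Differential expression**: two-sample Student's t-test (pooled
  variance; Welch behind a flag) of tumor vs normal on log2 values.
  A gene passes when `p ≤ 0.001`, `|log2FC| ≥ log2(2)` (two-sided) and
  its coefficient of variation on the linear scale is positive.
  No multiple-testing correction by default; Benjamini–Hochberg is
  available behind a flag. Constant genes get `t = 0, p = 1`.

A caveat worth knowing: quantile normalization is compositional. When a
large set of genes is strongly shifted in one group, unshifted genes are
displaced in the opposite direction on the shared quantile scale. This
produces (a) a modest count of spurious "down-regulated" calls and (b)
weak systematic *anti*-correlation between unrelated strongly-shifted
genes. Section 4 explains how the network stage deals with (b).

## 2. ISA biclustering

The Iterative Signature Algorithm alternates two thresholded scoring
steps on standardized copies of the matrix (rows z-scored to score
samples, columns z-scored to score genes). One refinement step is a pure
function of the gene membership set: sample scores are the mean
row-standardized profile of the current genes, thresholded at
`|z| > t_sample` with a coherent sign; gene scores are the
weighted mean column-standardized profile over the kept samples,
thresholded at `|z| > t_gene`. A bicluster is a fixed point of this map,
so re-applying the step to a result never changes it. Runs start from
random sparse gene seeds (2% of genes, ≥3) over a threshold grid
(genes 1.5–3.0, samples 1.0–2.0 by default); fixed points are
deduplicated at gene-set Jaccard > 0.9, keeping the higher-scoring one
after a deterministic sort, so the output does not depend on seed
enumeration order.

**Fixed-point score and robustness.** The score is the bilinear form
`u'Ev` with unit-norm gene/sample score weights on the row-standardized
matrix — a leading-singular-value analogue restricted to the fixed
point. A plain size product rewards large noise modules; the bilinear
form weighs coherence. Robustness compares this score against the best
score ISA reaches on copies of the matrix whose rows and then columns
are independently permuted (same thresholds; restarts plus a restart
from the bicluster's own genes). Both the raw score and the ratio to the
shuffled maximum are reported, and the size/robustness filter
(default ≥10 genes, ≥7 samples) accepts either metric by name.

Shuffled-data ISA is itself an optimizer and converges to substantial
noise attractors, so the ratio scale is compressed: pure-noise
biclusters sit near 1, genuine planted modules near 1.6–2.2 depending on
matrix size (the ratio grows with the cohort because signal scores grow
faster than the shuffled optimum). Across the scales exercised here,
noise fixed points score 0.8–1.0 and planted modules 1.6–2.3; the
pipeline filter default of 1.5 splits the two distributions.

**Subtype dominance.** Per bicluster, the subtype composition of its
tumor member samples is tabulated; rows sum to 1 exactly. Two selection
modes exist: `strict` keeps biclusters whose dominant subtype exceeds a
threshold (default 0.5), and `top_per_subtype` returns, for each
subtype, the bicluster maximizing that subtype's fraction. Published
dominance tables are read in the second way in practice — top cells can
sit below 0.5 — so the pipeline defaults to `top_per_subtype`, while
`strict` remains the documented default of the library function. An
alternative gene-based composition mode (`by="genes"`) exists for
callers that carry a gene → subtype association, e.g. signature-gene
panels; samples are the default because subtype labels are per-sample.

## 3. Mutual-information template network

Association is normalized plug-in mutual information: profiles are
discretized into `b` equal-frequency bins (ties split deterministically
by position), MI is computed from the joint histogram and divided by
`min(H(X), H(Y))`, so `MI ∈ [0, 1]` and the edge distance
`d = 1 − MI` is itself in [0, 1]. Constant profiles have zero entropy
and get `MI = 0` by convention. The default bin count is
`b = ceil(sqrt(n/5))` (≥3): the joint table then keeps roughly ≥5
expected counts per cell. A `sqrt(n)` rule, sometimes quoted for 1-D
histograms, yields `b² ≈ n` cells for the *joint* table and leaves the
plug-in estimate dominated by sparsity noise at n ≈ 100–250 — under it,
a planted ρ = 0.6 pair was not even significant at α = 0.05.

* **Significance**: per-pair permutation null (one profile's sample
  order permuted; marginals are permutation-invariant, so only the
  joint entropy is recomputed), `p = (1 + #{null ≥ obs}) / (1 + n_perm)`
  with 1000 permutations by default. Per-pair seeds and a canonical
  pair orientation are derived from the unordered node-id pair, so the
  edge set is invariant to gene input order.
* **Persistence** ("rewiring strength"): the fraction of sample
  *subsamplings* (80% drawn without replacement, 100 draws by default)
  in which the recomputed MI again exceeds the independence-null
  critical value at the subsample size. A with-replacement bootstrap is
  deliberately avoided: duplicated samples sharpen the joint histogram
  and inflate plug-in MI for *every* pair, which silently disables the
  filter. Because equal-frequency marginals are near-uniform for all
  genes, one simulated null at the subsample size serves every edge.
* **Edge rule**: keep a pair iff `p ≤ α` and persistence ≥ the
  threshold. Library defaults are α = 0.05 and persistence 0.8 (suited
  to testing a single designated pair); the pipeline uses α = 0.01 and
  persistence 0.6 because it scans thousands of candidate pairs —
  α = 0.01 keeps the expected number of surviving chance edges below
  one while planted bridges (ρ ≈ 0.4–0.6 at n ≈ 124) retain most of
  their edges at persistence 0.6.
* **Signed mode** (pipeline default): edges additionally require
  Spearman ρ > 0. MI is sign-blind, and the compositional
  anti-correlations of Section 1 otherwise enter the network as weak
  but persistent spurious bridges between unrelated modules, which is
  fatal for any bridge-centric topology analysis.
* An absolute-Spearman path mirrors the MI path end-to-end for
  metric-comparison reports.

The pipeline computes the network on tumor samples only: every DE gene
shares the normal-vs-tumor contrast, and over the pooled cohort that
contrast alone makes nearly all DE pairs significant, drowning module
structure. Isolated ncRNAs stay in the graph, flagged.

## 4. Node topology and brokerage

For node *i* with degree `k_i`, neighbor-link count `t_i`:

* clustering `C_i = 2 t_i / (k_i (k_i − 1))`;
* Burt effective size (unweighted) `S_i = k_i − 2 t_i / k_i`;
* local efficiency `E_i`: mean inverse shortest-path length between
  *i*'s neighbors inside the subgraph they induce, **with node *i*
  excluded** — paths between neighbors may not route through the node
  being scored; this exclusion is precisely what makes the measure
  detect brokers. Unreachable pairs contribute 0.
* brokerage `B_i = k_i − (k_i − 1) E_i`, so `B_i ∈ [1, k_i]` for
  non-isolated nodes, `B_i = k_i ⇔ E_i = 0`, and for `k_i ≥ 2`
  `B_i = 1 ⇔ E_i = 1` (a pendant node has `B = k = 1` with `E = 0`,
  so the second equivalence starts at degree 2). Isolated nodes get
  `B_i = 0` by convention.

Brokerage is min–max normalized over non-isolated nodes (a degenerate
range maps to 1). ncRNA nodes are ranked by normalized brokerage
(ties: degree, then id), each carrying its non-ncRNA neighbors as the
"functional context" gene set. All measures are computed on the
unweighted graph; a weighted variant (path lengths along `d = 1 − MI`)
exists behind a flag for exploration. Betweenness is reported for
comparison but never used in ranking. Articulation points and bridges
come from the standard depth-first algorithms.

**Disruption.** Targets are removed cumulatively; after each step the
component count and the giant-component fraction (relative to the
original node count) are recorded. The baseline repeats the removal
`n_random` times with nodes matched to each target's original degree
within ±1 (nearest degree as fallback), reporting mean and 5th/95th
percentiles. The matching pools exclude the targets themselves by
default: on desk-scale graphs the targets sit inside their own ±1-degree
pool, so a non-negligible share of "random" replicates would simply
re-remove them and the percentile comparison degenerates. A flag
restores inclusive pools.

## 5. Overlapping module landscape

A deliberately simplified influence-landscape community method. The
influence matrix is the geometric series `Σ_t (α P)^t` (row-stochastic,
weight-proportional transition matrix `P`; damping α = 0.85 by default;
iterated until the L1 norm of the term falls below 1e-8), so each row
sums to `1/(1 − α)`. Node height = total incoming influence; module
cores are the local maxima of the height field (exact ties break toward
the lexicographically smaller id, so a flat plateau yields one core);
node membership in a module is its influence on that module's core,
normalized across cores — overlapping by construction. One optional
meta-level (modules as nodes, summed cross-membership products as
weights) stands in for a full hierarchy. The fidelity target is
qualitative (overlapping hills; brokers show high membership entropy),
not numeric parity with any specific external tool.

## 6. Synthetic cohort generator

The generator emulates a two-group RNA-Seq cohort (defaults: 106 normal,
124 tumor; 1000 genes + 50 ncRNAs) on the log2 scale; the emitted matrix
is `2^log2` (log-normal marginals, FPKM-like). Components:

* background: i.i.d. Gaussian log2 values (mean 5, SD 1);
* subtype labels drawn i.i.d. (luminal A 0.35, luminal B 0.25,
  basal 0.25, normal-like 0.15);
* three planted biclusters of 20 genes × 10 tumor samples, each drawn
  from one dominant subtype with 10% contamination; member genes get a
  tumor-wide DE shift of `effect_size·noise_sd` (default 3 SD) plus the
  same shift restricted to the block, plus a per-sample latent factor
  `f_k` (loading 1.2·SD) shared by the module across all samples;
* 100 background DE genes with the tumor-wide shift only. The DEG list
  must be much larger than any one module: if modules are a third of
  the DE submatrix, their gene z-scores are compressed and ISA
  fragments them — this mirrors real cohorts, where thousands of DEGs
  dwarf any single co-expression module;
* ncRNAs (biotypes drawn pseudogene-heavy): two *brokers* loading on
  the latent factors of two modules each (per-factor loading 1.2·SD,
  intrinsic noise halved, plus co-activation with both bridged subtype
  blocks), one single-module ncRNA per module, ten DE-only ncRNAs, the
  rest pure background. Brokers are deliberately parameterized as
  bridges of the same strength as within-module co-expression — that
  is their ground-truth role; the realized bridge strength still varies
  noticeably with the latent-factor draw at n ≈ 124.

All randomness flows from a single integer seed through one generator;
identical seeds give byte-identical output.

**What passing the synthetic benchmarks shows — and does not.** The
generator produces Gaussian log2 noise, i.i.d. samples, block-constant
effects and linear factor structure. It exercises the estimators'
statistical calibration, the recovery machinery, and the topology
pipeline end-to-end, including the quantile-normalization compositional
artifact (which emerges on its own). It does not model count noise,
batch effects, gene-length/GC bias, correlated background structure,
heavy-tailed expression, or subtype-specific variance — recovery rates
here are upper bounds on what identically-parameterized real data would
give.

## 7. Pipeline and reproducibility

Stages: simulate/load → normalize + DE → ISA on the DE protein-coding
submatrix (tumor samples) → robustness filter → subtype dominance →
signature-gene template network with DE-ncRNA embedding → module
landscape → topology, broker ranking, disruption → per-broker context
reports (optional annotation and external-correlation tables are joined
pass-through, never recomputed). One master seed; per-stage seeds are
`(master + crc32(stage_name)) mod 2^31`, so any stage can be re-run in
isolation. The manifest records versions, seeds, artifact list, and a
SHA-256 hash of the effective parameters (the derived simulation seed is
excluded from the hash). Default problem sizes (1000 + 50 genes ×
230 samples, 100 ISA seeds × 12 threshold pairs, 1000 permutations,
100 subsamplings) complete in well under a minute on one core.

## 8. Known limitations

* The plug-in MI estimator is biased at small n; significance is
  handled by permutation, but the MI *values* on edges should not be
  compared across different sample sizes.
* ISA robustness ratios are scale-dependent (Section 2); the filter
  threshold is a per-dataset choice, not a universal constant.
* The module landscape is a one-level simplification; hierarchical
  structure beyond the meta-graph is out of scope.
* Broker ranking requires the ncRNA to survive the DE filter first; a
  bridging ncRNA that is not differentially expressed is invisible to
  this pipeline by design.
* External validation joins (RNA–protein correlations, survival,
  TF enrichment) are pass-through tables only; nothing is fetched or
  computed from external services.
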