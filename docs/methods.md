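# Methods

## Model and estimation

Expression samples are treated as draws from a linear Gaussian structural
equation model over `d` genes: `x = Wᵀx + e`, with `w_ij ≠ 0` meaning gene
*i* is a parent of gene *j*. With samples as rows, `X(I − W) = E`, so the
fit minimizes the least-squares score `(1/2n)‖X − XW‖²` plus an L1 penalty,
subject to the support of `W` being acyclic.

Acyclicity is imposed through the smooth log-determinant function
`h(W) = −log det(sI − W∘W) + d·log s` (`s = 1` by default), which is zero
exactly on acyclic supports and positive on any in-domain matrix whose
support contains a cycle. Its analytic gradient is `2(sI − W∘W)⁻ᵀ ∘ W`. A
trace-of-matrix-exponential form, `tr exp(W∘W) − d`, is available as an
alternative backend; the two agree on the zero set, and the log-det form is
the one used by the solver because its domain acts as a built-in barrier
against cyclic iterates.

The constrained problem is solved by **path-following**: stage `k`
minimizes `μ_k(score + λ·L1) + h(W)` with `μ_k = μ₀·γᵏ`
(`μ₀ = 1, γ = 0.1`, 4 stages), each stage warm-started from the previous
solution. The inner solver is full-batch adaptive-moment (Adam) gradient
descent on the smooth part with the L1 term handled **proximally**: after
each Adam step the iterate is soft-thresholded by the effective
per-coordinate step size, which produces exact zeros instead of
subgradient dithering. If a step leaves the domain of `h` (the spectral
radius of `W∘W` reaching `s`), the step is halved until the iterate
re-enters the domain. The zero start is deterministic, so identical inputs
give bit-identical fits.

### Penalty scaling

The L1 penalty on `w_ij` is weighted by the standard deviation of the
predictor gene *i* (equivalent to running the lasso on standardized
predictors while keeping the raw equal-variance score). On SEM data whose
marginal variances grow along the graph, an unweighted penalty leaves
noise-scale coefficients whose size tracks the predictor's variance; with
the weighting, the selection threshold is scale-free and a single `λ`
separates signal from noise across all genes. The default `λ = 0.1` sits
two to three times above the noise scale of standardized partial
covariances at `n ≈ 1000`; `λ` is exposed, logged in the run manifest, and
should be reduced (e.g. to 0.02) for data that is already z-normalized
per gene.

### DAG extraction

`adaptive_threshold` scans cuts `t = t_start, t_start − t_step, …`
(defaults 0.3, 0.01, floor 1e-4) on `|w_ij|` and returns the graph at the
last cut whose graph is acyclic — i.e. the cut immediately before the first
cycle, or the floor when no cycle ever forms. Weights exactly equal to the
cut are excluded, and the scan is deterministic. The output always passes
an independent cycle check, and the number of edges is non-increasing in
the threshold by construction.

Edge directions are retained only for CPDAG conversion and provenance; all
topological analyses (communities, separators, centrality, overlap tests)
use the undirected skeleton.

## Structural analyses

- **CPDAG**: compelled edges are found by orienting v-structures
  (`x → z ← y` with `x, y` non-adjacent) and closing under Meek's rules
  R1–R3; starting from v-structures alone these rules are complete, so R4
  (which only matters under background knowledge) is omitted. Correctness is
  tested against brute-force enumeration of the Markov equivalence class for
  every DAG on ≤ 4 nodes.
- **Separator genes**: a gene qualifies if deleting it splits the main
  connected component into ≥ 2 components, each with at least
  `min_component_size` genes (default 7). Components other than the largest
  one become *modules*; separators isolating the same component are merged
  into one conditioning set.
- **Partial correlation** is the correlation of residuals after linearly
  regressing both genes on the conditioning set (with intercept); an empty
  set reduces exactly to Pearson r. Module reports pair every in-module gene
  with every outside gene and compare |plain r| to |partial r given the
  separators| with a paired one-sided t-test.
- **Knockout response**: `Z(A|B) = (Expr(A|B) − Mean(A|Ctrl)) / Std(A|Ctrl)`
  — a control-referenced z-score (the subtraction binds before the
  division; the control standard deviation uses `ddof=1` and must be
  positive).
- **Length-two overlap test**: a learned edge `(a, c)` counts as an overlap
  when the combined comparison network contains a path `a – b – c`. The
  null replaces the designated replaceable component with an Erdős–Rényi
  graph of identical node and edge count (50 replicates by default);
  significance is the upper-tail normal probability of the z-score against
  the sampled null mean and standard deviation.
- **Betweenness** is exact Brandes shortest-path betweenness
  (unnormalized by default; both exposed since conventions differ). "High
  betweenness" defaults to the top 5% of nodes with nonzero betweenness.

## GNN benchmarking protocol

Node features are a gene's expression across conditions; the propagation
operator is `D̂^(−1/2)(A + I)D̂^(−1/2)` over the declared gene universe, with
genes absent from a network kept as isolated self-loop nodes so their
features pass through the convolution unchanged. Variants: two to four
convolution blocks (`gcn2/3/4`), attention propagation with learned
per-edge weights normalized over neighbors (`attention`), a single affine
map over the squared operator (`simplified_k2`, algebraically equal to two
linear identity-affine propagations), neighbor-mean aggregation with
separate self/neighbor maps that accepts a training subgraph
(`sage_inductive`), and a graph-free MLP with the same three hidden layers.

Training is full-batch Adam on the masked train-gene MSE, so validation and
test targets can never influence parameters (verified by a
target-permutation test). The protocol is: stratified 70/20/10 gene split
(stratified on membership in the reference network, allocation per stratum
with rounding, deterministic per seed); seeded random hyperparameter search
(default space: hidden sizes {16, 32, 64, 128}, learning rate log-uniform
[1e-4, 3e-2] — full-batch Adam above ~5e-2 can destabilize the final
retrain — epochs {30, 50, 100, 150}) selected on validation MSE;
retraining of the winning configuration on train+validation; test MSE and
Pearson r. The whole process is replicated over `n_splits × n_inits` runs
(5 × 10 default), reported as mean ± standard error with two-sided Welch
t-tests between networks on per-run MSEs. Pearson r is computed per run and
averaged (undefined r from constant predictions is reported missing, not
zero). The epoch grid tops out at 150 because full-batch Adam on graphs of
a few hundred nodes converges well before that; the grid is configurable.

The tensor backend is a small in-package reverse-mode autodiff engine over
dense numpy arrays (`latentdag._autodiff`), sufficient for full-batch
training at these graph sizes.

## Embedding clustering

Embeddings are the post-activation output of the last convolution layer of
the selected model (lowest test MSE across replicates, ties broken by run
index). The clustering pipeline standardizes each embedding dimension,
applies a neighborhood-preserving low-dimensional embedding (default
backend: UMAP with 20 components, 7 neighbors; a spectral k-NN-graph
fallback and a pass-through are provided — the contract is
neighborhood preservation, not a specific library), then runs density-based
hierarchical clustering: single linkage over mutual-reachability distances
(core distance = distance to the `min_samples`-th neighbor, default 10),
cut top-down at the highest merges into exactly `n_clusters` flat clusters.
Side branches smaller than `min_cluster_size` (default 10) fall out as
noise and keep the label −1. Requesting more clusters than the hierarchy
supports raises an error that reports the achievable maximum.

Clusterings are scored by the distribution of pair scores (e.g. expression
correlation or external interaction confidence) over all `C(m, 2)`
within-cluster pairs, pooled across clusters; two clusterings are compared
with a two-sided Welch t-test on the pooled distributions. Pairs missing
from the score table receive a configurable default (0) and are counted.

## Synthetic data: what it emulates, and what it does not

The generators emulate a z-normalized genes-by-conditions screen driven by
a known linear Gaussian SEM: random ER or preferential-attachment DAGs,
uniform ±[0.5, 2] coefficients (homoscedastic unit noise by default, which
keeps the equal-variance model identifiable so recovery tests are
meaningful), per-gene knockdowns implemented as a −5 shift of the gene's
exogenous mean propagated through the SEM (interventions reach descendants
only), and per-gene scalar targets
`y_i = mix · mean(neighbor feature means) + (1 − mix) · own feature mean + ε`
with `mix = 0.8` for graph-informative targets. Module fixtures use
disjoint, densely connected sub-DAGs with positive (co-activating) weights
so module members are positively co-expressed — with mixed-sign weights
within-module genes can be anti-correlated and no Euclidean clustering
pipeline would (or should) group them.

Not emulated: count-level single-cell noise (UMIs, dropout), nonlinear
regulation, batch or cell-cycle structure, measurement error in the
knockdowns, or unobserved confounders. Passing tests therefore demonstrate
correctness of the algorithms and their qualitative behavior under the
stated model, not performance on real screens.

Problem sizes used in the test suite are deliberately compact — e.g.
20 genes / 1000 samples for recovery, 300 genes / 50 conditions for the
network-ranking protocol, 100 genes in 5 modules for clustering — chosen as
the smallest scales at which the respective effects are stable across
seeds.

## Numerical choices and degenerate inputs

- Ties at the binarization threshold are excluded (strict `>`); scans are
  column-major and deterministic.
- Zero-variance genes are dropped (with a warning) before correlation
  networks; an all-constant matrix is an error.
- The turning-point rule for co-expression thresholds maximizes the
  discrete second difference of `log(1 + edge count)` over the grid and
  reports "no turning point" when that curvature profile is flat or
  monotone.
- Welch's t-test is computed from its closed form (Welch–Satterthwaite
  degrees of freedom); identical groups give t = 0, p = 1.
- The active/variable gene filter combines the mean-percentile and
  sd-percentile gene sets by union by default (intersection available);
  region scores average per-base values over 0-based half-open intervals,
  strand-agnostic, and report genes with no covered base as missing.
- All randomness flows through explicit integer seeds; derived seeds are
  spawned from a single master seed and kept below 2³¹.

## Known limitations

- The learner assumes complete, finite matrices; missing values fail fast.
- Scale-free generation cannot hit an arbitrary edge count exactly (only
  the ER model guarantees it); the attachment parameter approximates it.
- The attention variant materializes dense `n × n × k` score tensors and is
  only intended for graphs of a few hundred nodes.
- Exact flat cuts of the density hierarchy can be impossible when the data
  has fewer well-populated density modes than requested; the error reports
  the achievable maximum rather than silently merging.
- Recovery quality degrades when SEM coefficients approach the noise scale
  (below ~0.3 at n = 1000) or when the data is standardized per gene, which
  destroys the variance ordering that makes the equal-variance direction
  identifiable.
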