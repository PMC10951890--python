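# Methods

## Problem and model

The package predicts circRNA–disease associations as link prediction on a
tri-partite heterogeneous network G over node types C (circRNAs), M
(miRNAs) and D (diseases), with binary adjacency matrices A_CD (m×n), A_CM
(m×p) and A_MD (p×n). The modelling assumption throughout is guilt by
association: similar circRNAs tend to associate with similar diseases, and
miRNAs are informative intermediaries (circRNAs can act as miRNA sponges),
so paths through M carry signal that the bipartite C–D network alone does
not.

## Similarity layers

*Metapath similarities.* A metapath is a type sequence such as C-D-C; an
instance is a walk following it. Instance counts are pure matrix products,
so walks may revisit nodes — the worked toy example (c4's self-count of 3
via its three diseases) confirms walk semantics rather than simple paths.
PathSim for a palindromic path is `2·M[x,y]/(M[x,x]+M[y,y])` with the
convention 0 when the denominator vanishes. HeteSim splits an even-length
palindromic path at its middle type and takes the cosine of the two
reach-probability vectors (chained row-stochastic transition matrices);
all-zero rows stay zero and yield similarity 0, avoiding NaN on sparse
data. Both conventions matter in practice: real association networks have
many degree-0 rows. Per node type, the HeteSim/PathSim terms entering the
integration are the unweighted mean over that type's four standard
metapaths ({CDC, CMC, CDMDC, CMDMC} and {DCD, DMD, DCMCD, DMCMD}); there
is no principled basis for unequal weights, and the set is configurable.

*Semantic similarity.* Diseases covered by an ontology DAG get the Wang
measure: each ancestor contributes Δ^hops along its best path (Δ = 0.5,
exposed in configuration), the semantic value DV is the contribution sum,
and pairwise similarity is the shared-ancestor contribution sum normalised
by DV_i + DV_j. Uncovered disease pairs fall back to the GIP kernel
(bandwidth normalised by the mean squared interaction-profile norm; an
all-zero interaction matrix falls back to the identity).

*circRNA layers.* Expression similarity is the Spearman rank correlation
(average ranks on ties; pairs involving a constant profile are undefined
and flagged uncovered rather than invented). Functional similarity
best-match-averages the integrated disease similarities of the two
associated disease sets; circRNAs without diseases get a zero row apart
from the unit diagonal. Where expression exists the biological layer is
the plain average 0.5·(SF+SE), otherwise SF alone.

*Integration.* SD = 0.5·SD_bio + 0.25·HeteSim_D + 0.25·PathSim_D and
analogously SC; weights must sum to 1 and are validated. Functional
similarity is computed *after* SD, since it consumes the integrated
disease similarity.

## Feature extractors

All three extractors consume the integrated similarity rows as node input
features. miRNA nodes, which the similarity integration does not cover,
use a GIP kernel over their A_MD interaction rows — a deliberate design
choice to give metapaths through M meaningful intermediate features.

*Metapath attention (F1).* Type-specific projections W_type map similarity
rows to a shared l-dimensional space. Each metapath instance is encoded by
the elementwise mean of its nodes' projected features (a linear encoder is
available via configuration; the mean is the default because it is
parameter-free and order-insensitive for palindromic paths). Per metapath
and head, instance attention is additive: e = LeakyReLU(αᵀ[h'_anchor ‖
h_instance]), softmax over the anchor's instances, ELU of the weighted
sum; the K head outputs are concatenated. A second attention level
summarises each metapath (tanh affine map averaged over the type's nodes,
scored against a query vector) and softmax-fuses the per-metapath vectors.
Anchors without instances receive zero vectors. Instances per anchor and
metapath are capped at 32 by drawing a uniform subset *without*
replacement — implemented by unranking seeded random ranks against suffix
counts, so no exhaustive enumeration is ever materialised. Training
minimises mean binary cross-entropy of σ(h_cᵀh_d) on the training pairs
(the raw inner product is squashed through a logistic so the log is always
defined), full-batch Adam, lr 1e-3, 200 epochs, K = 8 heads, l = 64. The
batch is the full training set: at desk scale one minibatch per epoch is
the entire data, which keeps runs bitwise reproducible.

*Similarity-regularised NMF (F2).* Objective
‖W∘(H−CDᵀ)‖² + α(‖C‖²+‖D‖²) + λ(‖SC−CCᵀ‖²+‖SD−DDᵀ‖²) with C, D ≥ 0.
Optimisation is alternating multiplicative updates in
numerator/denominator form derived from the gradient split; because SC/SD
may contain negative entries (Spearman correlations), their positive and
negative parts are routed to numerator and denominator respectively. Each
factor update is damped by a backtracking exponent γ ∈ (0, 1] halved until
the objective does not increase, so the recorded objective trace is
nonincreasing by construction on every instance (γ → 0 recovers the
current iterate). Initialisation is |N(0,1)| scaled by √(mean(H)/r);
defaults r = 64 (clipped to min(m,n)−1), α = 0.01, λ = 0.1, tol = 1e-6,
max_iter = 500. During cross-validation the indicator W marks exactly the
training pairs (positives and sampled negatives), so held-out cells never
enter the loss.

*GraphSAGE (F3).* The graph is the union of training C–D edges with all
C–M and M–D edges; no similarity-thresholded edges are added (that would
introduce an undocumented threshold). Two layers with fan-outs (10, 10):
degree ≥ fan-out samples without replacement, smaller degrees sample with
replacement, isolated nodes aggregate themselves. Aggregation is
mean-then-affine with ELU (chosen over ReLU to avoid dead units in the
small projected space). Neighbourhoods are resampled each epoch from an
epoch-derived seed. The training signal reuses the link BCE above
(150 epochs, lr 5e-3, Adam).

The two gradient-trained extractors run on a small reverse-mode automatic
differentiation module written for this package (`elcda/_autograd.py`,
numpy only): broadcasting arithmetic, 2-D matmul, a two-operand einsum,
the needed activations, reductions, gathers and Adam. All parameters are
seeded `default_rng` draws, so fixed seeds give bitwise-identical
embeddings.

## Ensemble and evaluation

Pair features are [F(c) ‖ F(d)] with F = [F1 ‖ F2 ‖ F3]. Five classifiers
are fitted with library defaults and fixed seeds: an RBF SVM wrapped in
standard scaling and logistic (Platt-style) calibration on internal
training folds, a random forest, XGBoost, LightGBM and Gaussian naive
Bayes. Fusion is the unweighted mean of the five positive-class
probabilities (soft voting); classifiers are trained on the concatenated
features (5 models), not per-extractor (3×5), matching the concatenate-
then-classify algorithm statement.

Negatives are drawn uniformly without replacement from unobserved cells,
one per positive (balanced). Folds are stratified by label. The default
protocol is leakage-safe: for every fold, metapath counts, GIP, functional
similarity, the integrated SC/SD, the factorisation indicator and the
GraphSAGE edge set are recomputed from training-fold positives only; a
`paper_mode` flag computes similarities once from all positives, since
published evaluations of this family of methods rarely state fold-wise
recomputation and the two protocols are worth comparing. Metrics are the
confusion-matrix family at threshold 0.5 (the threshold is a convention,
exposed as a flag), AUC as the rank statistic, and AUPR by trapezoidal
integration of the precision–recall curve. Single-class fold labels report
AUC/AUPR as absent rather than a number.

## Synthetic data

The generator plants shared nonnegative rank-r factors U (circRNAs), V
(diseases), Z (miRNAs); each relation is Bernoulli(logistic(a·S + b)) with
S the standardised factor product, a = 4 fixed signal strength, and the
intercept b calibrated by bisection to the target density — emulating the
extreme sparsity skew of curated association data with a controllable,
recoverable signal. Expression profiles are U·G plus Gaussian noise
(sd 0.1, 10 samples), so expression similarity correlates with the planted
structure; the disease DAG is a random rooted tree over all diseases plus
a few forward cross edges. Default study conditions: m = 60, p = 30,
n = 40, r = 4, C–D density 0.05, C–M and M–D density 0.10, seed 0. These
sizes mirror the relative proportions of real curated data (circRNAs >
miRNAs > diseases, C–D sparsest) at a scale where exhaustive oracles
remain feasible.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline recovers planted low-rank structure without leaking
held-out edges and stays at chance on permuted labels; they do not
demonstrate performance on real curated networks, whose degree
distributions are heavier-tailed, whose similarities carry database biases
and whose negatives are unverified non-associations rather than true
negatives. The worked-example toy network is pinned exactly (the two
adjacency rows the example fixes plus the completion c1={d1}, c3={d2},
c5={d3} implied by the printed transition matrices).

## Numerical conventions and limitations

Zero-degree rows stay zero through every transition/normalisation (no
NaN); PathSim/HeteSim return 0 when undefined; attention over an empty
instance set returns a zero vector; fully-masked softmax slices return
zeros rather than NaN. Probabilities are clipped only inside the logistic
(|logit| ≤ 60) and BCE adds 1e-12 inside the log. Ties in Spearman ranks
use average ranks. The factorisation backtracking tolerance is 1e-12
relative; the monotonicity assertion tolerance is 1e-9.

Known limitations: no weighted edges and no gene nodes; the ADMM-style
update family mentioned in the literature is deliberately replaced by
multiplicative updates, trading convergence speed for provable
nonnegativity and a testable monotone objective; attention and GraphSAGE
training are full-batch and CPU-bound, sized for desk-scale networks
(hundreds of nodes) — published-scale data (thousands of nodes) would need
minibatching and sparse instance tables; and the prediction tables rank
*candidate* associations, which require literature or wet-lab confirmation
before any biological claim.
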