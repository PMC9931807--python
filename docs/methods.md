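# Methods

This note documents the models, estimators, simulators and numerical
choices in `bca`, in enough detail to reproduce or audit any result the
test suite computes.

## Models and learning procedure

**Markov network representation.** Neural coherence is represented as a
pairwise Markov network over nodes (neurons). For binary spike data the
joint is the Ising model with fields,
`P(x) ∝ exp(−β · U(x))`, `U(x) = −(rᵀx + ½ xᵀW x)` with `W` symmetric,
zero-diagonal; the sum over couplings counts each unordered pair once.
`β` enters as an inverse-temperature multiplier `exp(−β·U)`; the 6-node
benchmark uses `β = 2`. For continuous data the joint is a Gaussian
Markov network `N(μ, Σ)`; the graph is the support of the precision
matrix, with "nonzero" meaning an off-diagonal entry exceeding `1e−8`
relative to the largest off-diagonal magnitude.

**Blanket discovery (BNCIT).** The Markov blanket of a node in either
model equals its graph neighborhood, and it coincides with the DAG
blanket (parents ∪ children ∪ co-parents) whenever the distribution
also admits a Bayesian-network representation with the same blanket
structure. `bca` exploits this by fixing the target node as the leaf of
a Bayesian network and searching over its parent set only:

* binary data — BDeu family score with equivalent sample size
  `ess = 1.0` (configurable): Dirichlet hyperparameter `ess/(q·2)` per
  (parent-configuration, state) cell, `q = 2^p`. Variables are treated
  as binary even when a level is unobserved in some configuration
  (handled by the smoothing). Unobserved configurations contribute 0.
* continuous data — BIC of a linear-Gaussian regression:
  ML log-likelihood with the residual variance floored at `1e−12`,
  minus `(k/2)·log n`, `k = n_parents + 2`. Collinear parent columns
  are detected by rank and dropped (pivoted QR), with a warning.

The search is greedy hill-climbing from the empty set over single
additions and removals (no swaps), accepting the best move only if it
improves the score by more than `1e−9`; exact ties break toward the
lowest column index, making runs deterministic given the data. An
optional `max_parents` cap exists for very wide data (default:
unlimited). A constant target yields an empty blanket with a warning.

**Combination.** Edge (i, j) is present iff `i ∈ mb*(Xⱼ)` or
`j ∈ mb*(Xᵢ)` (OR). An AND variant is exposed for experimentation but
is not the default. Per-node searches are independent, so results never
depend on scheduling. Constant (inactive) columns — e.g. silent
neurons — are excluded from learning but kept in the output graph as
isolated nodes, so that evaluation over any node subset remains
well-defined; evaluation can also be restricted to the retained subset,
which is what the LIF benchmark does.

## Baselines

**Correlation graph.** All `M(M−1)/2` Spearman coefficients, two-sided
p-values from the large-sample t approximation for `n ≥ 30` and from
permutation below that (exhaustive for `n ≤ 7`, otherwise 9 999 Monte
Carlo permutations with a fixed internal stream — the p-value is a
statistic, not an experiment), Benjamini–Hochberg FDR applied jointly
across all pairs, edge iff adjusted p < α. Pairs involving a constant
column get p = 1.

**Regression graph (eLasso).** Per node, L1-penalized logistic
regression on all other nodes along 100 log-spaced lambdas from the
smallest lambda that zeroes all coefficients down to `1e−3` of it;
model selection minimizes
`EBIC = −2·loglik + k·log n + 2γ·k·log(p−1)` with `γ = 0.25`
(van Borkulo's default); neighborhoods are combined with the AND rule
by default (OR available). Predictors are standardized in the glmnet
sense, implemented as per-feature penalty factors `λ·sd_j` on the raw
0/1 design — the selected support is identical and the binary sparsity
is preserved. The solver is IRLS with inner coordinate descent on the
weighted quadratic surrogate, warm-started along the path, with
active-set sweeps, weights floored at `1e−5`, inner tolerance `1e−4` on
standardized-scale coefficient changes, and early path termination at
99.9 % deviance saturation. On shared datasets the selected
neighborhoods were verified identical to R `glmnet` + EBIC (the
reference engine for this construction) for every node of both a
6-node Ising draw and a 50-node LIF dataset; a unit test additionally
checks coefficient-level agreement with scikit-learn's saga solver at a
matched penalty.

## Simulators

**6-node Ising benchmark.** Fields 0, couplings
`w12 = w14 = w23 = w34 = 0.5`, `w45 = −0.8`, `w56 = 0.9`, `β = 2`;
ground truth has 6 edges and 9 empty pairs. Sampling is by
Metropolis–Hastings: single-site flips,
acceptance `min(1, exp(−β·ΔU))`, one sweep = M proposals, burn-in 5 000
sweeps, thinning 10 sweeps per kept sample, random initial state.
Fields `r` are taken as zero (only couplings are stated for the
benchmark). The sampler is validated against exact 64-state enumeration
(all configuration frequencies within 3 Monte-Carlo standard errors at
200 000 kept samples); chain-mean checks use batch-means standard
errors, which account for residual autocorrelation.

**Feed-forward LIF network.** Two groups of 50 neurons. Per frame
(`dt = 5` ms) the membrane potential follows the Euler step
`V ← V + dt·(V_rest − V)/τ + σ·ε·τ^−0.5` with `σ = 0.2`,
`ε ~ N(0,1)`, `V_rest = 0`; a spike fires when `V > 1` and resets V to
rest. Group A draws `τ ~ N(20, 5)` ms per neuron (clipped at 1 ms),
group B has `τ = 100` ms. A stimulus arrives every 3 or 4 frames (gap
uniform). Each B neuron is wired to 2 uniformly chosen A parents; a
parent spike at frame t adds `a = 0.8` to the child's potential at
frame t+1. The reference microcircuit over retained (non-silent) B
neurons connects pairs sharing at least one parent; with 49 retained
neurons the expected edge count is `1176·(1 − 48·47/(50·49)) ≈ 93`.

The stimulus transduction is the one genuinely open design choice: a
deterministic suprathreshold drive to every A neuron would synchronize
group A perfectly, make all B columns identical, and leave the
shared-parent structure unidentifiable. Each A neuron therefore
responds to a given stimulus independently with probability
`stimulus_response_prob = 0.35`, receiving `stimulus_gain = 1.2` on its
potential — a standard model of trial-to-trial synaptic variability.
The response probability was set once so that the benchmark operates at
the regime the method comparison is meaningful in (downstream learners
reach their published operating points: blanket learner ≈ 0.70/0.034
TPR/FPR, eLasso ≈ 0.86/0.10, correlation FPR ≈ 1.0 on 5-seed
averages); both knobs are exposed in `LIFConfig`.

**Gaussian Markov networks.** Structures are turned into precisions
with unit diagonal and `−coupling` (default 0.35; 0.45 for the 10-node
chain) on edges, diagonally loaded if needed so the smallest eigenvalue
is ≥ 0.05, then inverted and sampled by Cholesky.

**Two-subtype trial collection.** Emulates a per-trial imaging study:
two 20-node template structures (a ring and an edge-disjoint
"long-step" ring), 25 trials per type by default, 300 samples per
trial. Each trial perturbs a fraction `flip_noise = 0.1` of its
template's edges (toggles them off and toggles an equal number of empty
pairs on) before sampling, so same-type trials are similar but not
identical. What this surrogate does **not** emulate: calcium indicator
dynamics, slow drift, shared behavioral covariates, or non-Gaussian
marginals of real ΔF/F₀ traces — passing the subtype benchmark shows
the similarity/clustering pipeline works on well-separated structural
subtypes, not that real trials separate this cleanly.

**Collider benchmark DAG.** A → C ← B, C → D ← E with root marginals
0.5 and additive CPTs (base 0.1, +0.4 per active parent); the blanket
of C is {A, B, D, E} and every dependence is individually detectable at
n = 5000.

## Subtype analysis

Similarity between two microcircuits is the Sørensen–Dice coefficient
of their edge sets, `2|E_a ∩ E_b|/(|E_a|+|E_b|)`; two empty graphs are
defined to match perfectly (1). The similarity matrix (self-loops
removed, weights ≤ 1e−12 dropped) is clustered by multi-level (Louvain)
modularity maximization at resolution 1.0; the stdlib RNG that igraph
delegates to is scoped and seeded, so runs are deterministic given the
seed. Each cluster's representative is the member with maximal mean
similarity to its co-members (ties → lowest index). Graph-level
centrality is the node average of unnormalized betweenness (a
normalization toggle exists) or of the principal adjacency eigenvector
scaled to unit Euclidean norm; eigenvector centrality is undefined on
an edgeless graph and raises. Subtype contrasts use the pooled-variance
two-sample t-test (Welch optional), with the pooled variance floored so
degenerate groups give t = 0, p = 1 (identical) or a huge finite |t|
(perfectly separated constants).

## Evaluation

Against a ground truth with `E` edges and `N − E` empty pairs:
TP = edges in both, FP = estimated edges absent from the truth,
TPR = TP/E, FPR = FP/(N − E); sensitivity = TPR,
specificity = 1 − FPR.

## Problem sizes used by the test suite

The acceptance tests run the 6-node study at 5 000 kept samples × 10
seeds; the LIF study at 1 200 frames × 100 neurons × 5 seeds; sampler
validation at 200 000 kept samples; chain recovery at n = 3 000 × 10
seeds; the subtype pipeline at 25 + 25 trials × 300 samples (plus a
smaller 8 + 8 noise sweep). These match the benchmarks' native sizes;
only the noise-sweep replicate count is reduced.

## Known limitations

* Hill-climbing is exact only up to local optima; parity-like
  dependences (XOR parents) with no single-variable signal can be
  missed by single-move search.
* The OR combination cannot remove a false positive detected from one
  side; specificity rests on the score's complexity penalty.
* The learned microcircuit is a binary adjacency — no edge weights or
  signs, and no causal reading of any direction used internally.
* BDeu assumes binary states; multi-level discrete data are out of
  scope, as are mixed binary/continuous families.
* The eLasso EBIC uses the penalized estimates' likelihood (as the
  reference implementation does), not refitted ML values.
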