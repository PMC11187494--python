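# Methods

## Model and procedure

Graphical ensembling treats ensemble feature selection as a graph
optimization problem. A roster of base feature-selection techniques is run
on the training portion of each cross-validation fold, giving an importance
tensor `I(f, s, i)` over selectors `f`, folds `s` and features `i`. Two
aggregations are supported:

* the **co-selection matrix** `M[i, j] = Σ_{f,s} B(f,s,i)·B(f,s,j)`, where
  `B` marks each slice's top-`t` features (a "selection event"); its
  diagonal `M[i, i]` is the per-feature selection count used by classical
  majority voting;
* the **co-importance graph** with edge weights
  `w(i, j) = Σ_{f,s} min(I(f,s,i), I(f,s,j))` — treating a feature's
  importance as a capacity, an edge carries the most limiting capacity of
  the pair.

The signature is the `k`-subset of nodes maximizing the induced edge-weight
sum (Heaviest k-Subgraph). The intuition: a pair of features gets heavy
weight only if many selectors on many folds consider *both* valuable
simultaneously, so maximizing induced weight favours sets of features that
are jointly, robustly proposed — and, with redundancy-aware base selectors
(below), complementary rather than interchangeable.

Assumptions: features are real-valued after preprocessing; labels are
categorical with at least two classes and enough members per class to
stratify; base selectors return non-negative per-feature scores and are
deterministic given a seed.

## Base selector roster

The co-importance aggregation inherits its semantics from the base
selectors: it can only de-duplicate what the base selections already
distinguish. Redundancy-blind univariate filters (F-statistic, mutual
information, |Pearson|, chi-squared, variance) assign near-identical scores
to correlated copies of one signal; their pairwise minima are then *higher*
within a correlated group than across groups (correlated scores are jointly
high more often), and the heaviest subgraph degenerates into a redundant
clique. The default roster therefore uses seven techniques that each
concentrate weight on a low-redundancy subset per fold while spanning
paradigms:

| id | paradigm |
|---|---|
| `l1_logistic` | sparse linear, logistic loss |
| `l1_svm` | sparse linear, hinge loss |
| `decision_tree` | single CART, greedy axis-aligned splits |
| `gradient_boosting` | boosted trees (50 rounds) |
| `random_forest` | bagged trees (100 trees) |
| `mrmr` | greedy max-relevance (F-score) minus mean-|correlation| redundancy |
| `rfe_logistic` | recursive feature elimination wrapper |

The filter selectors remain registered for use on data without correlated
duplicates; the roster is a plain list argument everywhere. `mrmr` and
`rfe_logistic` propose explicit subsets capped at 25 features per fold.

Importance normalization is per-(selector, fold) division by the slice
maximum, so every slice peaks at 1 (an all-zero slice stays zero). Without
a common scale, selectors with large raw score ranges would dominate the
co-importance sum. Binarization keeps the `t` highest-importance features
of a slice, ties broken by lexicographic feature id; `t` defaults to `2k`,
keeping the co-selection graph richer than the final signature but small.

## Heaviest k-subgraph solvers

`solve_exact` is a depth-first branch and bound over include/exclude
decisions on nodes ordered by decreasing strength (weighted degree), with
the greedy solution as initial incumbent. At a search node with `r` slots
left, the upper bound is the current induced weight plus the sum of the `r`
largest optimistic gains over eligible nodes, a node's gain being its full
connection to the chosen set plus half the sum of its `r − 1` heaviest
edges to other eligible nodes. Halving the eligible-eligible edges makes
the bound admissible (each such edge is counted from both endpoints);
using `r − 1` rather than `k − 1` edges tightens it, since a completion
adds only `r` nodes. Co-optimal subsets are resolved to the
lexicographically smallest id sequence; the float tolerance for
objective/bound comparisons is 1e-9. The exact solver refuses instances
above 500 nodes by default (NP-hardness); `solver="auto"` then falls back
to the greedy heuristic, which seeds with the heaviest edge and repeatedly
adds the node with the largest marginal gain (all ties lexicographic).

The diagonal selection counts `M[i, i]` are node metadata only and are not
part of the optimization objective, which sums over *pairs*; features with
zero importance everywhere are excluded from the graph since they cannot
contribute positive induced weight.

## Pipeline and model selection

`make_split_plan` fixes a stratified test holdout (default 20%) and
stratified K-fold CV (default 5) on the remainder, fully determined by a
seed. Normalization is per-feature z-scoring with location/scale estimated
from fold-training rows only (sample SD, ddof 1; constant features get
scale 1 and transform to 0). Candidate classifiers (regularized logistic
regression, random forest, k-NN, Gaussian naive Bayes, and a soft-voting
ensemble of the first three) are fitted per fold on the
signature-restricted normalized data. Metrics are balanced accuracy
(unweighted mean of per-class recalls) and support-weighted
precision/recall/F1, with zero-division mapped to 0.

Model selection applies a sanity constraint — the candidate's
|mean train − mean validation| on the primary metric (default BA) must be
at most τ (default 0.10) — and among passing candidates picks the highest
mean validation value; ties go to the smaller gap, then the
lexicographically smaller model id. If nothing passes, the configurable
fallback returns the minimal-gap candidate with a warning (or raises).
The chosen model is refitted on all non-test rows and evaluated on the
test set exactly once.

## Network evaluation

The interactome is an undirected simple graph of gene symbols
(case-sensitive after whitespace stripping; no alias resolution). The
disease module is the largest connected component induced by a disease
gene list; ties between equal-sized components go to the one containing
the lexicographically smallest symbol. Distance of a signature gene to the
module is the hop count to the nearest LCC node (0 inside the LCC);
intra-signature distance is the mean over unordered present pairs. Genes
absent from the graph or unreachable pairs are excluded from means and
reported as counts — no arbitrary large-constant imputation. Random
references sample the requested number of genes without replacement, one
signature per seed. The over-representation test is the hypergeometric
upper tail `P(X ≥ k)` including the observed overlap, with the point
probability `C(n,k)·C(M−n,N−k)/C(M,N)` computed by `scipy.stats.hypergeom`
(log-space internally, stable for large `M`).

## Synthetic data generator

The generator emulates the target regime: `n_groups` latent class signals,
each realized as `group_size` correlated feature copies
(`feature = √ρ·z_g + √(1−ρ)·ε`, giving within-group correlation exactly ρ
and unit variance within class), plus independent standard-normal noise
features. Class centers are `effect_size` SD apart per feature (two classes
by default, "case" on the high side; multi-class spreads centers evenly).
Defaults are 300 samples, 5 groups × 3 copies at ρ = 0.9, 150 noise
features, effect 1.5 SD, balanced classes. The toy interactome is a
preferential-attachment graph (connected by construction) with a connected
disease module collected by deterministic BFS from the highest-degree
node.

What it does *not* emulate: count-distributed transcriptomic noise, batch
effects, missing data, non-Gaussian tails, or realistic PPI topology
beyond heavy-tailed degrees. Passing the recovery tests therefore shows
that the graph aggregation de-duplicates correlated Gaussian copies and
rejects independent noise at realistic sample sizes — not that it handles
cohort-level artifacts.

## Numerical and design choices

* Deterministic lexicographic tie-breaks everywhere (binarization,
  solvers, baselines, model selection), for bit-identical reruns across
  platforms.
* Selector or classifier failure on a fold degrades gracefully (all-zero
  slice / dropped candidate, with a warning) rather than aborting a run.
* Degenerate inputs: all-zero importance slices stay zero through
  normalization; a co-importance graph smaller than `k` is padded with the
  lexicographically smallest leftover features at zero objective weight; a
  constant feature scores 0 for every selector.
* Problem sizes in tests and the acceptance script (graphs of 6–14 nodes
  for enumeration oracles, 300 × 165 planted tables over 20 seeds,
  400-node toy interactomes) were chosen as the smallest instances that
  exercise every code path meaningfully while keeping full reruns on a
  single CPU in minutes.

## Known limitations

* The exact solver's worst case is exponential; the node budget is a guard,
  not a guarantee, and adversarial near-uniform weight graphs can be slow
  well below 500 nodes.
* The co-importance construction assumes base-selector importances are
  comparable after max-scaling; a selector with a pathological score
  distribution (e.g. one extreme outlier) compresses the rest of its slice
  toward 0.
* With redundancy-blind rosters the method's complementarity property
  degrades by design of the objective (see the roster section); roster
  choice is part of the modeling, not a free hyperparameter.
* Network metrics ignore edge confidence and degree bias; random
  references are not degree-preserving.
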