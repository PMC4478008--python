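# Methods

## Trait model

A discrete trait with *k* states evolves along the phylogeny as a
continuous-time Markov chain with the equal-rates ("ER") generator: every
off-diagonal rate equals *q* (units: expected transitions per ordered state
pair per unit branch length, branch lengths in expected substitutions per
site), diagonals −(k−1)q. The closed-form transition probabilities

P_ii(t) = 1/k + (k−1)/k·e^(−kqt),  P_ij(t) = (1 − e^(−kqt))/k

are used everywhere; a matrix–vector product collapses to
`e·v + (1−e)/k·sum(v)` with e = e^(−kqt), so the pruning recursion costs
O(nodes·k) rather than O(nodes·k²). The root prior is uniform — which is
also the ER stationary distribution, so the chain is time-reversible and
the likelihood does not depend on root placement. Likelihoods use
Felsenstein's pruning algorithm with per-node rescaling (log-scale
accumulation), which keeps trees with thousands of tips away from
underflow. Polytomies and zero-length branches (P = I) are handled; missing
tips contribute a vector of ones.

## Tip imputation

For a query tip *e* the tree is pruned to *e* plus all annotated reference
tips (unifurcations suppressed, merged branch lengths summed; the pruned
tree is rooted at the MRCA of the retained set). The ER rate is fitted by
maximum likelihood with *e* as missing data — numerically identical to a
reference-only fit — using deterministic bounded Brent minimization on
q ∈ [1e−8, 100] with xatol 1e−8. Because bounded Brent never evaluates the
endpoints, both endpoints are checked explicitly afterwards and ties
resolve to the endpoint; `at_bound` flags estimates within 1e−6 of either
bound (monotone cases: all references identical → lower bound; saturated
variation → upper bound).

The imputed vector is the marginal posterior at the query tip, computed by
the standard two-pass (down/up) marginal algorithm. For reversible ER with
a uniform prior this equals the recipe "reroot at the ancestor of the query
and its closest relative, reconstruct the state at that root from the
references, propagate across the query's pendant branch"; the tests assert
this equivalence against a brute-force enumeration oracle and verify
rerooting invariance directly. One ER model is fitted per query and per
trait field (k = number of labels in that field).

Two-stage classification: queries with P(spore_pigment) > 0.5 are excluded
as putative pigment loci (threshold configurable); chemotype vectors are
then computed for the remainder against the antibiotic references only,
and calls with modal probability ≥ 0.75 are flagged confident. Both
thresholds are ordinary config keys, not hard-coded magic.

## Trait clustering test

For a trait occupying m tips, Faith's PD (branch-length sum of the minimal
spanning subtree, measured below the MRCA; singleton → 0) is compared with
the PD of `n_draws` uniform random m-subsets of tips (default 10,000). The
score is the rank quantile (1 + #{draw PD ≤ observed PD})/(n_draws + 1).
Ties count as ≤ observed — conservative toward non-clustering — with a
relative tolerance of 1e−9, because floating-point sums of identical branch
sets can differ in the last ulp (without the tolerance the star-tree
degenerate case would not score exactly 1). A trait covering every tip is
degenerate and reported as quantile 1 with a warning. Under the null the
quantile is uniform on {1,…,n_draws+1}/(n_draws+1); the tests verify this
by Kolmogorov–Smirnov.

## Sequence groups

Percent identity is computed pairwise on the input alignment: columns where
both sequences have gaps are excluded; columns where exactly one has a gap
count as mismatches (a config switch excludes them instead); N matches
nothing; an empty comparable region yields identity 0 with a warning.
Binning traverses the tree from the tips toward the root and collapses
every maximal clade whose descendant tips are pairwise ≥ x% identical — the
furthest-neighbour criterion restricted to clades. Consequences, tested as
invariants: every intra-group pair meets the cutoff; groups at a lower
cutoff are unions of groups at a higher cutoff; group counts are monotone
in the cutoff. Sequences that are similar but phylogenetically separated
deliberately land in different groups (the collapse never crosses clades).
A reporting utility tabulates, per cutoff, how many reference-containing
groups mix chemotypes — the natural way to choose the binning threshold.

## Community matrices and dissimilarity layers

Rarefaction subsamples each sample without replacement to a common depth
(samples below depth are dropped and logged); each sample has its own RNG
substream derived from (seed, SHA-256 of the sample id), so results do not
depend on sample order. Group tables sum member columns (totals conserved);
trait tables are the matrix product counts × probability vectors, so each
row sums to the sample's sequence count — trait "pseudo-abundances".

Three layers: Bray-Curtis on group counts; normalized weighted UniFrac on
the sequence table (per branch b: l_b·|A_b − B_b| with A, B the fractions
of each sample's counts below b, normalized by Σ l_b(A_b + B_b), the score
of fully disjoint communities, so values lie in [0,1]; the unnormalized
variant is a flag); Bray-Curtis on the trait table. The weighted UniFrac
implementation is cross-checked in the tests against scikit-bio's.

## Spatial and driver statistics

All permutation tests permute rows and columns of one matrix simultaneously
and report p = (1 + #extreme)/(n_perm + 1) from a seeded generator
(default 999 permutations).

- **Mantel / partial Mantel** — Pearson correlation of lower triangles
  (Spearman optional); partial version residualizes both triangles on a
  conditioning matrix. The distance-decay slope regresses log10
  dissimilarity on log10 geographic distance; zero distances are excluded
  or floored at 0.01 m (sampling grain) by config. The 95% slope CI is a
  residual-randomization percentile interval driven by the same permutation
  stream as the test — the randomization-CI family of approaches; the exact
  published construction behind such CIs is not specified to equation
  level anywhere the package could follow, so this choice is recorded here.
- **ANOSIM** — R = (mean between-rank − mean within-rank)/(N(N−1)/4) with
  label permutation; cross-checked against scikit-bio.
- **MRM** — OLS of the response triangle on predictor triangles;
  per-coefficient two-sided p by permuting the response matrix and
  refitting (response permutation, not residual permutation — the simplest
  scheme; noted as a choice). Collinear predictors (condition number
  > 1e10) are rejected with the offending pair named.
- **bioenv** — variables min-max scaled to [0,1], constants dropped;
  exhaustive subset search maximizing the Spearman correlation between the
  subset's Euclidean distances and the community dissimilarities.
- **Variable pre-filtering** — of any variable pair with squared Pearson
  correlation ≥ 0.7 the later one (input order) is dropped, a deterministic
  stand-in for variable-clustering pre-filters.
- **Bonferroni** — applied across the family of tests in one driver run;
  raw and adjusted p are both reported.

Geographic distances are planar Euclidean for `x_m`/`y_m` metadata and
haversine great-circle for `lon`/`lat`.

## Synthetic data

`simulate_tree` draws a pure-birth (Yule) tree — exponential waiting times,
uniform lineage choice — and rescales the height to 1, so rates are in
units of tree height. `simulate_er_traits` inverts the trait model exactly
(root uniform, per-branch sampling from the closed-form kernel), returning
internal-node truth for oracle tests.

`simulate_landscape` emulates a three-continent soil survey. Defaults match
the field design the analyses target: 3 continents × 50 samples over a
170 km within-continent extent, intercontinental separation 8,000 km,
11,732 sequences with 80 per sample, 20 chemotypes, reference fraction
70/11,732, pigment fraction 2%. Tests and the acceptance script use
explicitly scaled-down configs (100–200 sequences, 15–30 samples) chosen
as the smallest sizes at which the statistical checks are stable.
Structure generated:

- one clade of ≈ pigment-fraction tips is the spore-pigment clade;
- chemotypes are painted on disjoint clade "patches" obtained by cutting
  the tree at a height chosen by bisection so that ≈ convergence_factor ×
  n_chemotypes patches exist, then dealt round-robin — each chemotype
  occupies ~3 distinct clades by default (trait convergence);
- each sequence has a home coordinate; its occurrence probability in a
  sample decays as e^(−λ·distance) (λ default 2×10⁻⁵ m⁻¹, i.e. a 50 km
  e-folding) and is multiplied by 0.1 off the home continent; samples draw
  a fixed number of distinct sequences, giving presence/absence tables;
- environmental variables are linear spatial gradients plus 30% noise;
  plant species get home coordinates and the same decay, so plant
  dissimilarity correlates with community dissimilarity;
- percent identity is derived from patristic distance via
  100·e^(−d/2) (a monotone surrogate); a config switch simulates explicit
  Jukes-Cantor sequences instead when an alignment is needed.

Everything is deterministic per seed, with fixed-label substreams so
components regenerate independently. What the generator does **not**
emulate: realistic KSα sequence evolution, gene copy-number variation,
alignment error, sampling-effort heterogeneity, or realistic environmental
covariance structure — so passing tests demonstrate correctness and
calibration of the algorithms under the stated generative assumptions, not
performance guarantees on field data.

## Numerical choices and degenerate inputs

- Missing newick branch lengths default to 0; negative lengths are
  rejected at I/O; internal node labels are parsed but ignored.
- Branch lengths are used as given (no rescaling before rate fitting).
- Faith's PD excludes the root-stem and the path above the MRCA
  (`pd_include_root_path`-style variants are not offered; the convention is
  fixed and documented).
- Probability rows are validated to sum to 1 within 1e−9; transition rows
  within 1e−12.
- The ER likelihood is unimodal in q on every instance encountered;
  bounded Brent with a fixed tolerance needs no restarts.
- Simulation problem sizes used by the acceptance script: 30 × 200-tip
  rate-recovery replicates (k = 4, q = 0.5); a 600-tip, 100-reference,
  400-query, 20-chemotype calibration benchmark (q = 0.05); a 120-tip PD
  test at 10,000 draws; a 180-sequence, 30-sample landscape; 300 Mantel
  null replicates at 199 permutations.

## Known limitations

- The ER model is the only trait model (no all-rates-different or
  branch-heterogeneous variants); marginal, not joint, reconstruction.
- The identity-from-distance surrogate makes binning depend on the tree
  alone unless explicit sequences are simulated or supplied.
- MRM response permutation can be anticonservative when predictors are
  strongly autocorrelated; interpret borderline p-values cautiously.
- Copy-number correction for multi-copy marker genes is deliberately out
  of scope, as is ordination (distance matrices are exported for external
  NMDS) and tree/alignment inference (both are inputs).
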