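# Methods

This note documents the models, numerical choices, and design decisions
behind `morphoconflict`, and what the synthetic-data tests do and do not
establish about real data.

## The Mk likelihood

Each character with k observed states evolves under a continuous-time
Markov chain with uniform stationary frequencies (1/k) and generator Q
normalized to one expected substitution per unit branch length at
stationarity. Unordered characters use equal exchange rates (off-diagonal
1/(k−1)); ordered characters use the tridiagonal stepwise generator in
which only neighboring states exchange, with rate k/(2(k−1)) per allowed
exchange. Both generators are symmetric, so transition matrices come from
a cached eigendecomposition, P(t) = V·diag(e^{λt})·Vᵀ, clipped at 0 to
absorb rounding.

State codes are remapped per character to 0..k−1 by rank, preserving
order; likelihood is invariant to relabeling for unordered characters, and
for ordered characters this convention treats the observed states as
adjacent steps (a character observed in states {0, 2, 4} is modeled as
three consecutive states). Polymorphic and inapplicable cells are treated
as missing everywhere in the likelihood: a polymorphism is functionally an
unknown state under ML, and the "?"/"-" distinction is notational.

**Partitioning.** Characters are grouped by (effective ordering, number of
observed states). Constant characters are excluded; declared-ordered
characters with only two observed states are demoted to the unordered
binary group, where the two models coincide. All partitions share one
branch-length set scaled by per-partition multipliers (the first fixed at
1 for identifiability, bounds [1e−3, 1e3]).

**Rate heterogeneity.** Discrete gamma with four categories,
mean-per-category discretization (category rate = the conditional mean of
the mean-1 gamma within each quartile), equal weights. The
characteristically character-poor groups — unordered 5-state and ordered
4-state — get no gamma by default (`no_gamma_groups`). With one category
the plain likelihood is recovered exactly.

**Ascertainment correction.** Morphological matrices contain only variable
characters, so each character's likelihood is conditioned on variability:
divided by 1 − Σ_s P(all taxa show state s), computed per partition on the
same tree and parameters with fully observed constant pseudo-patterns.
Per-character log-likelihoods are stored on this corrected scale, so they
sum exactly to the reported tree log-likelihood — the convention assumed
wherever site-likelihood tables feed the topology tests.

**Pruning and scaling.** Felsenstein pruning over pattern-compressed
columns, vectorized across patterns and gamma categories, with per-pattern
rescaling at every internal node to avoid underflow. Missing-like tips
contribute all-ones partials. Trees are treated as unrooted (a
bifurcating basal node is collapsed); uniform root frequencies make the
likelihood root-invariant.

## Optimization

Coordinate ascent: branch lengths, then partition multipliers, then gamma
shapes, repeated until the total log-likelihood improves by less than the
tolerance (default 1e−6, max 200 sweeps; a warning and best-so-far on
non-convergence). Each branch length is optimized by bounded Brent on a
one-dimensional likelihood function built from cached inside/outside
partials: with P(t) = V·diag(e^{λt})·Vᵀ the per-pattern likelihood is
Σ_j G_j e^{λ_j m r t} for a precomputed tensor G, so a trial length costs
one small contraction, and after an accepted update the inside partials
are refreshed only along the path to the root. Branch lengths are bounded
to [1e−8, 20], gamma shapes to [0.02, 100], and every line search only
replaces a parameter when it improves the likelihood, making sweeps
monotone.

Known limitation: partitions with very few characters (one or two) can
drive their rate multiplier or gamma shape to a bound — the parameters are
barely identifiable there. This mirrors the behavior of standard ML
phylogenetics software on tiny partitions and is why character-poor groups
get no gamma by default; treat multipliers from near-singleton partitions
as nuisance values.

## Tree search and bootstrap

Starting trees: stepwise addition in random taxon order, placing each
taxon on the edge minimizing Fitch parsimony length (state-set bitmasks;
ties broken at random), or neighbor joining on pairwise mismatch
proportions. The search then alternates full numeric optimization with
NNI rounds: every neighbor is screened at current parameter values, the
best improving move is applied and re-optimized, and the climb stops when
no neighbor improves; accepted moves strictly increase the likelihood.
Constraints (monophyly in the unrooted sense) are enforced during stepwise
addition and by rejecting violating NNI moves. Exact likelihood ties
between runs are broken by the lexicographically smallest canonical
newick, for determinism.

Clade support is a standard nonparametric bootstrap: characters resampled
with replacement within partitions (preserving the partition scheme, since
group sizes are very unequal — implemented as multinomial reweighting of
pattern weights), each replicate re-searched from the ML tree under a
small NNI budget. This is a deliberately simple support heuristic, not a
reimplementation of the ultrafast bootstrap approximation; supports are
comparable in spirit (percent of replicates containing a split) but not
numerically interchangeable with UFBoot values.

## Topology tests

All tests run on RELL replicates: B resamples of characters (stratified by
partition) summing stored per-character log-likelihoods, no
re-optimization. Centered replicate totals provide the null.

* **bp**: fraction of replicates in which a tree is best, exact ties split
  evenly.
* **KH**: one-sided test of each tree against the best of the *other*
  trees. The one-sided convention is what makes the SH ≥ KH dominance
  hold and matches the reporting style of standard ML software (the best
  tree gets a p-value below 1). Degenerate case: identical columns give
  p = 1.
* **SH**: max-statistic over all candidates (the tree itself included, so
  the best tree's p is exactly 1).
* **wSH**: per-pair standardized variant; pairs with zero resampling
  variance are inert unless the tree is genuinely worse on the total
  likelihood, in which case it is rejected outright.
* **ELW**: replicate-wise likelihood weights averaged over replicates;
  the confidence set accumulates trees by decreasing weight until 1 − α.
* **AU**: multiscale RELL at scale factors 0.5–1.4 (B/10 replicates per
  scale); Φ⁻¹(1 − bp) regressed on (√r, 1/√r) by weighted least squares;
  p = 1 − Φ(d − c). Saturated cases (bp ≈ 0 or 1 at every scale) short-
  circuit to 0 or 1; with fewer than two usable scales the scale-1 bp is
  returned.

A tree is *plausible* iff no test rejects it at α = 0.05 and it lies in
the ELW confidence set; the maximum-likelihood tree is always plausible by
contract. Calibration: under an exact null built from an
exchangeable-clades polytomy (so the two candidate resolutions have
identical expected likelihood by symmetry), the KH test rejects at 5.0%
(1000 simulated tables of 150 characters) — the test-suite gate allows
3–7%.

## Difficulty score

From N searched trees and their plausibility flags:
(d̄_all + d̄_pl + n′_all/n_all + n′_pl/n_pl + (1 − n_pl/n_all)) / 5, each
term in [0, 1]. Unique topologies are counted under RF = 0 equivalence
(branch lengths and supports ignored); average distances are means over
unordered pairs, defined as 0 for a singleton plausible set. RF is the
bipartition symmetric difference normalized by its binary-tree maximum
2(n−3).

## Signal decomposition

PS_i is the mean of the three absolute pairwise per-character
log-likelihood differences; ΔCLS(A,B)_i the signed difference. Favored
hypothesis = argmax, except that log-likelihoods within 1e−9 are reported
as ties and excluded from counts — PS-type statistics are overly sensitive
to small branch-length differences among the three optimized trees, and
near-ties must not be silently assigned. Outliers are one-sided (value >
mean + 3 sample standard deviations), computed over non-constant
characters; a character enters the conflict report when its PS *and* at
least two of its three |ΔCLS| values are outliers. "Strong" characters
have a best-vs-second gap above 0.5. The multinomial uniformity test is
exact (full enumeration of three-part compositions) up to n = 600 and
Monte Carlo (10⁶ draws) beyond.

## Perturbation experiments

Removal experiments drop the top-n PS characters (ties to the lower
index) or the PS-outlier set and re-search. The rescoring scan iterates
over characters whose column differs between two matrices under the
likelihood view of the data (polymorphic ≡ missing) and whose swap does
not create a constant column; each analysis swaps one column (shared taxa
only — extra taxa keep their own codings), re-searches, optionally
bootstraps, and classifies the focal-branch resolution by reference-taxon
ancestry. Per-character seeds derive from the master seed by hashing the
stage name and index, so results are independent of execution order.

Hypothesis classification roots the tree at the first listed outgroup
taxon and finds, for each reference pair, the smallest rooted clade
containing both; the detected resolution is the pair whose ancestor
excludes the third reference. For a binary tree this is always unique
(verified exhaustively on all 15 five-leaf topologies against an
independent reroot-and-MRCA implementation).

## Synthetic data

The generator emulates the structure of large early-dinosaur matrices:
default 80 taxa × 457 characters, state-count weights (0.82, 0.12, 0.04,
0.02) for k = 2..5 (matching a 375:76 binary:multistate split), 8%
declared-ordered characters, 57% missing data, and a ~0.3% polymorphic
cell fraction. Each character draws a generating topology from the
conflict weights (three trees identical except the focal-branch
resolution), a state count, an ordering flag, and a continuous gamma rate,
then evolves by the Mk process and is conditioned on variability by
rejection — the whole character, rate included, is redrawn, since a
near-zero rate can never produce a variable column. Missingness is
per-taxon: completeness drawn from a Beta with the target mean and a
spread parameter, because uniformly random missingness is unrealistically
benign for search difficulty compared to fossil taxa of very uneven
completeness. Scaffold trees place an outgroup pair plus three clades of
roughly equal size around the focal branch; branch lengths are
gamma-distributed with mean 0.1 by default.

What passing synthetic tests show: the likelihood machinery is exact (it
matches enumeration), the tests are calibrated, and the protocol recovers
known signal mixtures at realistic sizes. What they do not show: real
morphological characters are not independent draws from an Mk mixture —
correlated and hierarchically nested characters, coding subjectivity, and
non-random missingness are outside the generator, so conclusions about a
real matrix still require the perturbation experiments, not just the
global tests.

## Problem sizes

Desk-scale defaults keep a full protocol run tractable on one CPU: 20
exploratory searches, 200 bootstrap replicates, B = 2000 RELL replicates
(`paper_scale=True` restores 100/1000/10000). The acceptance script uses
14-taxon matrices of 150–300 characters with 10 exploratory searches; the
test suite's recovery oracles use 12–16 taxa and 400–500 characters.
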