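# Methods

## The problem

Metabolomics and proteomics case–control studies often have few cases and
many controls. Filter-based feature screening — scoring every feature with
a univariate or neighborhood statistic and keeping the top of the ranking —
is the standard first step, but different filters embody different notions
of relevance and therefore produce different rankings, and the disagreement
grows as the class distribution becomes more imbalanced. `rarank`
implements a two-stage answer: **re-balance** the classes in sample space,
then **aggregate** the rankings of eight filters into a single consensus
list in feature space (RAR: rank aggregation with re-balance; RA is the
same without re-balancing).

## Filters

Let the positive class C1 be the minority (n1 ≤ n2), and write x̄kj, s²kj
for the sample mean and variance of feature j in class k.

| method | statistic | direction |
|---|---|---|
| t test | Welch two-sample \|t\| | larger better |
| Fisher | \|x̄1j − x̄2j\| / √(s²1j + s²2j) | larger better |
| Hellinger | D²H between N(x̄1j, s²1j) and N(x̄2j, s²2j), in [0, 2] | larger better |
| Relief | Σᵢ −(xᵢⱼ − nearhitᵢⱼ)² + (xᵢⱼ − nearmissᵢⱼ)² | larger better |
| ReliefF | as Relief, averaged over the k nearest hits/misses | larger better |
| information gain | max over binary thresholds of Ent(D) − Σ wᵥ Ent(Dᵥ), bits | larger better |
| Gini | min over binary thresholds of Σ wᵥ Gini(Dᵥ) | smaller better |
| R-value | fraction of samples whose k-NN (on that feature alone) has > θ opposite-class members | smaller better |

Design choices where the method definitions leave room:

* **t statistic**: Welch (unequal variances). The ranking uses |t|, which
  orders features identically to the p-value when degrees of freedom vary
  smoothly; robust default for unequal class sizes.
* **Fisher and t sign**: absolute values — importance is the magnitude of
  the shift, not its direction.
* **Relief scaling**: features are min-max scaled to [0, 1] before the
  Euclidean neighbor search (standard Relief practice; otherwise large-
  scale features dominate the metric). Scores are reported on the scaled
  data. The update visits every sample once in index order, so Relief is
  fully deterministic; a random subsample (and then a seed) is used only if
  `n_iter < n` is requested.
* **ReliefF k**: default 10, clipped to `min(n1, n2) − 1` (Kononenko's
  convention). `k = 1` reduces exactly to Relief.
* **Discretization for IG/Gini**: supervised best binary split over the
  midpoints of consecutive sorted unique values — the decision-tree
  convention. Logarithms are base 2, so IG is in bits and bounded by
  Ent(D) (1 bit at class balance).
* **R-value**: k = 5, θ = k/2 = 2.5 with a strict inequality, the sample
  itself excluded from its neighborhood, distances computed per feature
  (1-D). The score is a fraction in [0, 1].
* **Ties**: every ranking breaks score ties by ascending feature index, so
  all eight lists are strict permutations and the whole pipeline is
  deterministic given seeds.

Degenerate inputs: a feature constant in both classes scores 0 for t,
Fisher, Relief and IG, and the parent Gini for the Gini filter; the
Hellinger score is undefined there and raises an error naming the feature.
Zero pooled variance with unequal means yields +inf for t/Fisher, which
sorts to the top.

## Rank aggregation

The consensus δ* minimizes Σᵢ wᵢ·d(δ, fᵢ) over permutations δ, with
uniform weights wᵢ = 1/m (the filters are treated as equally trustworthy)
and d the **unweighted Spearman footrule** Σ_t |rank_δ(t) − rank_f(t)|. A
score-weighted footrule (each term multiplied by the gap between
rank-position scores) is available behind a flag for callers who can
supply a meaningful score scale; eight filters with incommensurable score
scales cannot, which is why the unweighted form is the default.

The optimizer of record is a **cross-entropy (CE) Monte Carlo** search: a
p×p item-by-position matrix starts uniform at 1/p; each iteration samples
N permutations position-by-position (renormalizing over unplaced items),
keeps the elite ρ fraction by objective, re-estimates the matrix from
elite frequencies, and smooths exponentially. Defaults: N = 10·p²
(min 10), ρ = 0.1, smoothing 0.7, at most 100 iterations, stop after 5
iterations without improvement. The best-ever permutation is returned, so
the trace is non-increasing by construction; among equally optimal
permutations the lexicographically smaller is preferred.

Because the unweighted footrule objective separates into per-(item,
position) costs, the exact optimum is also computable in polynomial time
as a linear assignment (`aggregate_exact`), and by p! enumeration for
p ≤ 8 (`aggregate_brute_force`). Both serve as independent checks on the
CE search; in the test suite the CE optimizer matches the enumerated
optimum in ≥ 19/20 random p = 5 problems with default settings.

Concordance between rankings is Kendall's τ (pair concordance count over
p(p−1)/2 pairs; rankings are strict so no tie correction is involved).

## Re-balancing

Three generators: random duplication/removal, SMOTE (synthetic point
x' = xᵢ + u·(xᵢₕ − xᵢ) with one scalar u ~ U(0,1) per point and xᵢₕ one of
the k = 5 nearest minority neighbors), and the smoothed bootstrap (draw a
source row uniformly within its class, add diagonal Gaussian kernel noise
with per-feature Silverman bandwidth 0.9·min(sd, IQR/1.34)·nk^(−1/5),
computed per class; when a class has no spread the bandwidth falls back to
1% of the overall per-feature range). Seven cases compose these:

| case | rule | sizes after |
|---|---|---|
| 1 | none | (n1, n2) |
| 2 | SMOTE minority ∪ random-cut majority | (2n1, 2n1)* |
| 3 | full smoothed-bootstrap re-draw | (⌊n/2⌋, ⌈n/2⌉) |
| 4 | random minority duplication | (n2, n2) |
| 5 | smoothed-bootstrap minority top-up | (n2, n2) |
| 6 | random majority removal | (n1, n1) |
| 7 | majority replaced by smoothed-bootstrap draws | (n1, n1) |

*Case 2 clamps the common target to n2 when n2 < 2n1, the only reachable
balanced size by under-sampling there. Case 3's "approximately equal"
sizes are realized as floor/ceil of n/2 with the majority taking the
ceiling. Case 7 is read as an under-sampling variant: the majority class
is replaced by n1 kernel-bootstrap draws from itself.

Every output carries per-row provenance (original vs synthetic); original
rows are bit-identical to their inputs and all operations are reproducible
from their seeds.

## Evaluation

Gmean = √(TPR·TNR) and F1 from counts after thresholding random-forest
probabilities at 0.5 (majority vote); AUCROC via the Mann–Whitney
identity; AUCPRC as **average precision** (the trapezoidal PR integral is
optimistic between sampled recalls and is offered only as an option). The
top-k search fits a 500-tree random forest on the top-k consensus features
for every k, scores held-out folds of a stratified 5-fold split by
AUCPRC, and returns the smallest k attaining the maximal mean (parsimony
tie-break) together with the whole curve.

Two evaluation modes exist in the pipeline: the default re-applies the
re-balance case inside each training fold, so synthetic points never leak
into held-out data; the `resample_in_folds=False` switch evaluates
directly on the re-balanced table, which reproduces the workflow behind
the packaged benchmark tables (and, like those tables, reports optimistic
absolute numbers — the metric is then computed partly on synthetic rows).

The table-summary utility counts, per benchmark metric table, the rows in
which a focal column reaches the row maximum of a comparison set; ties
count as reaching it, and rows with missing cells are skipped with a
warning.

## Simulation

`generate_two_class_gaussian` draws the majority from Np(0, Σ) and the
minority from Np(shift, Σ); Σ defaults to the identity, n to 960, and the
ratio ladder to 1, 3, 9, 31, 95 (all divide 960 exactly; the class split
must be exact or the configuration is rejected). Case one uses p = 8 with
shifts 2.4, 2.2, …, 1.0; case two appends eight zero-shift features. Each
(ratio, repeat) cell runs on an independently spawned RNG stream.

What the generator does *not* emulate about real metabolomics data:
correlated features, heavy tails and heteroscedastic technical noise,
batch effects, and missingness. Passing the concordance and recovery
tests therefore shows the machinery behaves as designed under the stated
Gaussian conditions, not that any particular real dataset will reach the
same numbers.

Measured under those conditions (100 repeats, balanced 1:1): the mean
pairwise τ among the eight filter rankings is ≈ 0.89 for case one and
≈ 0.80 for case two, and falls sharply by 95:1 — the motivating
degradation. The moment-based filters (t, Fisher, Hellinger, IG, Gini)
order even null features near-identically (pairwise τ ≈ 0.99–1.00), which
places a fairly high floor under the case-two mean.

## Problem sizes used in the shipped checks

The acceptance script runs the concordance study at full size (n = 960,
100 repeats per case). The test suite scales the stochastic end-to-end
checks down to keep them quick: 25-repeat concordance runs, 50 repeats of
the case-two recovery property, and 5 repeats × 100 trees for the
re-balancing-improves-AUCPRC comparison at 31:1. These sizes are the
package's own choice of desk-scale defaults; all are parameters.

## Known limitations

* Binary classification only; the multi-class extensions of ReliefF/IG
  are out of scope.
* The CE search is a stochastic optimizer: for large p it can return a
  near-optimal rather than optimal permutation (the exact assignment
  solver is the cheap alternative whenever the unweighted footrule is the
  objective).
* Filter scores are univariate (except the Relief family): interacting
  features that are individually uninformative will be missed.
* The smoothed bootstrap assumes a locally Gaussian neighborhood; on
  strongly skewed features its synthetic points can leave the support of
  the data.
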