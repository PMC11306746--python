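# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `quboselect`. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from elsewhere.

## Problem setting

The input is a respondents × items table: p categorical features with a
small number of ordered levels (Likert items, integer-coded 0…L−1) and
one continuous dependent variable y, typically a summed questionnaire
score. The task is to rank the items by how useful they are for
modelling y, trading off *relevance* (information an item carries about
y) against *redundancy* (information items share with each other).

## Information estimators

All quantities are plug-in (maximum-likelihood) estimates in nats from
contingency tables:

* entropy H(X) = −Σ p̂ log p̂ with p̂ = count/n over observed levels;
* mutual information I(X;Y) = H(X) − H(X|Y), computed from the joint
  count table; symmetric; tiny negatives (< 1e−12, floating-point
  cancellation only) are clamped to zero;
* conditional mutual information I(X;Y|Z) = Σ_z p̂(z)·I(X;Y|Z=z) by
  stratification, which for plug-in estimates equals H(X|Z) − H(X|Y,Z);
  empty strata carry zero weight.

No small-sample bias correction (Miller–Madow, shrinkage) is applied:
the raw plug-in estimator keeps every number exactly reproducible from
counts and makes the test oracle a direct cell-by-cell sum. The bias of
plug-in MI between independent variables is ≈ (cells−1)/(2n) nats; at
the default scale (5×10 cells, n = 751) that is ≈ 0.03 nats, which is
why ranking margins, not absolute MI values, are what matters here.
Bias-corrected estimators are an explicit extension point.

The continuous y is discretized before estimation with equal-frequency
(quantile) binning, default 10 bins: robust to skewed score
distributions, and every bin is populated when n ≥ n_bins. Tied values
are assigned as a block to the lowest bin any of them would occupy, so
equal inputs always get equal codes; without ties bin populations
differ by at most one. A constant sample collapses to one bin and emits
a warning. The bin count is exposed in every API that builds a model;
halving or doubling it moves plug-in MI values but not, in our tests,
the resulting rankings.

## The selection QUBO

Selection is a bit vector x ∈ {0,1}^p scored by
f(x) = Σᵢ Qᵢᵢxᵢ + Σ_{i<j} Qᵢⱼxᵢxⱼ = xᵀQx, minimized over x. Three
constructions of Q are shipped because the conditional-information
variant admits more than one reading — in particular, a per-feature
diagonal built from a three-argument quantity I(X;Y|Z) requires a
choice of conditioning variable that is not canonical:

* `literal` (default): Qᵢᵢ = −I(Xᵢ;Y), Qᵢⱼ = +I(Xᵢ;Xⱼ). Relevance is
  rewarded (negated, since we minimize), pairwise redundancy penalized;
  the classic mRMR trade-off in QUBO form. With this construction the
  diagonal is ≤ 0 and the off-diagonal ≥ 0 entrywise.
* `miqubo`: Qᵢᵢ = −I(Xᵢ;Y), Qᵢⱼ = −[I(Xᵢ;Y|Xⱼ) + I(Xⱼ;Y|Xᵢ)]/2. The
  mutual-information QUBO known from annealer applications: pairs are
  rewarded for carrying *complementary* information about y. Exact
  duplicates get a zero off-diagonal (no reward, no penalty).
* `conditional_diag`: Qᵢᵢ = −mean_{j≠i} I(Xᵢ;Y|Xⱼ), literal
  off-diagonal: per-feature relevance measured conditionally on each
  other item in turn.

The construction mode is recorded in the matrix metadata and threads
through all artifacts.

### Cardinality constraint

A target subset size k is imposed with the standard quadratic penalty
f′(x) = f(x) + λ(Σxᵢ − k)². On binary variables this adds λ(1−2k) to
each diagonal entry and 2λ to each upper off-diagonal entry; the
constant λk² is kept in metadata so reported energies are comparable
across k. The automatic weight λ_auto = 2·p·max|Q| + ε upper-bounds
the objective gain of any single-bit constraint violation, so every
exact minimizer of the penalized problem is feasible — verified by
enumeration in the tests. ε = 1e−6 keeps the penalty active even for a
zero Q.

### Ising form

Annealing hardware is specified over spins s ∈ {−1,+1}; the affine map
x = (1+s)/2 converts the QUBO to biases h = diag/2 + (row sums of the
symmetrized couplings)/4, couplings J = Q_upper/4, plus an additive
offset. The conversion is exact (round-trip to 1e−12) and preserves the
full state-energy ordering, so argmin maps to argmin.

## Solvers

`solve_exact` enumerates all 2^p states (guarded at p ≤ 22, chunked so
memory stays bounded) and breaks ties toward the lexicographically
smallest bit vector, leading bit compared first — which means that
between two tied single-feature solutions the *later* index wins,
because (0,1) precedes (1,0). This is the oracle for everything else.

`solve_sa` is seeded simulated annealing: Metropolis sampling over a
geometric inverse-temperature ladder β_start → β_end across n_sweeps
sweeps (one sweep = p proposals), n_reads independent restarts, each
read on its own substream derived from (seed, read index) so results
are identical whatever n_reads is — making best-over-reads monotone in
the read prefix. Each read returns its best-seen state, re-evaluated
against Q before returning.

Two numerical choices matter and were made after the first version of
the sampler demonstrably failed on penalized selection problems:

* **Move set.** Proposals mix single-bit flips with symmetric pair
  exchanges (50/50). Under a cardinality penalty with λ_auto the
  barrier between adjacent same-weight subsets is ~λ, which at desk
  scale is three orders of magnitude larger than the information-scale
  energy differences (~0.03 nats) the sampler must resolve; a
  flips-only chain freezes into an essentially random feasible subset.
  Pair exchanges move directly between equal-weight subsets without
  touching the penalty term, restoring mixing. The exchange proposal
  (uniform ordered pair, no-op when the bits agree) is symmetric, so
  plain Metropolis acceptance applies. ΔE is computed incrementally
  from a cached field vector (O(p) per accepted move).
* **Temperature range.** Defaults β: 0.1 → 100. The cold end must
  freeze differences at the scale of the objective being solved; for
  information-built QUBOs gaps of 0.01–0.1 nats require β of order
  100, whereas O(1) random instances freeze fine by β ≈ 10. At the
  default schedule the sampler matches the enumerated optimum on 100
  of 100 seeded runs across 20 random p = 12 instances.

An external BQM sampler (e.g. a hardware annealer client) can be
substituted anywhere a solve callable is accepted; none is required.

## Cardinality sweep and ranking

One Q is built per dataset (information estimates do not depend on k);
for each k in 1…p the penalty is re-applied and the penalized problem
solved — exactly for p ≤ 22, otherwise by annealing, counting only the
best read. A solution violating its cardinality triggers one retry at
10·λ and is logged; a second violation aborts the sweep naming k. When
all constraints hold, Σ counts = Σ k, asserted on every sweep.

A feature's importance is its appearance count across the sweep; ties
resolve by diagonal relevance (−Qᵢᵢ) descending, then feature index
ascending. Per-k solutions need *not* be nested, and nothing assumes
they are. The per-k SA seed is derived from (schedule seed, k), so the
whole sweep is reproducible from one integer.

## Baseline and validation harness

The regression baseline fits one joint OLS of y on all features,
standardized to zero mean and unit variance, and ranks by
|standardized coefficient| (sign-blind — the only defensible reading
of a coefficient magnitude as an importance score), index ascending on
ties. Constant columns are dropped with a warning and ranked last;
when n ≤ p the fit falls back to a lightly regularized ridge, also
with a warning.

Validation evaluates cumulative top-k feature sets (default 10, 20,
30, 40, 50, capped at p) with gradient-boosted trees under two tasks:

* classification — y median-split into binary classes (balanced by
  construction, no clinical threshold being available), stratified
  k-fold CV, metric = balanced accuracy (sensitivity+specificity)/2;
* regression — plain k-fold CV, metric = negative mean absolute error
  (larger is better, matching the classification direction); negative
  mean squared error is available behind a flag.

Defaults: 10 folds, 30 repeats, library-default booster
hyperparameters with a fixed per-repeat seed derived from
(config seed, repeat). A `model="dummy"` switch substitutes
median/prior constant predictors as the chance-level reference.
Methods are compared per (task, condition) with Welch's two-sample
t-test (unequal variances between selection methods are likely;
pooled-variance has no advantage here), two-sided p, flagged at 0.05;
a zero-variance-in-both degenerate pair reports t = 0, p = 1 with a
flag rather than NaN.

## Synthetic data generator

Real survey datasets of this kind are generally not shareable, so the
generator plants known structure at the study's scale. Defaults:
n = 751 respondents, 40 items with 5 levels — 5 relevant, 5 redundant,
30 noise.

* Relevant items are i.i.d. uniform over levels; the target is
  y = effect_size · Σⱼ z(Xⱼ) + N(0, noise_sd²) over relevant items,
  with z the centered equally spaced level scores −(L−1)/2 … +(L−1)/2
  (the simplest monotone coding of an ordinal item). Defaults
  effect_size = 1, noise_sd = 0.5 give each relevant item a marginal
  R² ≈ 0.2 — a strong but not degenerate questionnaire item.
* Redundant item j copies relevant item (j mod n_relevant) entry-wise
  with probability ρ and resamples uniformly otherwise; ρ = 1 gives
  exact duplicates, ρ = 0 independence, and MI(copy, parent) is
  monotone in ρ. Default ρ = 0.5, a typical inter-item correlation for
  survey scales measuring one construct. The choice is load-bearing
  for ground-truth recovery: as ρ → 1 a copy becomes statistically
  indistinguishable from its parent, and at ρ ≈ 0.8 a strong copy can
  legitimately out-inform the weakest parent (plug-in MI ~0.09 vs
  ~0.105 nats), at which point the objective — correctly, by its own
  lights — prefers the copy at large k and no selection method could
  be expected to rank all parents above all copies. Recovery claims
  are therefore statements about moderately redundant instruments,
  not near-duplicate ones.
* Noise items are i.i.d. uniform and independent of y.

Everything is reproducible from one seed. What the generator does
*not* emulate: real item wording or category structure, ordinal
response curves (graded-response-style models), correlated noise
items, respondent-level effects, and missingness-generating
mechanisms (missing values are planted explicitly where tests need
them). Passing tests therefore demonstrate correct mechanics and
recovery under a known planted model — not performance guarantees on
any particular real instrument.

## Preprocessing

Mirroring common survey practice: columns containing any missing value
are dropped whole (rows never are), surviving cells are untouched;
groups of item columns can be summed into single score columns (the
sum replaces the first source column in place); and an explicit
drop-list removes items the analyst judges duplicated — duplicate
detection is deliberately never automatic, because that judgement is
about item semantics, not statistics.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at sizes chosen to make every
claim checkable against enumeration or a brute-force oracle: exact
solver paths at p ≤ 16, annealer-vs-enumeration at p = 12, full
sweeps and validation at the default 751 × 40 over 20 seeds, and the
preprocessing contract at the original survey scale (751 × 560 → 270
columns). The boosted-tree comparisons use 2 repeats of 10-fold CV
per dataset, which is ample for the 20-seed paired comparisons they
feed; the 30-repeat default applies to single-dataset analyses.

## Known limitations

* Plug-in MI bias grows with level count and bin count; items with
  many levels are slightly favoured. Rankings at the default scale are
  insensitive to this, but comparing items of very different
  cardinality warrants a bias-corrected estimator.
* The appearance count conflates "selected early" with "survives
  late"; a feature's count mixes relevance-rank information across all
  k. It is the method's defining statistic, reported as such.
* Simulated annealing is a classical stand-in: energies, schedules and
  run times are not comparable to any hardware annealer, and no
  minor-embedding or chain-strength logic exists here.
* Welch t-tests across CV repeats inherit the usual optimism of
  repeated-CV comparisons (repeats are not independent samples);
  p-values order methods but should not be read as calibrated error
  rates.
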