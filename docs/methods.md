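# Methods

## Problem setting

Two-class tabular classification with many weakly or non-informative
features, the canonical case being motor-imagery EEG: trials × channels
feature tables in which a small subset of electrode channels carries the
class-discriminative signal. The package's job is to find that subset with
a wrapper search, quantify the resulting classifier, and explain single
predictions.

## The optimizer

The continuous whale optimization algorithm maintains `n_agents` position
vectors in the box [lb, ub]^d. Per agent and iteration it draws a
per-dimension uniform vector r (giving coefficient vectors A = 2a·r − a and
C = 2r), a spiral parameter l ~ U[−1, 1] and a branch draw p ~ U[0, 1],
then applies exactly one of

* spiral (p ≥ 0.5): X ← |X* − X| · e^{bl} cos(2πl) + X*,
* encircling (p < 0.5, |A| < 1): X ← X* − A ∘ |C ∘ X* − X|,
* exploration (p < 0.5, |A| ≥ 1): X ← X_rand − A ∘ |C ∘ X_rand − X|,

with X* the elitist leader (never worsens) and X_rand a uniformly chosen
*other* agent (in a singleton population the agent itself). a decays
linearly from 2 to 0 across the `max_iter` budget, shifting the search from
exploration to exploitation.

**Branch statistic.** A is a vector here (r is drawn per dimension, which
matches the vector arithmetic of the update rules), but the
encircle/explore decision is a per-agent scalar test. We branch on the
magnitude of A's first component: its distribution is exactly the
U[−a, a] of the scalar formulation, so the classic explore/exploit balance
is preserved at every dimensionality. Any norm-based statistic would
concentrate around a·√(d/3) and lock high-dimensional searches into pure
exploration for most of the schedule.

**Numerical choices.** Positions are clipped to [lb, ub] after every
update. Default bounds are ±4 so the sigmoid transfer spans roughly
(0.018, 0.982); wider boxes saturate the transfer and freeze masks. One
`numpy` PCG64 generator seeded by `seed` drives every draw, so runs are
bit-reproducible. Iteration t evaluates the current population, updates
the leader, records the best-so-far cost, then moves with a = 2(1 − t/T);
the convergence curve therefore has exactly `max_iter` entries and is
monotone non-increasing by construction.

## Binary wrapper selection

Each position component x_j maps to a selection probability
s(x_j) = 1/(1 + e^{−x_j}) and is thresholded against a fresh per-dimension
uniform draw; the boundary (equality) counts as selected. An all-zero mask
is repaired by setting one uniformly random bit, since the cost is
undefined for empty subsets and a classifier needs at least one feature.

The cost of a mask is ρ·Err + (1 − ρ)·|F|/|T| with ρ = `weight_error`
(default 0.99). Err is the error rate of the wrapper classifier trained on
the selected columns of a stratified 80/20 split drawn once per run
(k-fold cross-validation is available via `SplitSpec(n_folds=...)`).
Because the split is fixed within a run, mask evaluations are cached
exactly by mask; the `evaluations` counter reports cache misses only. The
weight convention makes classification error dominate and the ratio term a
small tie-breaker toward compact subsets; setting `weight_error = 0.01`
reproduces the opposite (ratio-dominant) weighting for sensitivity
analyses.

## Classifiers and evaluation

The native classifier is Euclidean majority-vote k-NN with k = 5. Vote
ties (impossible for odd k with two classes) are broken toward the tied
class with the smaller summed neighbour distance, then the lowest label —
deterministic and distance-respecting. Its ranking score, used for AUC, is
the fraction of positive votes among the k neighbours. The registry also
exposes scikit-learn LDA (svd solver), decision tree (gini), random forest
(100 estimators, gini) and L2 logistic regression; these are configuration
entries, not re-implementations, and tree randomness is seeded from the
run seed.

Class 1 (the smaller original label) is the positive class for confusion
counts. Accuracy, sensitivity tp/(tp+fn) and specificity tn/(tn+fp) are
reported; a zero denominator raises `MetricUndefinedWarning` and yields
NaN rather than a silent zero.

The experiment protocol derives one seed per run from a master seed
(`numpy.random.SeedSequence`), runs selection + evaluation per seed, and
aggregates mean ± SD (sample SD for n > 1, 0 for a single run). The same
run seed is reused across classifier arms, so comparisons are paired. The
reported metrics are computed on the same held-out partition the wrapper
optimized, mirroring the usual wrapper-selection reporting; they are
optimistic relative to a fully untouched test set.

## Local explanations

`lime_explain` follows the canonical tabular local-surrogate recipe:
Gaussian perturbations around the instance scaled by training-set
per-feature SDs, black-box scores for each perturbation, proximity weights
exp(−d²/w²) on standardized Euclidean distance with default
w = 0.75·√d, selection of the `top_k` (default 10) features by absolute
weighted correlation, then a weighted ridge fit (α = 1) on standardized
features. The signed ridge coefficients are the contributions; a feature
that is constant in training (SD numerically zero) is never perturbed and
contributes exactly 0; a constant black-box score is flagged as degenerate
and yields all-zero weights. Quartile range conditions
("q1 < f3 ≤ q2") are reporting sugar only — the surrogate is fit on
continuous values. The number of perturbations (default 1000), kernel and
regularization are conventions of this explanation family, not estimates
of anything.

## Synthetic study conditions

The generator draws class labels Bernoulli(`class_balance`) and features as
class-conditional Gaussians with unit within-class SD; informative columns
separate the class means by `effect_size` SDs, and redundant columns are
noisy copies (copy = source + N(0, noise_sd²)). The standard fixture is
300 samples × 40 features, 5 informative at effect size 2.0 — a mid-sized
effect typical of a usable motor-imagery feature — and 3 copies at
noise_sd = 0.5, i.e. source–copy correlation ≈ 0.89, comparable to
neighbouring-electrode correlations. The toy-epoch generator adds a
random-phase sinusoid on discriminative channels of class-1 epochs sized
so total power is `power_ratio`× baseline, and reduces epochs to
per-channel log-variance — a minimal stand-in for a band-power feature
extractor, not a model of real EEG spectra, artifacts or montages.

What passing tests on these tables show: the optimizer minimizes the
stated cost (it matches exhaustive subset enumeration on small problems),
selection concentrates on discriminative columns, and the pipeline is
reproducible. What they do not show: performance on real EEG, whose
features are non-Gaussian, temporally dependent and heavily correlated
across many channels at once.

## Known limitations

* **Error quantization vs. full recovery.** With a fixed 20% holdout the
  wrapper error moves in steps of 1/n_test (1/60 on the standard fixture).
  Several small subsets — often substituting a redundant copy for its
  source — reach zero measured error, and the ratio term then prefers
  them over the complete informative set. The optimizer is correctly
  minimizing the stated cost when it drops an informative feature whose
  removal costs no measured error; run-to-run selection frequency, not any
  single mask, is the right readout of which features matter. Larger test
  partitions or k-fold evaluation soften but do not remove this.
* Reported metrics share the wrapper's split (see above); treat them as
  model-selection scores, not unbiased generalization estimates.
* Only binary classification; only box constraints; no transfer-function
  or WOA variants beyond the s-shaped/standard forms.

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run at desk scale: 30 agents ×
60–80 iterations on 120–300-sample tables, 20 repeated runs, exhaustive
enumeration limited to 8-feature tables (255 subsets), and the sphere
benchmark at 30 agents × 200 iterations × 10 dimensions. These sizes make
every check recomputable in about a minute each while leaving the
qualitative behaviour unchanged.
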