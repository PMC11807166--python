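# Methods

## Problem and scope

`gafs` performs feature-subset selection on labeled real-valued feature
matrices. The intended input is the output of a deep feature extractor (a
channel-attention-equipped CNN's pre-final dense layer applied to
histopathology images is the motivating case), but the library is agnostic:
anything with rows = samples, columns = continuous features, one class label
per row. The extractor itself (network, training, image preprocessing) is
out of scope; the package does include the channel-attention recalibration
math as a standalone operator so its algebra is testable without any
pretrained network.

## Filter scoring (mRMR)

Relevance of a feature is the one-way ANOVA F-statistic against the class
label: between-class mean square over within-class mean square. Redundancy
is the absolute Pearson correlation between features. Features are ranked
greedily: the first pick maximizes relevance; at iteration i > 1 every
remaining feature's score is its relevance divided by its mean |correlation|
with the already-selected set, and the maximizer is appended. Every feature
ends up with the score it had at the iteration it was selected.

Numerical conventions (all degenerate cases are deliberate definitions, not
fallbacks):

- Constant columns have F = 0 and correlation 0 — no relevance, no
  redundancy signal.
- Zero within-class variance with a real class effect would make F infinite;
  it is capped at `F_CAP = 1e12` so perfectly separating features rank first
  and sorting stays finite.
- A candidate numerically uncorrelated with everything selected has an
  undefined quotient; the denominator is floored at `1e-12` (configurable)
  so "high relevance, zero redundancy" wins rather than crashes.
- Greedy argmax ties break toward the lowest feature index; runs are
  deterministic.
- Scores are computed on the training rows only. Evaluation rows never enter
  feature scoring, so no label information leaks from val/test.

One consequence of the quotient form worth knowing: because mean
|correlation| ≤ 1, a feature's recorded score is never *below* its raw
relevance penalty-wise — an exact duplicate of an already-selected feature
scores exactly its relevance (denominator 1), while near-orthogonal features
get boosted above theirs. The redundancy penalty is therefore relative:
duplicates are denied the boost, not pushed below relevance.

The scorer is registered in a small registry (`register_filter`) so
alternative filter statistics can be plugged into the same fitness
machinery; mRMR is the one shipped.

## The genetic algorithm

Chromosomes are binary inclusion vectors of length d. Defaults follow the
published configuration: population 20, 60 iterations, crossover probability
0.8, mutation probability 0.01 → 0.04, α = 0.99, KNN k = 5. (The published
iteration experiments peak at 50 iterations; 60 is the canonical
configuration-table value and the shipped default, 50 is a documented
alternative.)

- **Initialization:** each chromosome draws an inclusion density uniformly
  from [0.2, 0.8] and then genes Bernoulli(density) — subset sizes start
  widely spread.
- **Fitness:** `α·acc + (1−α)·(d − Σ agent)/d`. In filter mode `acc` is the
  chromosome's mean mRMR score divided by the maximum single-feature score
  (capped at 1), which keeps fitness in [0, 1] and removes classifiers from
  the loop entirely. In wrapper mode `acc` is the validation accuracy of a
  KNN fitted on the training rows restricted to the selected columns. Both
  modes ship because the method's description supports both readings;
  neither touches test rows.
- **Selection:** roulette wheel, probability proportional to fitness. If any
  fitness is ≤ 0 the vector is shifted so the minimum sits just above zero;
  already-positive fitnesses are used raw, so probabilities are exactly
  fᵢ/Σf.
- **Crossover:** per-gene probabilistic swap — at each position, with
  probability 0.8 the two parents exchange values in the children. This is
  the operationally specified operator; a classical k-point variant sits
  behind `crossover_op: k_point`.
- **Mutation:** independent bit flips with probability interpolated linearly
  over generations from 0.01 to 0.04 (exploration grows late).
- **Replacement:** children fully replace the generation; the global best is
  tracked separately and re-injected over the worst member whenever it
  vanishes, which guarantees a non-decreasing best-fitness trajectory.
- **Repair:** any all-zero chromosome (from init, crossover, or mutation)
  gets one uniformly random gene switched on — the mean over an empty
  selection is undefined.
- **Determinism:** one seeded generator drives init, selection, crossover
  and mutation in a fixed call order; population sorting breaks fitness ties
  by popcount then lexicographically. Identical dataset + config + seed
  reproduce the result bit-for-bit.

## Channel attention

For a C×H×W map, global average and max pooling give two C-vectors; both
pass through a shared two-layer MLP (weights V0: hidden×C, V1: C×hidden,
hidden = ⌈C/r⌉) and are summed before a logistic sigmoid. ReLU is the hidden
activation (the standard choice for this construction; configurable), biases
are off by default, and the reduction ratio defaults to r = 8 — an
implementation choice, as no canonical value is fixed for this operator in
the intended pipeline. The sigmoid output is clipped to the open unit
interval by one float64 ulp because the exact sigmoid saturates to 0/1 for
|pre-activation| ≳ 37, and the gating contract is strictly (0, 1). No
training loop is provided; weights are user-supplied or seeded-Gaussian
initialized with fan-in scaling.

## KNN and evaluation

KNN uses Euclidean distance with majority vote; k = 5 by default. Features
are standardized by the training mean/sd before distances (toggleable) so
high-variance columns cannot dominate; whether the original pipeline used
raw or standardized features is not documented, and standardization is the
safer default for deep features. Vote ties break by the smaller mean
neighbor distance, then the lowest class index — predictions are
deterministic. The report computes the confusion matrix (rows = true),
per-class one-vs-rest precision/recall/F1 with the zero-denominator → 0
convention (logged), and unweighted macro averages (equal to weighted
averages on balanced data). The rank-sum harness compares two samples of
run accuracies two-sidedly at significance 0.05, with exact enumeration for
tie-free samples of at most 8 runs and the midrank normal approximation
otherwise; a comparison in which every observation is tied raises an
explicit degenerate-test error.

## Synthetic data

The generator plants a known structure so selection quality is measurable:

- **Informative columns** have class-conditional means placed on a regular
  simplex, tiled across columns and scaled so the Euclidean distance between
  class centroids over the whole informative block equals
  `class_separation` within-class standard deviations (within-class sd = 1).
  The scaling is exact whenever the informative count is a multiple of
  (n_classes − 1) and mean-exact otherwise. Simplex placement guarantees
  equal pairwise separation for any class count, and every informative
  column carries the same between-class variance.
- **Redundant columns** are near-copies: column j duplicates informative
  column (j mod n_informative) plus N(0, 0.1²) jitter by default; each copy
  records its source, so twin-aware recovery metrics are possible.
- **Noise columns** are class-independent standard normal.

Classes are balanced by default (per-class weights available); splitting is
stratified by class at 0.7/0.2/0.1 by default with largest-remainder
apportionment, so per-class counts follow the fractions to within one row.

What the generator does *not* emulate: the marginal distributions, sparsity
patterns and inter-feature dependence of real CNN features (no public
characterization exists to target), class imbalance artifacts, or batch
effects. Passing tests on this benchmark demonstrate that the machinery
finds planted signal under Gaussian conditions, not that any particular
accuracy transfers to real histopathology features.

## Benchmark conditions and what the experiments show

The standard desk-scale experiment (used by the acceptance script and the
recovery test) is 300 samples × 64 features: 8 informative at separation 5,
8 redundant copies, 48 noise, 3 balanced classes — a scaled-down analog of
reducing a 128-dimensional deep feature vector to a fraction of its size.
The GA runs under the published defaults in wrapper mode, since the filter
surrogate (a mean of per-feature scores) is maximized by very small, even
singleton, subsets and is therefore the wrong instrument for a
recover-most-of-the-signal experiment; wrapper mode is the configuration
under which subset recovery is identifiable. Recovery counts an informative
column as found when the subset contains it or one of its recorded twins —
a redundant copy is statistically the same planted signal.

Two caveats on this benchmark's resolution, measured and documented rather
than hidden: the 30-row test split quantizes accuracy in steps of 3.3
percentage points, so single-sample differences dominate comparisons tighter
than that; and once validation accuracy saturates (common at separation 5),
fitness differences between signal subsets vanish and roulette probabilities
over fitnesses clustered in a narrow band are nearly uniform, so which twins
survive is close to a best-of-N-draws process. Across replicate seeds the
selector reliably halves the feature space and matches or beats full-feature
KNN accuracy on held-out rows, but per-seed guarantees at the one-sample
level are not attainable under these conditions.

## Design choices on genuinely open points

- Per-gene swap crossover over "multi-point": the stage-level description of
  the crossover operation is per-gene probabilistic swapping, which is what
  ships by default; the k-point operator is available via config.
- Filter mode is the package default (the headline idea is removing
  classifiers from the fitness loop); wrapper mode is one config key away.
- Conditional (not unconditional) shift in roulette selection keeps
  probabilities exactly proportional for positive fitnesses while still
  handling non-positive values.
- The pipeline manifest contains no timestamps; identical config + seed
  yields byte-identical artifacts, which makes reproducibility checkable
  with `diff`.
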