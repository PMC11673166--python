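# Methods

## Problem setting

The package generates a patient-level numeric table from a flat vector of
published summary statistics, for situations where the real table is
inaccessible but its statistics are public. The generating model is a
GAN whose generator and discriminator are both conditioned on the
statistics vector; because no real table exists at training time, the
training corpus itself is manufactured from the statistics.

## Statistics schema

A table schema lists columns with kind (`continuous`, `count`, `binary`),
an inclusive value range, an optional clinical risk threshold with a
direction, and exactly one binary outcome column. The statistic menu is
a pure function of the schema: per column `min`, `max`, `mean`; per
thresholded feature column the *risky fraction* (share of values strictly
beyond the threshold) and the *odds ratio* of the risk indicator against
the outcome; and the outcome prevalence. For the default nine-column
diabetes schema this yields 44 statistics. The menu is configuration,
not a fixed constant: schemas with different thresholds produce different
vector lengths.

Numerical conventions:

* Percentages are stored as fractions in [0, 1]; CSV export keeps the
  fractional scale.
* The odds ratio is the cross-product ratio (a·d)/(b·c); when any cell of
  the 2×2 table is zero, 0.5 is added to every cell (Haldane–Anscombe),
  keeping the statistic finite so it can serve as a conditioning value.
* Extraction reduces each column after sorting it, so the extracted
  vector is bit-identical under any permutation of table rows.
* Perturbation is multiplicative: v → v·(1+u), u ~ Uniform(−a, +a), with
  a = 0.01 by default (a ±1% envelope). A repair pass afterwards restores
  the invariants (bounds clipped to the schema range, min ≤ mean ≤ max,
  fractions in [0, 1], odds ratios ≥ 0).

## Statistics-constrained table synthesis

No sampling law is implied by a statistics vector alone, so the corpus
builder fixes one that is deterministic and auditable:

1. **Risky partition.** Each feature column is split into risky and
   non-risky sub-ranges at the threshold. The risky count is
   `round(fraction · n_rows)` (ties to even); rows are assigned to the
   two groups at random (per column, seeded) so that risk flags are
   independent across columns, and values are drawn uniformly within each
   sub-range. Count columns use the integer sub-ranges
   (e.g. above-threshold integers), so rounding cannot move a cell across
   the threshold.
2. **Mean matching.** An iterative clip-and-shift moves the column mean
   onto the target while clipping each group back into its sub-range;
   for count columns the adjustment nudges individual cells by whole
   units instead (a uniform sub-0.5 shift would be erased by rounding).
   Tolerance: 1% of the column range, evaluated after rounding.
3. **Outcome assignment.** The number of cases is
   `round(prevalence · n_rows)`, clipped so both classes are present.
   Which rows become cases is a weighted draw without replacement
   (Gumbel-max): each row's log-odds is the sum of log target odds ratios
   over its risk flags. Realized odds ratios therefore *approximate*
   their targets; with eight feature columns and one outcome column the
   per-column odds ratios cannot in general be matched exactly, and the
   round-trip guarantees cover bounds, means, risky fractions and
   prevalence only.

The corpus builder perturbs the base vector once per table, synthesizes
the table, and then **re-extracts** the statistics from the written file,
so row i of the statistics CSV equals the extraction of table file i
exactly. The reference table itself never enters the corpus; it is held
out as ground truth for evaluation.

## Table-Similarity loss

For real X and synthetic Y of identical shape: column sums R, S give the
vertical term μ = mean|R_m − S_m|; row sums r, s give per-row minima
δ_n = min_i |r_n − s_i|, their mean ν, and the repeated-minimum fraction
P = N/n_rows where N counts δ entries whose value (rounded to 6 decimals)
occurs at least twice; D = ν·P and L = D + μ. The batch loss is
√(mean L).

Choices made where the definition admits readings:

* Column differences are paired by index and taken in absolute value;
  signed differences could drive μ and L negative and break the square
  root. The literal signed variant is available behind a flag.
* N counts all members of repeated groups (so identical tables give
  N = n_rows, P = 1, and still L = 0 because ν = 0).
* The square root on the batch mean is applied by default, with a flag to
  disable.
* The training gradient treats P as a constant per evaluation (it is
  piecewise constant in Y); the subgradient of the min uses the argmin
  row, and sign(0) = 0 makes the gradient vanish exactly on identical
  tables. The analytic gradient is verified against finite differences
  in the test suite.

## Conditioned GAN

Both networks are small fully connected stacks implemented directly on
numpy with hand-written backpropagation and Adam (β = (0.5, 0.999), a
common GAN-stabilizing choice).

* **Generator.** Input: noise (default dim 128) concatenated with the
  normalized statistics vector; the statistics are concatenated again
  after two hidden layers (re-injection keeps the conditioning visible
  after early layers have begun reconstructing the table). Hidden
  activations LeakyReLU(0.2); sigmoid output reshaped to
  (n_rows, n_cols) in [0, 1], then denormalized through the schema's
  per-column ranges. Default widths (256, 256, 256); output 766 × 9.
* **Discriminator.** The table is flattened; the statistics vector is
  concatenated onto the feature map after the first hidden layer
  (configurable). Output is a sigmoid probability.
* **Normalization.** Tables map to [0, 1] per column; statistics map to
  comparable units (range-scaled for min/max/mean, identity for
  fractions, x/(1+x) for odds ratios) — a pure function of the schema.
* **Objectives.** Discriminator: −(1/m)Σ[log D(x) + log(1 − D(G(z)))].
  Generator: (1/m)Σ log(1 − D(G(z))) + L_TS, where the TS loss is
  computed between the generated batch and the real tables paired with
  the same statistics rows. Scores are clamped to [1e−7, 1 − 1e−7]
  before logs.
* **Training.** Batches of 64 (statistics, table) pairs, trailing
  incomplete batches dropped, generator lr 1e-4 and discriminator lr
  5e-5 (the asymmetry damps mode collapse), up to 70 epochs by default.
  Training history records per-iteration generator/discriminator/TS
  losses and a per-epoch scatter snapshot of a monitored feature pair
  for visual drift inspection; stopping is by epoch count only — no
  automated quality-based stop is claimed.
* **Generation.** One seeded forward pass; postprocessing clips cells to
  column ranges, rounds count columns, thresholds the outcome at 0.5 and
  flips one cell if a class is missing.

Determinism: every stochastic step takes a seed; the pipeline derives
per-stage seeds as SHA-256(master seed, stage name) mod 2³¹−1. Repeated
runs with the same seeds are bit-identical on the same platform and
BLAS.

## Evaluation

**Fidelity (URA).** Per numeric feature column: Welch's t-test
(unequal-variance statistic, Welch–Satterthwaite degrees of freedom;
pass iff two-sided p > 0.05) and the 1-Wasserstein distance between
empirical CDFs after min-max scaling by the *real* column's range (pass
iff < 0.1; the threshold is configurable). The outcome column gets a
chi-square test on class counts, χ² = Σ(S−R)²/R with k−1 degrees of
freedom. Per metric, pass counts map to labels: Excellent above 50% of
features, Poor at zero, Good otherwise — a tie at exactly 50% is
conservatively Good. The URA total converts labels to 3/2/1, weights by
M = 1/n_metrics (kept exact internally; 0.33 is display rounding),
sums, rounds half-up and maps back.

**Utility (TSTR/TRTR).** Stratified 80/20 split of the real table (the
split protocol is this package's default, fixed-seed convention). TRTR
trains on the real training split, TSTR on the full synthetic table;
both score on the identical real test split with accuracy and weighted
precision/recall/F1. Classifier configurations are fixed: RF(88 trees,
depth 11, Gini, state 28), KNN(4 neighbours, cosine), DT(depth 7,
max features 2, state 27), MLP(hidden (32, 128, 256), ≤30 epochs,
stop after 10 epochs with <1e-4 loss improvement, state 9). The table
is Excellent when every |TRTR − TSTR| gap is strictly below 0.4; the
Good (< 0.8) / Poor extension is an artifact convention flagged as such.
TRTS is deliberately not part of the protocol.

## Synthetic reference fixture

The built-in 766 × 9 reference table emulates the marginal shapes of the
well-known Pima-Indians diabetes data (truncated Poisson pregnancies,
near-normal glucose/blood pressure/BMI, log-normal insulin and pedigree
function, gamma-shifted age) with the outcome drawn from a logistic
model on glucose, BMI, age, pedigree and pregnancies, calibrated to
~30% prevalence. Risky thresholds (glucose > 140, BMI > 30, blood
pressure > 90, age > 50, insulin > 200, skin thickness > 40, pedigree
> 1.0, pregnancies > 6) are clinically plausible fixture parameters.
It is a synthetic stand-in: it reproduces plausible marginals and
epidemiologically sensible odds ratios, but not the real data's missing
values coded as zeros, its exact correlation structure, or its outliers.
Passing tests against this fixture demonstrate that the machinery works
under controlled conditions, not that the generator reproduces the real
dataset.

## Problem sizes used in tests

The test and demonstration configurations are scaled down so the full
suite runs in seconds: a three-column schema with 50-row tables and
200-pair corpora for training checks (300 iterations), 40-pair corpora
for smoke tests, and a 200-pair / 100-row / 30-epoch demonstration
pipeline in the README. The full-scale defaults (10,000 pairs of 766 × 9
tables, 70 epochs, 10,920 iterations) are exercised arithmetically and
via shape checks at reduced pair counts.

## Known limitations

* Odds ratios are matched only approximately, both by the corpus
  synthesizer (greedy weighted assignment) and by the GAN.
* The corpus sampler draws uniformly within sub-ranges; it does not
  attempt realistic marginal shapes or inter-feature correlation — that
  is deliberately left for the GAN to learn.
* Only binary outcomes and numeric features are supported; no free-text
  or multi-class categorical columns.
* Privacy metrics (membership inference, distance to closest record) are
  out of scope; the method never sees real rows, but no formal privacy
  guarantee is evaluated.
* At desk scale the generator matches means well before it matches full
  distribution shapes; Wasserstein-based fidelity typically needs larger
  corpora and longer training than the scaled-down demos use.
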