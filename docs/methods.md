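# Methods

## The modeling problem

Given a table of molecular descriptors (numeric features computed from
chemical structures; here consumed in the PaDEL-Descriptor CSV layout)
and a measured activity (pIC50, the negative decadic logarithm of the
molar IC50), the workflow selects a small descriptor subset, fits a
multiple linear regression to it, establishes that the model is
predictive rather than a chance correlation, and delimits the region of
descriptor space in which its predictions can be trusted.  An extreme
learning machine provides a nonlinear comparison model on the same data.

pIC50 convention: activities are −log10 of the *molar* concentration, so
an IC50 given in µM converts as `pIC50 = 6 − log10(IC50[µM])` (1 µM →
6.0).  This is the only reading consistent with the bundled activity
range (4.0–5.5 for IC50s in the tens of µM).

## Pretreatment and data division

`pretreat` removes, in order: descriptors with any missing value;
near-constant descriptors (value range or variance below
`variance_epsilon`, default 1e-4); and, scanning left to right, any
descriptor whose absolute Pearson correlation with an earlier-kept one
exceeds `correlation_cutoff` (default 0.95).  Keeping the first member of
each correlated group makes the operation order-dependent but
deterministic and idempotent.  Min–max normalization is available but
never applied implicitly: the bundled external-validation table carries
raw-scale descriptor values, which shows the published model was fitted
on unnormalized descriptors.

`kennard_stone_split` seeds with the most distant compound pair
(Euclidean, on min–max-scaled descriptors by default so no single
large-scale descriptor dominates) and then repeatedly adds the compound
whose minimum distance to the selected set is largest, until
`floor(train_fraction · n)` training compounds are chosen (0.7 · 24 → 16,
matching the published 16/8 division).  All ties break toward the lowest
compound index; the floor (rather than round) is required to reproduce
the published 70% = 16-compound training set.

## GFA model selection

Candidate models are descriptor subsets with between `model_terms[0]` and
`model_terms[1]` members (default (4, 4), mirroring the published
four-descriptor model).  Fitness is the Friedman lack-of-fit of the OLS
fit, `LOF = SEE/(1 − (c + d·p)/M)²` with `c = p + 1` model terms
(intercept counted) and smoothing parameter `d = 0.5` by default; neither
`c`'s convention nor `d` is fixed by the source material, so both are
configurable.  The GA uses tournament selection (size 3), single-point
crossover on the sorted parent subsets with repair to the size bounds,
per-gene member-swap mutation (probability 0.1), elitism (2), and a small
random-immigrant step (5% of the population per generation) that guards
against premature convergence.  All randomness flows from one seed;
elitism makes the best-LOF history non-increasing.  The final population
is deduplicated by descriptor set and ranked ascending by LOF.

`enumerate_models` fits every subset of a given size exactly (capped at
1e5 subsets) and is the oracle the GA is tested against.

Known limitation: with 24 compounds and 200 descriptors the fitness
landscape is deceptive — a single informative descriptor with a moderate
coefficient can fit no better than a lucky noise subset, so signal is
visible only when several true descriptors co-occur in one individual.
At the tested budget (population 100, 200 generations) true-support
recovery on the synthetic preset is ≈ 90% of seeds, not 100%; larger
populations or budgets raise it.

## Validation battery

- `R² = 1 − Σ(y − ŷ)²/Σ(y − ȳ)²` on the training fit; adjusted R² uses
  the standard form `1 − (1 − R²)(n − 1)/(n − p − 1)` (the source's
  printed variant is typographically defective; the standard form
  reproduces its own worked value 0.990276 from R² = 0.992869, n = 16,
  p = 4 exactly).
- `q2_loo`: leave-one-out Q² via the PRESS identity
  `e_(i) = e_i/(1 − h_ii)`, algebraically equal to refitting without each
  compound (tested to 1e-10 against explicit refits).  Leave-one-out is
  the conventional cross-validation scheme for training sets this small.
- `r2_pred = 1 − Σ(ŷ_test − y_test)²/Σ(y_test − ȳ_ref)²`.  The reference
  mean ȳ_ref is selectable: `training_only` (default for new work) or
  `all_compounds` — the published worked example uses the mean of all 24
  activities (4.3699), not the 16 training ones (4.4348), and only that
  convention reproduces its R²pred of 0.7560.  The report records which
  convention was used.
- VIF per descriptor from auxiliary regressions (infinite, not an
  exception, under exact collinearity); mean effects normalized to sum
  to 1.
- Y-randomization: OLS refits on permuted activities;
  `cRp² = R·sqrt(R² − mean R²_perm)` (0 when the gap is negative).
- Applicability domain: leverages `h_i = a_i(AᵀA)⁻¹a_iᵀ` with an
  intercept column appended (so training leverages lie in [1/n, 1] and
  sum to p + 1), warning threshold `h* = 3(p + 1)/n`, standardized
  residuals = residual / training SEE with the conventional ±3 outlier
  band.  When the training fit is exact (SEE < 1e-12) standardized
  residuals are defined as zero rather than dividing rounding noise by
  rounding noise.
- Checklist thresholds: R² ≥ 0.6, Q² ≥ 0.5, R² − Q² < 0.3, ≥ 5 external
  compounds, cRp² ≥ 0.5.

## The bundled study data and the reconstructed equation

The three printed activity tables (24 experimental/predicted activities
with the 16/8 partition; the 8 external compounds' raw descriptor values
and predictions; the 24-compound model-comparison table with per-compound
% errors) are bundled as CSV fixtures.  The published model equation's
ETA_Shape_P coefficient was printed as an integer with its decimal point
lost; `paper_model()` reconstructs it at run time by a one-unknown
least-squares solve over the eight external rows (≈ 1.72442; a 1e-6
brute-force scan agrees), after which all eight printed predictions are
reproduced within 5e-4.  Printed residuals and the 4-decimal rounding of
the tables limit agreement on recomputed statistics to roughly 1e-4,
which is the tolerance the reproduction checks use.

## Extreme learning machine

Hidden weights and biases are drawn uniformly from [−1, 1] under a seed
(the conventional ELM initialization; the distribution is not otherwise
specified by the protocol), the hidden output matrix is
`P = γ(XWᵀ + b)` for an activation γ in {sigmoid, sine, hardlim, tribas},
and output weights are `pinv(P)·y`, the minimum-norm least-squares
solution.  `(seed, n_hidden, activation, n_inputs)` regenerate the hidden
layer exactly, so a model serializes as those four values plus the output
weights.  `optimize_elm` shuffles compounds under a split seed, holds out
every fifth compound (4:1), scans activations × hidden counts (1–100),
and keeps the lowest test RMSE, breaking ties by higher CC and then fewer
hidden nodes.  Metrics: MAE, RMSE, Pearson CC, and MAPD =
mean(100·|error|/observed).

On noiseless linear data the selected network's test RMSE plateaus near
1–2% of the activity spread rather than at zero: random bounded sigmoid
features approximate but cannot represent an affine map exactly.

## Synthetic data

`generate_dataset` draws standard-normal descriptors (a lognormal option
exercises the normalization path with heterogeneous, skewed scales),
plants constants, exact duplicates and Gaussian-mixed correlated pairs,
and builds the activity as a sparse linear signal (default 4 informative
descriptors, coefficients of random sign with magnitude 0.5–2.0) plus
Gaussian noise (default SD 0.05 pIC50 units) and an offset of 4.4 to land
in a plausible potency band.  `paper_shaped_dataset` fixes the study
geometry (24 × 200).  What the generator does *not* emulate: real
descriptor semantics, their heterogeneous units and ranges (beyond the
lognormal flag), block-correlation structure among descriptor families,
or activity measurement error beyond i.i.d. Gaussian noise — so passing
tests demonstrate algorithmic correctness under the assumed statistical
structure, not performance on real chemistry.

## Problem sizes and determinism

Tests and examples run at the study's own scale (≤ 24–40 compounds,
≤ 200 descriptors; GA budgets of 100 × 200) so the full suite completes
in well under a minute of compute.  Every stochastic component (GA, ELM
weights, splits, permutation tests, the generator) takes an explicit seed
and is bit-reproducible; the pipeline writes all seeds to its run log and
rerunning a config reproduces every artifact byte-for-byte.
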