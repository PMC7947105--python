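# qsarforge

A Python library for building and validating quantitative
structure–activity relationship (QSAR) models, built around the workflow
used to model the antiproliferative activity (pIC50 against the MiaPaCa-2
pancreatic cancer cell line) of a series of 2-alkoxycarbonylallyl esters:

- **Pretreatment** of PaDEL-style descriptor tables: removal of columns
  with missing values, near-zero variance, or high pairwise correlation;
  optional min–max normalization `x' = (x − x_min)/(x_max − x_min)`.
- **Kennard–Stone splitting** into a space-covering training set and an
  external test set by deterministic max–min Euclidean selection.
- **Genetic function approximation (GFA)**: a genetic algorithm over
  descriptor subsets, each scored by an OLS fit's Friedman lack-of-fit

  `LOF = SEE / (1 − (c + d·p)/M)²`, `SEE = sqrt(RSS/(n − p − 1))`,

  with `p` descriptors, `c` model terms (intercept included), smoothing
  parameter `d`, and `M` training compounds; plus an exhaustive
  enumeration oracle for small instances.
- **Validation battery**: R², adjusted R², leave-one-out Q², external
  R²pred, per-descriptor variance-inflation factors `VIF = 1/(1 − R²_j)`
  and mean effects `ME_j = B_j ΣD_j / Σ_j(B_j ΣD_j)`, Y-randomization
  (cRp²), and a leverage applicability domain
  `h_i = x_i(XᵀX)⁻¹x_iᵀ` with warning threshold `h* = 3(p+1)/n`
  (Williams-plot data), checked against the conventional minima
  (R² ≥ 0.6, Q² ≥ 0.5, R² − Q² < 0.3, ≥ 5 test compounds, cRp² ≥ 0.5).
- **Extreme learning machine (ELM)**: a single-hidden-layer network with
  seeded random hidden weights, output weights solved via the
  Moore–Penrose pseudoinverse, and activation/hidden-node optimization on
  a seeded 4:1 split scored by MAE, RMSE, CC and MAPD.
- **Synthetic data** with known ground truth (sparse linear signal,
  planted constant/duplicate/correlated nuisance descriptors) so every
  stage is testable end to end.

The published study's printed activity tables ship as built-in fixtures
(`load_fixture("table4"|"table5"|"table10")`), including the published
model equation — whose fourth coefficient lost its decimal point in
typesetting and is reconstructed at run time by a one-unknown
least-squares solve over the printed external-validation rows.

## Worked example

```
$ python examples/reproduce_published_tables.py
completed model:
  ATSC3c       +2.115052
  MATS5p       -0.917422
  minHBint5    -0.160590
  ETA_Shape_P  +1.724420
  intercept    +3.419964

external test-set predictions (computed vs printed):
  compound 10: 4.5560 vs 4.5560
  compound 12: 3.8943 vs 3.8942
  ...
published-value checks:
  PASS  r2_pred: 0.7561
  PASS  test_pearson_r2: 0.8396
  PASS  warning_leverage: 0.9375
  PASS  qsar_mae: 0.0562
  ...
```

The completed four-descriptor equation reproduces all eight printed
external predictions within 5×10⁻⁴ pIC50 units; R²pred = 0.756 means the
model explains three quarters of the external test-set activity variance
around the reference mean (4.3699), and `h* = 0.9375` is the leverage
beyond which a compound lies outside the model's applicability domain.

Other examples: `synthetic_gfa_workflow.py` (pretreat → Kennard-Stone →
GFA → validation on ground-truth data), `elm_regression.py`,
`applicability_domain.py`.

A thin CLI mirrors the library:
`qsarforge pretreat|split|gfa|predict|validate|elm|synth|fixtures|run|reproduce-paper`
(see `qsarforge --help`).

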