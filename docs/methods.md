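# Methods

## Synthetic cohort generator

The generator emulates a two-wave midlife survey panel. Each subject has 32
bounded attitude items, age, sex, six baseline (wave-1) and six follow-up
(wave-2) Ryff well-being scores, and a binary depression label. Default
sizes follow the modelled study design: 2718 training subjects with no
depressed individuals, and a test partition of 394 depressed plus 779
non-depressed (total 1173).

Planted structure, and what it is for:

* **Latent attitude traits.** Items are not independent: a primary "coping"
  trait loads along the normalized depression-shift direction and an
  orthogonal secondary trait loads on the same item block (loadings fixed,
  trait SDs 2.0 and 1.0). Attitude items in real questionnaires correlate
  through latent dispositions; operationally the traits give the 2-D map
  axes to embed, so the direction in which depressed respondents differ is
  representable on the map. Without them a 32-D isotropic cloud has no
  2-D structure and the depressed subpopulation would scatter uniformly
  over the grid.
* **Depression shift.** Depressed subjects' item means move by a per-item
  vector (default −1 on items 1–8, +1 on items 9–16, on a 1–7 scale with
  item SD 1.1). That is a ≈2-trait-SD displacement along an embedded
  direction: strong enough to form a high-odds region, weak enough that
  the regions overlap (the max-odds cluster's odds land near 1–1.6, not
  at infinity).
* **Items.** Truncated normal per item (scipy `truncnorm` with per-subject
  location), so values respect the 1–7 bounds without a clipping spike.
  Items 17–24 drift up and 25–32 down with age (slope 0.8 over ±25 years
  around age 50); ages are uniform on 25–74. This both makes
  psychological age recoverable from the questionnaire and gives the
  well-being/age trend curves non-trivial shape.
* **Follow-up well-being.** `wb2_d = clip(g_d(items) + ε)`, with
  `g_d = 1 + 6·expit(w_d·(items − 4)/||w_d||)` and ε Gaussian
  (`noise_sd = 0.5`). The link is monotone but nonlinear (sigmoidal), so
  linear baselines underfit while a small network recovers it; with
  `noise_sd → 0` the follow-up is an exact function of the items, which
  the predictor tests exploit. The default weights `w_d` load positively
  on items 1–8 and negatively on 9–16 — matching the depression shift's
  sign pattern, so depressed-leaning profiles have lower planted future
  well-being — plus one extra per-dimension weight on an age-drifting
  item so the six dimensions differ.
* **Baseline well-being.** Scaled Beta(5, 1.5) on the 1–7 range (bulk near
  the top, long left tail — the regime in which bin means are
  unrepresentative and the share-of-high-scorers trend statistic earns its
  keep), plus a 0.3-weighted alignment with the planted item signal so the
  baseline has some, but not decisive, predictive value for the follow-up.
* **Sex.** P(male) is 0.32 for depressed and 0.41 for non-depressed
  subjects (≈0.40 marginal). A plain Bernoulli(0.40) would also do, but
  the depression-dependent rate gives the cluster table's sex column a
  planted pattern (the depression-prone cluster comes out least male),
  mirroring the sex imbalance reported in depression epidemiology.

One global seed feeds a `SeedSequence`-spawned stream per subsystem (age,
sex, traits, items, wave-1, wave-2), so regeneration is bit-identical and
each subsystem's draws are independent of the others' order of evaluation.

What the generator does **not** emulate: item wording or real marginal
distributions, missing data, panel attrition, measurement invariance
across waves, or any causal structure between attitudes and later
depression. Tests passing on these cohorts show the algorithms recover
planted structure of the stated kind and strength — not that the same
structure exists in real survey data.

## SOM

From-scratch online Kohonen training. Choices the underlying description
leaves open, fixed as follows:

* **Scaling.** Items are z-scored with training-data statistics stored in
  the model; SOM distances are scale-sensitive and codebook read-outs are
  inverse-transformed back to 1–7 item units for reporting.
* **Schedule.** `σ(t) = σ₀/(1 + t/(T/2))`, same for the learning rate,
  with `T = max_epochs × presentations-per-epoch` (defaults: 100 epochs,
  one pass worth of samples per epoch, sampled with replacement). This is
  the standard asymptotic-decay schedule of common SOM libraries.
* **Initialization.** Codebook sampled uniformly within the per-feature
  range of the scaled data, from the config seed.
* **Convergence.** After each epoch the quantization error (QE) over the
  full training data is logged; training stops when QE has failed to
  improve by more than `1e-4` (standardized units) for 5 consecutive
  epochs. The returned codebook is the best state seen, the initial one
  included — on small maps a broad neighborhood can transiently worsen an
  already-good random start, and best-state restoration makes "training
  never degrades QE" hold unconditionally.
* **Grid.** Rectangular lattice, neighborhood distance in grid
  coordinates, 8-connectivity for both the U-matrix and the path graph
  (diagonal steps allowed). Cell indices are 0-based row-major; ties in
  BMU lookup resolve to the lowest index.

## Atlas

Per-cell odds are raw `n_depressed / n_nondepressed`; a cell with depressed
subjects but no non-depressed ones reports infinite odds flagged "capped",
and unoccupied cells report NaN. Cluster statistics sum counts over cells
first and take the odds of the sums (not the mean of per-cell odds).
Clusters are re-labelled 1..k by descending odds so "cluster 1" is always
the depression-prone one. The odds/well-being association uses Spearman
correlation across occupied cells with finite odds — odds are heavy-tailed
and the relationship is monotone, not linear; p-values are reported
per-dimension without multiplicity adjustment (six tests, stated as such).

With a 25 × 25 map and ~1200 mapped test subjects there are ~2 subjects
per occupied cell, so per-cell odds are noisy and the three-cluster
contrast is diluted relative to a 12 × 12 map; the cluster-level odds
remain ordered but the max-odds cluster can land slightly below or above
odds 1 depending on the seed. The worked examples use 12 × 12 for this
reason; the acceptance script runs the full 25 × 25 configuration.

## Paths

Bellman–Ford is implemented directly (the graph is small; 625 nodes,
~4800 edges). Among equally short paths, the lexicographically smallest
cell sequence is returned by walking from the source and taking the
lowest-index neighbor consistent with the distance-to-target field (float
ties compared at relative tolerance 1e-9). Endpoints: hotspot = occupied
cell with maximal odds (capped infinities allowed; ties by depressed
count, then index), stable = minimal odds (ties by non-depressed count,
then index). Recommendations rank features by the signed endpoint delta in
original item units; ranking by the max–min excursion along the path is
available behind a flag (`mode="range"`). Exactly-zero deltas are dropped
from the top lists.

## Predictors

The published architecture (4 hidden layers; 256 units for age, 400 for
well-being; LeakyReLU; dropout 0.25; L2 1e-6 / 1e-7; MAE objective) is
preserved in the configuration (`PredictorConfig.paper_scale`), but the
compute backend is scikit-learn's `MLPRegressor`, which imposes three
deviations: ReLU instead of LeakyReLU, no dropout (the `dropout_p` field
is recorded but inert), and a squared-error training objective (MAE is
the reported metric, not the loss). Defaults are scaled down to 2 × 64 for
desk-scale runs. The adam solver uses batch 32 with early stopping
(patience 10, 10% validation split); an L-BFGS solver option converges
much tighter on small noiseless fits and is used by the planted-recovery
tests. Determinism is per-seed (fold seeds derive from the config seed).

Two numerical caveats surfaced by degenerate targets: a near-unregularized
network fitted to a *constant* target interpolates it exactly on training
points yet wiggles between them (out-of-fold MAE ≈ 0.4); with strong L2
the weights vanish, biases carry the constant, and the out-of-fold error
drops to ~1e-3. The constant-target test therefore uses `l2 = 1.0`.

Age correction fits a linear regression of predicted on chronological age
over the training split and returns
`chronological + (predicted − fit(chronological))`; a regression fit was
chosen over binned means (the open alternative) because it is smooth,
needs no bin-width choice, and makes the residualization property —
corrected deltas uncorrelated with age — exact in expectation.

Well-being trends use the fraction of subjects at ≥ 90% of the scale
maximum per 5-year age bin (bin width is a convention, not fitted); bins
with no subjects or zero actual fraction are excluded from the
predicted-vs-actual trend MAPE with a warning.

## Selection and importance

`shadow_select` is Boruta-style all-relevant selection: per round, every
feature gets an independently permuted shadow copy, a random forest
(80 trees, √p features per split) is fitted, and a feature scores a hit if
its impurity importance beats the best shadow. Hits over 50 rounds are
tested against Binomial(rounds, 0.5) at α = 0.01, one-sided each way;
with several targets a feature confirmed for any target is confirmed
overall and rejection must be unanimous. Known small-sample caveat: with
in-sample impurity importance the feature with the largest *chance*
association in a fixed finite sample can beat the re-rolled shadows
round after round and get confirmed even under a null design — visible at
n ≈ 300, gone by n ≈ 2000. The type-I property (confirmed fraction
≤ 2α over seeded null replicates) holds at small n; exact zero
confirmations should only be expected at large n.

`vif_filter` computes VIF_j = 1/(1 − R²_j) via statsmodels with an
intercept column added internally (statsmodels assumes the design carries
a constant), removing the highest-VIF feature (lowest index on ties) until
all survive at VIF ≤ 10; exact collinearity yields infinite VIFs that are
removed first.

`en_importance` regresses one follow-up well-being dimension on sex, age,
the model-predicted value for that dimension, and all six baseline scores.
Predictors are standardized first — the coefficients are compared as
importances, which requires a common scale. Hyperparameters come from
5-fold cross-validated MAE over the fixed grid (l1_ratio 0, 0.01, …, 1;
penalty 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.0, 1.0, 10, 100); the literal
penalty 0.0 is treated as the unpenalized least-squares limit and fitted
by `LinearRegression`. The winner is the predictor with the largest
absolute coefficient, with near-ties flagged.

## Problem sizes

Unit tests run on reduced fixtures (cohorts of a few hundred subjects,
maps of 5 × 5 to 12 × 12); the shared end-to-end fixture uses the full
cohort proportions on a 12 × 12 map. The acceptance script runs the full
study conditions — 2718/1173 cohort, 25 × 25 map, complete elastic-net
grid, 50-round selection — in about two minutes on one CPU.

## Known limitations

* The SOM quality cross-check compares quantization error against a
  minimal independent online-Kohonen oracle at matched parameters, not
  against an external SOM library.
* Cluster count k = 3 is an input, not inferred; the dendrogram is cut at
  exactly k.
* The elastic-net winner-takes-all reading of standardized coefficients
  ignores coefficient uncertainty; near-ties are only flagged, not tested.
* Real-data error levels (psychological-age MAE in years on survey data,
  per-dimension well-being MAPE) are properties of the restricted survey
  cohort and are not reproduced by the synthetic conditions; the package's
  planted-cohort results validate the machinery, not those numbers.
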