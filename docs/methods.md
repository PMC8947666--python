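# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `metalrisk`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py` at run time.

## Exposure model

Each detection record is one laboratory measurement (mg/kg) of chromium,
cadmium or arsenic in a grain processing product. Preprocessing applies, in
order: stripping of a leading `<` from semi-quantified results (the numeric
value is kept and the record treated as uncensored); substitution of
below-LOD ("not detected") results by half the limit of detection — the
standard credible treatment of left-censored contaminant data, preferred to
zero-substitution because it neither hides nor exaggerates low-level
contamination; and conversion of total arsenic to inorganic arsenic at a
fixed 70% ratio, guarded by a per-record flag so re-running the step cannot
double-convert. LOD resolution prefers a per-record value and falls back to
a per-metal table, since real surveillance mixes assays with different LODs.

Per day and metal we aggregate the pollution indexes P = X/S (S the national
limit standard, configurable; defaults 1.0 / 0.2 / 0.2 mg/kg for Cr / Cd /
inorganic As in grain products) into max and mean, and the concentrations
into 50th and 95th percentiles (linear-interpolation quantiles; the scheme
is configurable because published analyses rarely state theirs).

Three daily indexes follow per metal:

* NIPI = sqrt((Pmax² + Pavg²)/2) — sensitive to peak contamination;
* TCR = EF·ED·CSF·EDI50/ATC, EDI50 = FC·X50/W — chronic cancer risk at the
  typical (median) daily concentration;
* THQ = EF·ED·EDI95/(ATC·RfD) — non-cancer hazard at the day's upper tail.

Units: RfD is interpreted as mg/(kg·d) — the printed reference values
0.003/0.001/0.0003 for Cr(III)/Cd/As match the standard oral references on
that scale — concentrations as mg/kg, consumption FC as kg/d. With the
default EF = 365 d/yr, ED = 70 yr and ATC = 365·ED d, the chronic prefactor
is identically 1, so TCR = CSF·EDI50 and THQ = EDI95/RfD to machine
precision (asserted in the tests). All three indexes are positively
homogeneous of degree one in the concentration scale, which the property
suite also asserts; this homogeneity is what lets the synthetic generator's
regime multipliers translate directly into index displacements.

FC defaults to the unweighted mean of the 20 provincial consumption values
(kg/d). The survey table is provincial while the exposure equations call for
a per-capita national figure; the unweighted mean is the neutral choice in
the absence of population weights, and per-province assessment is available
by passing the provincial value instead.

## Entropy-weight fusion

The nine per-metal indexes are reduced to comprehensive NIPI/TCR/THQ with
entropy weights: column proportions p_tj = x_tj/Σ_t x_tj (0·ln 0 ≡ 0),
normalised entropy e_j = −(1/ln n)Σ p ln p, weight w_j ∝ 1 − e_j. Indicators
that vary more across days carry more information and weigh more; constant
columns get weight zero, and an all-constant matrix is an error.

The nine weights sum to one globally, but each comprehensive index is
produced from only its three per-metal values, so the default fusion mode
renormalises each index type's three weights to a convex combination. A
`global` mode (raw weights, no renormalisation) exists for sensitivity
analysis, and subjective multipliers can be folded in for combined
subjective/objective weighting. Weights are fitted on the training portion
of the series only and frozen afterwards, so the test period cannot leak
into the fusion.

## Risk levels

The comprehensive triples are min–max normalised to [0,1]³ (bounds stored
for forecasts and for the inverse transform; min–max rather than z-scoring
because the published normalized centers lie in the unit cube) and clustered
with K-means++: distance-squared-proportional seeding, Lloyd iterations to
an assignment fixpoint, best of 10 restarts by within-cluster sum of
squares. Empty clusters are repaired by re-seeding the center to the point
farthest from its assigned center, keeping k fixed. On tiny instances the
fit provably reaches the global optimum (checked against exhaustive
enumeration over all labelings in the tests).

The cluster count is selected by the average silhouette coefficient over
k = 3…7; ties go to the smaller k. Singleton-cluster members score 0 by
convention. Centers are ordered by Euclidean distance to the origin and
named Low / Medium / Second-Highest / High risk (generic names for k ≠ 4);
a longer distance means a higher integrated risk. Classification of any
normalized triple is nearest-center; exact ties break toward the lower-risk
level — the alternative (conservative escalation) would inflate alarms, and
on continuous data ties have probability zero anyway.

## Forecasting

Forecasting operates on the normalized scale so forecasts feed the
classifier directly. A window of n = 7 days (the weekly reporting cycle)
maps to the next day's value; τ-step forecasts iterate the one-step model,
feeding each prediction back into the window, so beyond 7 steps the input is
fully synthetic and errors can accumulate — which is why evaluation fixes a
21-day step with horizons reported at 7/14/21 and weekly accuracy treated as
the headline.

Three one-step architectures are trained per comprehensive index: a simple
recurrent (tanh) unit, a GRU and an LSTM, each a single recurrent layer
(32 units) with a linear read-out, squared-error loss, full-batch Adam
(lr 0.01, 200 epochs), gradient clipping at global norm 5, deterministic
initialisation from the seed. They are implemented directly in NumPy with
hand-written backpropagation through time, verified against
finite-difference gradients in the tests; at this problem size (a few
hundred windows of length 7) a training run takes well under a second, so no
framework or accelerator is warranted.

Training adds per-epoch Gaussian jitter (sd 0.03 on the normalized scale) to
the input windows. This is the standard mitigation for the exposure-bias
failure of recursive forecasting: a model fitted only on observed windows
can respond erratically to windows containing its own slightly-off
predictions, and a small input perturbation during training makes the
learned map smooth in exactly the neighbourhood recursion explores. Without
it, recursive trajectories were observed to overshoot the series mean and
cross risk-level boundaries spuriously.

The voting ensemble combines the three architectures' forecasts with simplex
weights chosen by exhaustive grid search (step 0.05, 231 candidates for
three models) to maximise the risk-level prediction accuracy on the final 21
days of the training segment — never on test data. PA is piecewise constant
in the weights, so a grid is exact up to its resolution and exactly
reproducible; ties break to the lower mean squared error, then
lexicographically. Evaluation uses three dataset splits: two share the 80/20
ratio with different 21-day test windows, the third shares the second's test
window with a 70%-length training span, separating the effect of the test
period from the effect of the split ratio. A naive persistence baseline
(repeat the last observed value) is scored alongside the sub-models and the
ensemble.

## Synthetic data

The real national sampling dataset is access-restricted, so the generator
emulates its statistical shape rather than its content:

* concentrations are log-normal (the standard model for contaminant data),
  with per-metal medians 0.08 / 0.045 / 0.06 mg/kg and log-scale SDs
  0.45 / 0.40 / 0.35 for Cr / Cd / As — chosen so daily NIPI values straddle
  1 under contaminated regimes;
* daily sample counts are Poisson with mean 150 per metal, comparable to the
  ~70 samples/metal/day of a national-scale programme and enough to make
  daily quantiles informative;
* LODs of 0.05 / 0.025 / 0.035 mg/kg censor roughly 11% of records;
* four contamination regimes drive the day's distribution: background;
  elevated-median (median ×2.0 — moves TCR and the mean pollution index);
  heavy-tail (log-SD ×2.6 — moves THQ and the daily maximum while barely
  moving the median); and combined. Regimes follow a sticky Markov chain
  (persistence 0.9) whose switch propensities favour background 6 : 1 : 1.5
  : 0.5, reproducing the strong low-risk imbalance of real surveillance
  series (most days are ordinary);
* a shared AR(1) log-median wander (lag-1 correlation 0.92, stationary SD
  0.06) gives the series day-to-day continuity beyond regime switches, the
  temporal structure a recurrent forecaster is supposed to exploit.

`regime_separation_check` propagates the regime multipliers through the
index pipeline by Monte Carlo and reports the per-regime centroids in
normalized space; under the defaults all pairwise centroid distances exceed
0.15, which is why the end-to-end run recovers the four regimes (silhouette
selects k = 4; adjusted Rand agreement above 0.8, typically 1.0).

What the generator does **not** emulate: provincial or seasonal composition
(province labels are sampled independently of concentration), laboratory
batch effects, reporting delays, and any real dependence between metals
beyond the shared daily regime and trend. Passing tests therefore
demonstrate that the pipeline recovers structure of this idealised form, not
that it would classify the real national data identically.

## Numerical and degenerate-input conventions

* Quantiles: linear interpolation between order statistics; values sorted
  before aggregation so summaries are exactly order-invariant.
* Entropy: 0·ln 0 ≡ 0; all-zero columns are treated as constant (zero
  weight).
* K-means: assignment-fixpoint stopping (tol guards are nominal), 10
  restarts by default, all randomness from one integer seed recorded in the
  fitted model.
* Min–max normalization refuses constant columns; forecast-period values may
  leave [0,1] legitimately (the bounds come from the training portion).
* Recursive forecasting with τ = 0 returns an empty forecast; a history of
  the wrong length is an error.
* The simplex grid requires the step to divide 1 exactly (rational grid), so
  candidate weights sum to one without rounding error.

## Limitations

* Risk levels are relative (data-driven cluster positions), not absolute
  toxicological thresholds; a fully low-risk year would still be divided
  into levels if silhouette favoured it.
* The silhouette criterion can legitimately prefer merging the two
  least-separated regimes (k = 3) on unlucky draws; the level classification
  itself remains accurate in those cases.
* The MSE-trained forecasters are calibrated for point accuracy, not level
  accuracy; only the ensemble weights optimise the level criterion directly.
  On a strongly regime-switching series a persistence baseline is a hard
  target for 7-day level accuracy, and matching it (rather than beating it)
  is the typical outcome.
* Evaluation windows are short (21 days per split) by design — the weekly
  reporting use case — so reported accuracies are coarse-grained (multiples
  of 1/21).
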