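# metalrisk

Early-warning analysis of heavy-metal hazards in grain processing products:
daily detection records of chromium, cadmium and arsenic are turned into
risk-assessment indexes, fused into a comprehensive daily risk profile,
classified into data-driven risk levels, and forecast up to three weeks
ahead with a voting ensemble of recurrent neural predictors.

The package is aimed at food-safety surveillance analysts who receive daily
laboratory sampling results and need a weekly, level-based risk outlook
rather than raw concentration tables.

## The model

For every day *t* and metal *j*, three indexes are computed from the day's
samples (concentrations X in mg/kg, national limit S in mg/kg):

* **NIPI** (Nemerow integrated pollution index)
  `Pc = sqrt((Pmax² + Pavg²)/2)` over the day's pollution indexes `P = X/S`
  — a quadratic mean emphasising peak contamination;
* **TCR** (target cancer risk)
  `TCR = EF·ED·CSF·EDI50 / ATC` with `EDI50 = FC·X50 / W`, the estimated
  daily intake at the day's median concentration;
* **THQ** (target hazard quotient)
  `THQ = EF·ED·EDI95 / (ATC·RfD)` at the day's 95th percentile.

Defaults: exposure frequency EF = 365 d/yr, duration ED = 70 yr, averaging
time ATC = 365·ED d (so EF·ED/ATC = 1), body mass W = 60 kg, consumption FC
from a 20-province survey table, RfD = 0.003/0.001/0.0003 mg/(kg·d) and
CSF = 0.5/6.3/1.5 (kg·d)/mg for Cr/Cd/As, total arsenic counted as 70%
inorganic. Below-LOD results are replaced by half the limit of detection.

The nine per-metal indexes are fused into comprehensive NIPI/TCR/THQ with
**entropy weights** `w_j ∝ 1 − e_j`, where `e_j` is the normalised Shannon
entropy of indicator *j* across days. Days are then clustered with
**K-means++** on the min–max-normalised triples; the cluster count is chosen
by the average silhouette coefficient, and clusters are ordered into risk
levels (Low < Medium < Second-Highest < High) by the Euclidean distance of
their centers from the origin. Any day — observed or forecast — is assigned
the level of its nearest center.

Forecasting iterates one-step recurrent regressors (simple RNN, GRU, LSTM,
window of 7 days) recursively for τ-step prediction; the three sub-model
forecasts are combined by a **voting ensemble** `h_t = Σ w_i ζ_i` with
simplex weights selected by exhaustive grid search to maximise the risk-level
prediction accuracy `PA = (1/T) Σ I(K(h_t) = K(y_t))`.

The real national sampling dataset is access-restricted, so a seeded
synthetic generator (`metalrisk.synthetic`) emulates its structure:
log-normal concentrations with below-LOD censoring, province labels, a
sticky Markov schedule of contamination regimes and a slow AR(1) drift of
the daily median.

## Worked example

```python
from metalrisk import run_pipeline

res = run_pipeline(seed=1, n_days=300)
print("selected k:", res.selected_k)
print("regime agreement (ARI):", round(res.regime_agreement, 3))
print("7-day level accuracy, ensemble:   %.2f%%" % (100 * res.pa("voting-ensemble", 7)))
print("7-day level accuracy, persistence: %.2f%%" % (100 * res.pa("persistence", 7)))
print({k: round(v, 3) for k, v in res.level_proportions.items()})
```

prints (exactly reproducible from the seed):

```
selected k: 4
regime agreement (ARI): 1.0
7-day level accuracy, ensemble:   90.48%
7-day level accuracy, persistence: 90.48%
{'Low-Risk': 0.547, 'Medium-Risk': 0.3, 'Second-Highest Risk': 0.123, 'High-Risk': 0.03}
```

i.e. the silhouette criterion recovers the four injected contamination
regimes perfectly, and the voting ensemble predicts the correct risk level
on 19 of the 21 evaluation days (three datasets × 7-day horizon), matching
the naive persistence baseline on this run.

The same stages are available from the shell:

```sh
metalrisk simulate --seed 1 --days 300 --out records.csv
metalrisk assess --input records.csv --out assessed/
metalrisk classify --series assessed/comprehensive.csv --out levels/
metalrisk evaluate --seed 1 --out report/
metalrisk config --show-defaults
```

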