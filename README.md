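# icucourse

Ordinal disease-course trajectory modelling for critically ill patients.

Intensive-care records are a heterogeneous mix of static admission
variables (demographics, injury characteristics, imaging reports, free
text) and dynamic in-ICU measurements (vitals, labs, medications), sampled
irregularly and riddled with missing values that are often informative in
themselves. `icucourse` converts such records — with minimal processing
and no imputation — into an interpretable prognostic time series:

1. **Tokenisation.** Each stay is split into non-overlapping time windows
   (2/8/12/24 h). Numeric values become quantile-bin tokens learned from
   training data, categorical and normalised free-text values become
   `variable_value` tokens, and every missing value becomes an explicit
   `variable_NA` token. Static tokens are carried into every window.
2. **Trajectory model.** Each token has a learned embedding vector and a
   positive relevance weight; a window is the relevance-weighted average of
   its token vectors. A GRU or LSTM consumes the window sequence, and an
   ordinal decoder emits, per window, monotone threshold probabilities
   `q_t(k) = sigmoid(b·h_t − θ_k)` over the six cuts of a 7-category
   functional-outcome scale (an 8-point scale with two categories merged),
   plus the implied class probabilities and the expected outcome index
   `e_t = Σ_c c·p_t(c)`.
3. **Evaluation.** Repeated stratified nested cross-validation (up to
   20 repeats × 5 folds), Somers' Dxy of outcome given model score
   (the proportion of ordinal outcome variation explained), logistic
   recalibration slope and smoothed calibration curves, bootstrap
   bias-corrected cross-validation (BBC-CV) intervals across candidate
   configurations, and time-resolved metric series aligned both from
   admission and backwards from discharge.
4. **Transitions & attribution.** High-magnitude prognostic transitions
   are consecutive-window probability changes beyond the population's
   1st/99th percentiles within a calibrated analysis region; each is
   attributed to time windows and tokens with Shapley values against an
   "average patient" baseline (tokens present in ≥ 50% of training
   windows), using temporal coalition pruning to group the distant past.

Because real critical-care registries are access-restricted, the package
ships a synthetic-cohort generator with the same statistical structure —
mixed-type variables, 2-h sampling, variable-length stays, MNAR
missingness, a proportional-odds outcome — and a known ground-truth
severity, whose Monte-Carlo concordance ceiling D* anchors all recovery
tests.

## Worked example

```bash
icucourse generate --out-dir demo/data --n-patients 200 --seed 1
icucourse train --data-dir demo/data --run-dir demo/run \
    --window-h 24 --n-bins 10 --embed-dim 16 --repeats 1 --folds 5 --seed 1
icucourse evaluate --run-dir demo/run --window-h 24
icucourse transitions --run-dir demo/run --window-h 24
```

On this 200-patient cohort the run prints, per fold, lines such as

```
repeat 0 fold 0: test Dxy at discharge = 0.490
...
pooled out-of-fold Dxy at discharge: 0.444
mean calibration slope at discharge: 0.519
30 high-magnitude transitions
```

meaning: ranking patients by the model's expected outcome index at
discharge explains ~44% of the ordinal variation in their outcomes
(pooled over out-of-fold predictions); a recalibration slope well below
one indicates overfitting at this small cohort size (at 2,000 patients,
`scripts/acceptance.py` reaches Dxy ≈ 0.53 with slope ≈ 0.86); and 30
consecutive-window probability jumps exceeded the population's
extreme-percentile cut-offs inside the 10–168 h calibrated region.
Library usage mirrors the CLI; see the module docstrings under
`src/icucourse/`.

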