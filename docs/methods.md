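# Methods

This note records the modelling assumptions, numerical choices, and the
design decisions that were genuinely open, in the package's own terms.

## Data model

Records are long-format observations `(patient, variable, time_h, value)`
with a variable dictionary (static/dynamic; numeric/categorical/text; one
of nine category groups; intervention and physician-impression flags) and
a 7-category ordinal outcome per stay (an 8-point functional-outcome scale
with the two lower-severe-disability categories merged, giving six ordered
thresholds `k = 1..6`, "outcome above cut k"). Admission is time 0;
static observations carry no timestamp at all, so "static" is structural
rather than a time-0 convention. Stays must last at least 24 h. Files
are tab-separated UTF-8 with the literal missing marker `NA`; rows sort
canonically on write so read/write round-trips are byte-exact. The
outcomes file also carries each stay's discharge hour, since stay length
is a first-class quantity (windowing, discharge-aligned metrics) and no
other file could hold it without overloading the observation rows.

## Tokenisation

* Windows are half-open `[w·W, (w+1)·W)` hours from admission, `W ∈ {2, 8,
  12, 24}`; the final partial window is kept so discharge-aligned analyses
  see the last data collected.
* Numeric bin edges are the interior n-quantile cut points (`n ∈ {3, 4, 5,
  7, 10, 20}`) of the pooled training values, quantiles by linear
  interpolation between order statistics (the common "type 7" rule, used
  consistently for bins and for transition percentiles). Duplicate edges
  merge, so heavily tied variables get fewer bins; a constant variable
  collapses to a single value token. Values below/above the training
  range clamp to the extreme bins, preserving ordering; unseen
  categorical/text tokens map to a reserved `<UNK>` embedding.
* Binning is inclusive on the left: a value equal to an edge takes the
  lower bin.
* Text normalisation keeps lowercase alphanumerics only; an empty result
  is treated as missing.
* Every variable owns a `variable_NA` token. A window's token set is
  static tokens ∪ in-window dynamic value tokens ∪ `NA` tokens of dynamic
  variables unobserved in that window, so each variable is represented in
  every window and the embedding average is always well defined.
  Repeated within-window numeric observations each contribute their bin
  token; sets deduplicate identical bins. This is the least lossy choice
  for a set representation; worst-value aggregation would be a sensitivity
  axis, not the default.

## Trajectory model

The model is implemented in NumPy with hand-derived gradients (verified
against central differences in the test suite) and Adam.

* Relevance weights are `softplus` of a free parameter, initialised so
  `w ≈ 1`; a window embedding is `Σ w_i v_i / Σ w_i` over its unique
  tokens.
* The recurrent core is a single-layer GRU (default) or LSTM, hidden state
  initialised to zeros. Outputs at window t depend only on windows ≤ t.
* Ordinal head: scalar score `s = b·h`, cut points ordered by construction
  via `θ_1 = c_0`, `θ_k = θ_{k-1} + softplus(c_{k-1})`, and
  `q(k) = sigmoid(s − θ_k)`, so threshold monotonicity holds exactly for
  every output. Class probabilities come from differencing; the expected
  outcome index is their mean. The multinomial head is a 7-way softmax
  whose threshold probabilities are upper-tail sums; both heads emit both
  representations, derived consistently.
* Loss: mean negative log-likelihood of the true category over all
  (patient, window) cells, equally weighted — the simplest defensible
  choice, and it makes per-timepoint evaluation comparable across stay
  lengths. Early stopping on validation NLL (patience 12, max 150
  epochs); class probabilities are floored at 1e−12 inside the log.
* Defaults: embedding 16, hidden 32, Adam at 0.01, batch 64. One seed
  fans out to initialisation and batch shuffling, so runs are
  bit-reproducible; checkpoints embed the vocabulary checksum and refuse
  to load against a different vocabulary.

## Evaluation

* Partitions: repeated stratified k-fold (default 20 × 5) with a
  stratified validation split (15%) nested in each training remainder;
  stratification of the validation split falls back to a plain shuffle
  when a fold's category counts cannot support it (tiny cohorts only).
* Somers' Dxy is the concordance of the ordinal outcome given a scalar
  score, `(C − D)/(C + D + T_score)` over outcome-discordant pairs —
  equivalently twice the usable-pair c-index minus one. The scalar score
  is the expected outcome index at the evaluated window (threshold-level
  concordance can be derived from the exported trajectories). Constant
  scores give Dxy 0 (all usable pairs are ties); a single outcome
  category makes Dxy undefined, reported as a value-with-reason rather
  than a number.
* Calibration: probabilities are clipped to `[1e−6, 1−1e−6]` before the
  logit; the slope is the coefficient of a binomial GLM of outcome on
  `logit(q_k)`, summarised per timepoint as the mean over the six cuts.
  Smoothed curves use a local-linear LOWESS (default span 0.75, widened
  with a warning when the sample is tiny) on a 101-point grid over the
  observed prediction range; the summary is the mean absolute deviation
  from the diagonal.
* BBC-CV: patient-level bootstrap of pooled out-of-fold predictions;
  each resample selects the best configuration in-bag and scores it
  out-of-bag; the estimate is the mean out-of-bag metric and the interval
  its 2.5/97.5 percentiles. Resamples whose out-of-bag patients cannot
  support the metric are redrawn and counted. With one configuration this
  reduces to an ordinary bootstrap.
* Time-resolved series cover the first and last 7 days of stay; patients
  contribute only while in ICU, and timepoints with fewer than 50
  contributors (configurable) are suppressed as unstable tails.

## Transitions

Consecutive-window threshold-probability differences are pooled across
test-set trajectories (across partitions) within the calibrated region,
default 10–168 h from admission. Per threshold, the cut-offs are the 1st
percentile of negative and 99th percentile of positive differences
(percentile level configurable — the 1%/99% choice is a convention, not an
estimate); zero differences belong to neither collection, and comparisons
at the cut-off are inclusive. A transition between windows t−1 and t is
stamped at `t·W` hours.

## Attribution

The "average patient" baseline is the token set present in at least half
of training windows (inclusive at exactly 50%); because rarely observed
variables appear mostly via their missing tokens, the baseline is never
empty. A player that is absent from a coalition has its content replaced
by the baseline: whole windows for window-level games, per-token baseline
substitution (the variable's baseline token, typically its `NA` token) for
token-level games. Temporal pruning grows the suffix of individually
resolved windows until the grouped past's two-player Shapley contribution
falls within `prune_tol` (default 0.05 on the target scale); smaller
tolerances never resolve fewer windows. Games with ≤ 12 players are
solved exhaustively (efficiency, null player, and symmetry hold to
numerical precision); larger games use KernelSHAP-weighted regression on
paired antithetic coalition samples with a fixed seed, which preserves the
efficiency constraint exactly. Targets are the expected outcome index
(default for population summaries) or any single threshold probability.
Token-level attribution defaults to the event window plus the preceding
window; population summaries average per patient over that patient's
events before taking medians across patients, and rank the ten most
negative then ten most positive non-missing-value variables, with
missing-token effects summarised separately.

## Synthetic cohort

The generator emulates the *structure* the pipeline assumes, not any real
cohort's marginals: per patient, standard-normal static numerics,
3-level categoricals, free-text from a small phrase bank with punctuation
and case noise (exercising text normalisation); a dynamic-only latent
`u ~ N(0,1)` expressed solely through AR(1) dynamic trajectories sampled
every 2 h; latent severity `s = β·statics + γ·u + ε`; a proportional-odds
outcome `P(Y > k) = sigmoid(s − θ_k)`; per-observation missingness
`sigmoid(logit(base) + δ_var·s)` (MNAR when δ ≠ 0); and log-linear
severity-coupled stay lengths floored at 24 h, with an optional
"extreme severities discharge sooner" coupling for stay-length subgroup
analyses. All randomness flows from one seed through named substreams.

Default conditions: 4 static numerics with β = (1.0, 0.8, 0.5, 0.0),
3 categoricals with ±0.6 level effects, γ = 0.8, ε-sd 0.25, 10% baseline
missingness, AR(1) with ρ = 0.7 and innovation sd 0.5. The noise and
missingness levels are set so that the observable records retain most of
the systematic severity signal — with heavy missingness or a dominant ε
the oracle ceiling would be unreachable by *any* observer of the files,
and recovery tests would measure the generator, not the model.

The oracle ceiling D* is the Monte-Carlo concordance of the *systematic*
severity (β-weighted statics plus γ·u) with outcomes drawn from the full
latent including ε: ε shapes the outcomes but no model observing the
records could recover it, so it belongs in the outcome draw and not in the
score. Its standard error comes from 20 batch replicates.

What passing recovery tests do and do not show: the generator has linear
effects, stationary AR dynamics, a correctly specified proportional-odds
link, and a token vocabulary that is small relative to real registries
(~15 variables vs ~1000). Recovery within a fixed band of D* therefore
demonstrates that the pipeline loses little information to tokenisation,
embedding, and recurrent fitting under these conditions — not that it
would explain comparable outcome variance in real critical-care data,
where effect sparsity, non-stationarity, and inter-centre heterogeneity
dominate.

## Problem sizes

Cross-validated recovery runs use 24-h windows and 10-quantile bins on
2,000 patients (1 repeat × 5 folds) in `scripts/acceptance.py`; the test
suite runs the same constructions at 300–1,000 patients, and the
informative-missingness comparison at 400 patients × 5 generator seeds
with 8-h windows (finer windows make the per-window missingness indicator
more informative, which is the quantity under test). These sizes are the
package's desk-scale defaults; every construction scales up unchanged.

## Known limitations

* No unit harmonisation or free-text NLP beyond character normalisation.
* The model is explanatory, not a deployable predictor; trajectories are
  for mining observational structure, and Shapley values are associative,
  not causal.
* No neural-ODE alternative to discretised time; no variable-interaction
  Shapley values; no GPU path.
* The multinomial head's threshold probabilities are derived (tail sums),
  so their monotonicity is inherited rather than parameterised.
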