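# Methods

`valuelearn` simulates a child value-learning study — Pavlovian
conditioning of five geometric cues followed by an instrumental
approach/avoid task — and implements the analysis chain used to quantify
learning and its behavioral use. Because every stage of the analysis is
validated against cohorts with planted ground truth, the package doubles
as a parameter-recovery harness for the estimators it ships.

## Task model

A session presents 5 cue conditions (points, positive image, aversive
noise, negative image, neutral) × 14 trials = 70 trials in a random
per-participant order. Cues are shown for up to 1.5 s, followed by a 6 s
fixation delay and a 1.5 s outcome; inter-trial intervals are jittered
uniformly on 2.5–5.5 s. Non-neutral cues deliver their reinforcer with
probability 0.8 per trial (independent Bernoulli draws by default; an
`exact_ratio` switch forces round(0.8·14) = 11 reinforcers per condition
for deterministic fixtures). The neutral cue is always followed by the
scrambled image. Cue–condition pairings are counterbalanced across
participants with a deterministic cyclic Latin square (row *i* is row 0
shifted by *i*); any Latin square satisfies the counterbalance, and the
cyclic one makes pairings reproducible. Schedule onsets use the full
1.5 s response window rather than each agent's realized reaction time, so
a schedule is fully determined by its configuration and seed and can be
built before any agent exists.

## Generative agent

Cue values follow the Rescorla–Wagner delta rule, V ← V + α(r − V), with
reward coding r = +1 when an appetitive reinforcer is shown, −1 when an
aversive one is shown, and 0 for the scrambled image. This is the minimal
learning model with a single learning-rate parameter; values stay in
[−1, 1] by construction. The default generating α is 0.2, the group value
the estimator is expected to recover.

Expression channels:

- **Reaction time.** RT = rt_base − rt_gain·|V| + N(0, rt_sd), truncated
  to [150, 1500] ms. Salience is unsigned: conditioning speeds detection
  regardless of valence. Defaults: rt_base 600 ms, rt_gain 300 ms,
  rt_sd 65 ms (cohort sampling jitters these per participant;
  rt_gain ∈ [250, 350], rt_sd ∈ [50, 80]). The linkage strength is set so
  that the pooled learning-rate recovery study at n = 72 is well powered
  (standard error of the pooled grid argmin ≈ 0.006, i.e. below one grid
  step); a much weaker or noisier linkage would make the central recovery
  property a test of sampling luck rather than of the estimator.
- **Ratings.** pre ~ N(50, vas_sd) and post = pre + vas_gain·V_final +
  N(0, vas_sd), both clipped to the 0–100 visual-analogue scale.
- **Choice.** P(approach) = logistic(β·V), the two-action softmax.
  Approaching reveals the scheduled outcome; avoiding shows a blank
  screen, so with `continue_learning` enabled only approached trials
  update V (the avoided outcome is unobserved).
- **Recall.** Two 4AFC blocks (cue→outcome, outcome→cue; block order
  counterbalanced). Each item is retrieved with probability p_recall;
  on failure the agent guesses uniformly among the 3 distractors, or
  among all 4 presented options in the `guess_among_all` variant
  (accuracy p + (1 − p)/4).
- **Cardiac IBI.** Beat-to-beat interval = ibi_base + ibi_react·boxcar(t)
  + N(0, ibi_sd), where the boxcar is |valence| over each trial's 6 s
  anticipation window: a cardiac orienting (deceleration) response to any
  motivationally salient cue, so both appetitive and aversive conditions
  lengthen IBI relative to neutral. Defaults 800 / 50 / 20 ms.

## Planted phenotypes

The cohort generator plants a 2×2 mixture with equal weights. All
phenotypes share α = 0.2; they differ in *expression* gains:
vas_gain ∈ {2, 30} (low/high learning evidence in the conditioning task)
and β ∈ {0.3, 6} (low/high use of value in the choice task). This is the
simplest generative account of a learning/use dissociation — learning is
intact everywhere, expression varies by channel — and `continue_learning`
is exposed for the alternative re-learning account. Per-participant
randomness derives from `SeedSequence(seed).spawn`, so cohorts are
bit-reproducible across platforms (PCG64).

What the generator does *not* emulate: missing responses, attentional
lapses or RT drift, demographic covariates, rating anchoring biases, ECG
artifacts beyond out-of-range beats, and any correlation between
channels other than that induced by the shared value trace. Passing
recovery tests therefore show the estimators are correct under the
generative model, not that real data satisfy that model.

## Learning-rate estimation

For each α on the grid {0.01, …, 1.00} the realized outcome sequence is
replayed through the delta rule to give S_t = |V_t| before trial t's
update; RT is regressed on S_t by closed-form OLS and the SSE recorded.
The subject estimate is the grid argmin (smallest α on ties, for
determinism). Missing RTs are excluded from the regression but still
drive value updates, since the outcome was displayed regardless. A
profile is declared unidentifiable when its range is below 1e−6 of its
minimum (flat by construction when RTs carry no value signal); such
subjects get the grid midpoint, flagged, and are excluded from pooling.
The group estimate is the argmin of the summed SSE profiles
(fixed-effects pooling); the median of per-subject estimates is reported
alongside because a single group value could equally be a central
tendency of individual fits. The regression slope is reported unsigned
(expected negative: speeding); no sign constraint is imposed.

## Behavioral analysis

- **Learn score:** unstandardized residualized change — (post − pre)
  regressed on pre, residuals returned; they sum to zero and are
  orthogonal to pre. With zero pre-variance the centered change is
  returned with a warning. Scores are multiplied by condition valence
  (`sign_align`) so "higher = more learning" on every axis.
- **Use score:** fraction of expected responses (approach appetitive,
  avoid aversive) over the first 5 trials. Default scope is
  `per_condition` (first five trials of that condition); `whole_task`
  restricts to the condition's trials among the first five trials of the
  whole task and may be undefined for some subjects, which is why
  per-condition is the default for clustering.
- **Clustering:** per-condition k-means (Lloyd, random initialization,
  best of `restarts` by inertia, fixed random_state) on the two
  within-condition z-scored features; k = 4 for the headline analysis.
  Clusters are labeled by centroid quadrant (HH/HL/LH/LL). `select_k`
  provides a mean-silhouette sensitivity analysis with a no-structure
  flag when the maximum silhouette is below 0.25; note that an
  unstructured 2-D Gaussian cloud still scores ≈ 0.33 under Euclidean
  k-means, so the flag marks only severe absence of separation and the
  meaningful comparison is against the planted-structure score.
- **Concordance:** learn and use are dichotomized (median split with
  ties to "low", or a 1-D 2-means split), cross-tabulated, and
  summarized by Cohen's κ and the uncorrected chi-square statistic.
- **Conditioning effect:** a sign-flip permutation test on mean rating
  change (two-sided, p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1))
  replaces mixed-model fits, which need the real multi-level data.

## Physiology

Instantaneous IBI (t_k − t_{k−1}, assigned to the later beat) is screened
against 300–2000 ms plausibility bounds (an automated stand-in for visual
artifact inspection), linearly interpolated onto a 4 Hz grid spanning the
valid beats (no extrapolation), and averaged over half-open per-trial
windows: anticipation [cue onset, cue onset + 6 s) and reinforcer
[outcome onset, next cue onset), the latter 4–7 s long under the default
design (1.5 s outcome + 2.5–5.5 s ITI). Epochs with fewer than two grid
samples are flagged.

## Numerical and design choices

- Fixed α grid rather than continuous optimization: the reported group
  value is a single number and a grid argmin is exactly reproducible;
  ties break to the smaller α.
- Half-open epoch windows avoid double-counting grid samples.
- k-means uses random (not k-means++) initialization with multiple
  restarts, matching plain Lloyd-with-restarts semantics.
- Problem sizes in the validation suite: 50 replicate cohorts of n = 72
  for learning-rate recovery, 40 seeded cohorts for quadrant coverage,
  500 replicates for permutation-test uniformity — sizes at which the
  Monte-Carlo error of each property is small relative to its margin.

## Known limitations

- The RT linkage is linear with Gaussian noise; no drift-diffusion or
  lapse process, so fitted intercepts/slopes should not be interpreted
  mechanistically.
- Fixed-effects SSE pooling assumes a shared α; with true heterogeneity
  the pooled argmin is a variance-weighted compromise, not a mean.
- Quadrant coverage at n = 72 fails in a small fraction of cohorts
  (≈ 10%) purely through sampling: a mixture cell can be drawn small
  enough that k-means merges it with a neighbor. This is a property of
  the planted study size, not of the clustering code.
- The IBI generator produces stationary noise around a baseline; no
  respiratory sinus arrhythmia or slow drift.
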