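# valuelearn

Simulator and inference pipeline for studies of conditioned value
learning in children: a Pavlovian conditioning task in which five
geometric cues are probabilistically paired with appetitive, aversive, or
neutral outcomes, followed by an instrumental approach/avoid task, an
explicit recall test, and cardiac (inter-beat-interval) recording.

The package is aimed at researchers who want to (a) prototype and
power-check this paradigm, and (b) validate the paradigm's analysis chain
by parameter recovery on cohorts with planted ground truth:

- **Design** — counterbalanced, seeded trial schedules: 5 conditions ×
  14 trials, 0.8/0.2 probabilistic reinforcement, Latin-square
  cue–condition pairing.
- **Agents** — Rescorla–Wagner learners, V ← V + α(r − V), whose values
  drive reaction times (RT = β₀ − β₁·|V| + ε), 0–100 valence ratings,
  a logistic approach policy P(approach) = σ(β·V), 4AFC recall, and
  anticipatory cardiac deceleration.
- **Cohorts** — populations with a planted 2×2 phenotype mixture
  (high/low learning expression × high/low use), written to tidy CSVs.
- **Inference** — learning-rate estimation by grid search: for each α,
  RT is regressed on the model-implied salience |V_t| and the group α is
  the argmin of summed SSE profiles.
- **Analysis** — residualized-change learning scores, expected-use
  scores, per-condition k-means with HH/HL/LH/LL quadrant labels,
  Cohen's κ concordance, a sign-flip permutation test.
- **Physio** — beat series → 4 Hz interpolated IBI → per-trial
  anticipation/reinforcer epoch means.

## Worked example

```
valuelearn recover --n 72 --seed 0 --out report/
cat report/recovery.txt
```

prints

```
generating alpha        : 0.20
pooled alpha estimate   : 0.20
median subject alpha    : 0.20
quadrant coverage       : {'points': True, 'positive_image': True, 'aversive_noise': True, 'negative_image': True}
recall accuracy (mean)  : 0.886
IBI aversive - neutral  : 43.2 ms
all checks passed       : True
```

Reading this: 72 simulated children learned with α = 0.2, and the
RT-based grid fit recovered exactly that pooled value. k-means (k = 4) on
standardized learn × use features found clusters covering all four
high/low-learning × high/low-use quadrants in each of the four reinforcer
conditions — the planted dissociation between Pavlovian learning and its
instrumental use. Recall accuracy (88.6%) sits far above the 25% 4AFC
chance level, and anticipation-epoch IBIs on aversive-noise trials run
~43 ms longer than on neutral trials, recovering the planted +50 ms
cardiac orienting effect through the resampling/epoching pipeline (edge
samples of each 6 s window dilute the boxcar slightly).

The same stages are available piecewise:

```
valuelearn simulate --n 72 --seed 0 --out data/
valuelearn fit-alpha --data data/ --out fits/
valuelearn analyze   --data data/ --out analysis/ --k 4 --first-k 5
valuelearn epoch-ibi --data data/ --out ibi_epochs.csv
```

or from Python:

```python
from valuelearn import sample_cohort, fit_cohort, build_features, cluster_learn_use

ds = sample_cohort(n=72, seed=0)
fits, group = fit_cohort(ds.conditioning_trials)
print(group.pooled_alpha)            # 0.2
feats = build_features(ds.ratings, ds.choice_trials, "points")
print(cluster_learn_use(feats, k=4, seed=0).quadrant_labels)
```

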