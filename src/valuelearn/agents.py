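"""Generative model of one participant.

A single agent learns cue values with the Rescorla-Wagner delta rule
(V <- V + alpha * (r - V), reward code r = valence on reinforced trials and
0 on scrambled outcomes), and expresses that value through four channels:

* reaction times that speed linearly with cue salience |V|,
* pre/post valence ratings on a 0-100 visual analogue scale,
* a logistic approach/avoid policy on signed value in the choice task,
* cardiac inter-beat intervals that lengthen during anticipation of
  motivationally salient outcomes (cardiac orienting).

A four-alternative forced-choice recall model covers the explicit memory
test of the cue-reinforcer pairings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import (
    NON_NEUTRAL_CONDITIONS,
    Outcome,
    ReinforcerKind,
    SessionSchedule,
)

__all__ = [
    "AgentParams",
    "ValueTrace",
    "rw_update",
    "simulate_conditioning_session",
    "generate_vas_ratings",
    "choice_policy",
    "simulate_choice_session",
    "simulate_recall",
    "simulate_ibi_series",
    "RT_FLOOR_MS",
    "RT_CEILING_MS",
]

RT_FLOOR_MS = 150.0
RT_CEILING_MS = 1500.0


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated participant.

    alpha            learning rate in [0, 1]
    rt_base_ms       baseline reaction time (ms)
    rt_gain_ms       RT speeding per unit salience |V| (ms)
    rt_sd_ms         Gaussian RT noise SD (ms), > 0
    vas_gain         rating points per unit value
    vas_sd           rating noise SD (points)
    beta_choice      inverse temperature of the approach policy, >= 0
    p_recall         probability of retrieving a pairing from memory
    ibi_base_ms      baseline inter-beat interval (ms)
    ibi_react_ms     IBI lengthening during salient anticipation (ms)
    ibi_sd_ms        beat-to-beat Gaussian IBI noise SD (ms)
    continue_learning  keep updating values from observed outcomes in the
                       choice task (approach trials only; avoiding hides
                       the outcome, so no update occurs)
    """

    alpha: float = 0.2
    rt_base_ms: float = 600.0
    rt_gain_ms: float = 300.0
    rt_sd_ms: float = 65.0
    vas_gain: float = 30.0
    vas_sd: float = 8.0
    beta_choice: float = 6.0
    p_recall: float = 0.9
    ibi_base_ms: float = 800.0
    ibi_react_ms: float = 50.0
    ibi_sd_ms: float = 20.0
    continue_learning: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.rt_sd_ms <= 0:
            raise ValueError("rt_sd_ms must be > 0")
        if self.vas_sd < 0:
            raise ValueError("vas_sd must be >= 0")
        if self.beta_choice < 0:
            raise ValueError("beta_choice must be >= 0")
        if not 0.0 <= self.p_recall <= 1.0:
            raise ValueError("p_recall must lie in [0, 1]")
        if self.rt_base_ms - self.rt_gain_ms < RT_FLOOR_MS:
            raise ValueError(
                "rt_base_ms - rt_gain_ms must stay above the "
                f"{RT_FLOOR_MS:.0f} ms floor so RTs remain positive"
            )
        if self.ibi_base_ms <= 0 or self.ibi_sd_ms < 0:
            raise ValueError("invalid IBI parameters")


@dataclass
class ValueTrace:
    """Per-cue value trajectories; values[cue][k] is V after the cue's k-th update.

    Element 0 is the initial value 0, so each trajectory has
    (number of that cue's trials + 1) entries. Values stay within [-1, 1]
    because |reward codes| <= 1 and alpha in [0, 1].
    """

    values: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def final(self) -> dict[str, float]:
        return {cue: float(v[-1]) for cue, v in self.values.items()}


def rw_update(v: float, r: float, alpha: float) -> float:
    """One delta-rule step: v + alpha * (r - v). Fixed point at v = r."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return v + alpha * (r - v)


def _reward_code(condition: ReinforcerKind, outcome: Outcome) -> float:
    return float(condition.valence) if outcome is Outcome.REINFORCER else 0.0


def simulate_conditioning_session(
    agent: AgentParams,
    schedule: SessionSchedule,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, ValueTrace]:
    """Run one conditioning session.

    Per trial the agent presses as soon as it detects the cue:
    RT = rt_base - rt_gain * |V| + N(0, rt_sd), clipped to [150, 1500] ms,
    with V the cue's value *before* this trial's outcome is integrated.
    """
    rng = np.random.default_rng(seed)
    v = {cue: 0.0 for cue in schedule.pairing}
    traj: dict[str, list[float]] = {cue: [0.0] for cue in schedule.pairing}
    rows = []
    noise = rng.normal(0.0, agent.rt_sd_ms, size=len(schedule.trials))
    for i, trial in enumerate(schedule.trials):
        if trial.cue_id not in v:
            raise KeyError(f"cue {trial.cue_id!r} not in schedule pairing")
        v_pre = v[trial.cue_id]
        salience = abs(v_pre)
        rt = agent.rt_base_ms - agent.rt_gain_ms * salience + noise[i]
        rt = float(np.clip(rt, RT_FLOOR_MS, RT_CEILING_MS))
        r = _reward_code(trial.condition, trial.outcome)
        v[trial.cue_id] = rw_update(v_pre, r, agent.alpha)
        traj[trial.cue_id].append(v[trial.cue_id])
        rows.append(
            {
                "trial_index": trial.index,
                "condition": trial.condition.value,
                "cue_id": trial.cue_id,
                "outcome": trial.outcome.value,
                "value_pre": v_pre,
                "salience": salience,
                "rt_ms": rt,
                "cue_onset_s": trial.cue_onset_s,
                "outcome_onset_s": trial.outcome_onset_s,
                "iti_s": trial.iti_s,
            }
        )
    trace = ValueTrace({cue: np.asarray(t) for cue, t in traj.items()})
    return pd.DataFrame(rows), trace


def generate_vas_ratings(
    agent: AgentParams,
    final_values: Mapping[str, float],
    pairing: Mapping[str, ReinforcerKind],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Pre/post 0-100 valence ratings per cue.

    pre ~ N(50, vas_sd) clipped to [0, 100];
    post = clip(pre + vas_gain * V_final + N(0, vas_sd), 0, 100).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cue, cond in pairing.items():
        pre = float(np.clip(rng.normal(50.0, agent.vas_sd), 0.0, 100.0))
        post = float(
            np.clip(
                pre + agent.vas_gain * final_values[cue] + rng.normal(0.0, agent.vas_sd),
                0.0,
                100.0,
            )
        )
        rows.append(
            {"cue_id": cue, "condition": cond.value, "pre_rating": pre, "post_rating": post}
        )
    return pd.DataFrame(rows)


def choice_policy(v: float, beta_choice: float) -> float:
    """Probability of approach: logistic(beta * v). 0.5 at v=0 or beta=0."""
    if beta_choice < 0:
        raise ValueError("beta_choice must be >= 0")
    return 1.0 / (1.0 + math.exp(-beta_choice * v))


def simulate_choice_session(
    agent: AgentParams,
    schedule: SessionSchedule,
    value_trace_final: Mapping[str, float],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Approach/avoid choices given the values learned during conditioning.

    Approaching reveals the scheduled outcome; avoiding shows a blank
    screen, so no outcome is observed and (when continue_learning) no
    value update occurs on that trial.
    """
    rng = np.random.default_rng(seed)
    v = dict(value_trace_final)
    rows = []
    for trial in schedule.trials:
        v_pre = v[trial.cue_id]
        p = choice_policy(v_pre, agent.beta_choice)
        approach = bool(rng.random() < p)
        observed = trial.outcome.value if approach else "none"
        if approach and agent.continue_learning:
            r = _reward_code(trial.condition, trial.outcome)
            v[trial.cue_id] = rw_update(v_pre, r, agent.alpha)
        rows.append(
            {
                "trial_index": trial.index,
                "condition": trial.condition.value,
                "cue_id": trial.cue_id,
                "value_pre": v_pre,
                "p_approach": p,
                "approach": approach,
                "observed_outcome": observed,
                "button_green_side": trial.button_green_side,
            }
        )
    return pd.DataFrame(rows)


def simulate_recall(
    agent: AgentParams,
    pairing: Mapping[str, ReinforcerKind],
    seed: int | np.random.Generator,
    guess_among_all: bool = False,
    block_order: int = 0,
) -> pd.DataFrame:
    """Two-block four-alternative forced-choice recall of the pairings.

    Block A shows each cue and asks which outcome followed it; block B shows
    each reinforcer and asks which cue preceded it. Each item is retrieved
    with probability p_recall; on failure the agent guesses uniformly among
    the 3 distractors, or among all 4 options when guess_among_all is set.
    """
    rng = np.random.default_rng(seed)
    cues = list(pairing)
    conds = [pairing[c] for c in cues]
    blocks = [
        ("shape_to_outcome", cues, [c.value for c in conds]),
        ("outcome_to_shape", [c.value for c in conds], cues),
    ]
    if block_order % 2 == 1:
        blocks = blocks[::-1]
    rows = []
    for block_name, prompts, answers in blocks:
        order = rng.permutation(len(prompts))
        for j in order:
            correct_option = answers[j]
            # 4AFC item: the correct option plus 3 distractors drawn from the rest
            others = [o for o in answers if o != correct_option]
            distractors = list(rng.choice(others, size=3, replace=False))
            if rng.random() < agent.p_recall:
                response = correct_option
            else:
                pool = [correct_option] + distractors if guess_among_all else distractors
                response = pool[rng.integers(len(pool))]
            rows.append(
                {
                    "block": block_name,
                    "block_order": block_order % 2,
                    "prompt": prompts[j],
                    "correct_option": correct_option,
                    "response": response,
                    "correct": response == correct_option,
                }
            )
    return pd.DataFrame(rows)


def _anticipation_windows(schedule: SessionSchedule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts, ends, mags = [], [], []
    for t in schedule.trials:
        starts.append(t.cue_onset_s)
        ends.append(t.cue_onset_s + schedule.config.delay_s)
        mags.append(abs(t.condition.valence))
    return np.asarray(starts), np.asarray(ends), np.asarray(mags, dtype=float)


def simulate_ibi_series(
    agent: AgentParams,
    schedule: SessionSchedule,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Beat timestamps (ms) spanning the session.

    Local IBI = ibi_base + ibi_react * boxcar(t) + N(0, ibi_sd), where the
    boxcar is |valence| over each trial's 6 s anticipation window: a cardiac
    orienting response that slows the heart while a motivationally salient
    outcome is awaited. Neutral trials leave the baseline unchanged.
    """
    rng = np.random.default_rng(seed)
    starts, ends, mags = _anticipation_windows(schedule)
    last = schedule.trials[-1]
    session_end_ms = (
        last.outcome_onset_s + schedule.config.outcome_duration_s + last.iti_s
    ) * 1000.0

    beats = [0.0]
    t = 0.0
    while t < session_end_ms:
        ts = t / 1000.0
        k = np.searchsorted(starts, ts, side="right") - 1
        effect = 0.0
        if k >= 0 and ts < ends[k]:
            effect = mags[k]
        ibi = agent.ibi_base_ms + agent.ibi_react_ms * effect + rng.normal(0.0, agent.ibi_sd_ms)
        ibi = max(ibi, 300.0)
        t += ibi
        beats.append(t)
    return np.asarray(beats)
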