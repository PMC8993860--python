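"""Trial-schedule construction for the conditioning and behavioral-choice tasks.

The paradigm pairs five geometric cues with five reinforcer conditions
(points, positive image, aversive noise, negative image, neutral). Each
session presents 14 trials per condition (70 total) in a randomized order;
non-neutral cues are followed by their reinforcer with probability 0.8 and
by a scrambled neutral image otherwise, while the neutral cue is always
followed by the scrambled image. Cue-condition pairings are counterbalanced
across participants with a cyclic Latin square.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ReinforcerKind",
    "Outcome",
    "DesignConfig",
    "TrialSpec",
    "SessionSchedule",
    "DEFAULT_CUE_IDS",
    "NON_NEUTRAL_CONDITIONS",
    "build_latin_square",
    "assign_pairings",
    "make_conditioning_schedule",
    "make_choice_schedule",
]


class ReinforcerKind(str, Enum):
    """One of the five cue conditions, with its motivational valence."""

    POINTS = "points"
    POSITIVE_IMAGE = "positive_image"
    AVERSIVE_NOISE = "aversive_noise"
    NEGATIVE_IMAGE = "negative_image"
    NEUTRAL = "neutral"

    @property
    def valence(self) -> int:
        """+1 appetitive, -1 aversive, 0 neutral."""
        return _VALENCE[self]


_VALENCE = {
    ReinforcerKind.POINTS: 1,
    ReinforcerKind.POSITIVE_IMAGE: 1,
    ReinforcerKind.AVERSIVE_NOISE: -1,
    ReinforcerKind.NEGATIVE_IMAGE: -1,
    ReinforcerKind.NEUTRAL: 0,
}

NON_NEUTRAL_CONDITIONS = (
    ReinforcerKind.POINTS,
    ReinforcerKind.POSITIVE_IMAGE,
    ReinforcerKind.AVERSIVE_NOISE,
    ReinforcerKind.NEGATIVE_IMAGE,
)

#: Default cue identifiers (arbitrary shape names; one per condition).
DEFAULT_CUE_IDS = ("circle", "square", "triangle", "star", "pentagon")


class Outcome(str, Enum):
    REINFORCER = "reinforcer"
    SCRAMBLED = "scrambled"


@dataclass(frozen=True)
class DesignConfig:
    """Timing and probability constants of one task session.

    Defaults reproduce the paradigm: 5 conditions x 14 trials, cue up to
    1.5 s, 6 s fixation delay, 1.5 s outcome, jittered 2.5-5.5 s ITI, and
    0.8 reinforcement probability on non-neutral trials.
    """

    n_conditions: int = 5
    trials_per_condition: int = 14
    p_reinforce: float = 0.8
    cue_duration_s: float = 1.5
    delay_s: float = 6.0
    outcome_duration_s: float = 1.5
    iti_range_s: tuple[float, float] = (2.5, 5.5)
    exact_ratio: bool = False  # force round(p * trials) reinforcers per condition

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_reinforce <= 1.0:
            raise ValueError(f"p_reinforce must lie in [0, 1], got {self.p_reinforce}")
        for name in ("cue_duration_s", "delay_s", "outcome_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.iti_range_s
        if lo > hi or lo < 0:
            raise ValueError(f"invalid iti_range_s {self.iti_range_s}")
        if self.n_conditions < 1 or self.trials_per_condition < 1:
            raise ValueError("n_conditions and trials_per_condition must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.trials_per_condition

    def to_yaml(self, path) -> None:
        d = {
            "n_conditions": self.n_conditions,
            "trials_per_condition": self.trials_per_condition,
            "p_reinforce": self.p_reinforce,
            "cue_duration_s": self.cue_duration_s,
            "delay_s": self.delay_s,
            "outcome_duration_s": self.outcome_duration_s,
            "iti_min_s": self.iti_range_s[0],
            "iti_max_s": self.iti_range_s[1],
            "exact_ratio": self.exact_ratio,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        iti = (d.pop("iti_min_s", 2.5), d.pop("iti_max_s", 5.5))
        return cls(iti_range_s=iti, **d)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: what is shown and when."""

    index: int
    condition: ReinforcerKind
    cue_id: str
    outcome: Outcome
    cue_onset_s: float
    outcome_onset_s: float
    iti_s: float
    button_green_side: Optional[str] = None  # "left"/"right", choice task only


@dataclass
class SessionSchedule:
    """Ordered trials of one session plus the pairing that generated them."""

    trials: list[TrialSpec]
    config: DesignConfig
    pairing: dict[str, ReinforcerKind]
    seed: int
    task: str = "conditioning"

    def __post_init__(self) -> None:
        counts: dict[ReinforcerKind, int] = {}
        for t in self.trials:
            counts[t.condition] = counts.get(t.condition, 0) + 1
        expected = self.config.trials_per_condition
        bad = {c: n for c, n in counts.items() if n != expected}
        if bad:
            raise ValueError(f"condition counts differ from {expected}: {bad}")
        if len(set(self.pairing.values())) != len(self.pairing):
            raise ValueError("pairing is not a bijection")

    def to_frame(self, participant_id: Optional[str] = None) -> pd.DataFrame:
        rows = [
            {
                "participant_id": participant_id,
                "task": self.task,
                "trial_index": t.index,
                "condition": t.condition.value,
                "cue_id": t.cue_id,
                "outcome": t.outcome.value,
                "cue_onset_s": t.cue_onset_s,
                "outcome_onset_s": t.outcome_onset_s,
                "iti_s": t.iti_s,
                "button_green_side": t.button_green_side,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def build_latin_square(n: int) -> np.ndarray:
    """Cyclic n x n Latin square: entry (i, j) = (i + j) mod n.

    Deterministic, so the cue-condition counterbalance is reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    i = np.arange(n)
    return (i[:, None] + i[None, :]) % n


def assign_pairings(
    participant_index: int,
    square: np.ndarray,
    cue_ids: Sequence[str] = DEFAULT_CUE_IDS,
    conditions: Sequence[ReinforcerKind] = tuple(ReinforcerKind),
) -> dict[str, ReinforcerKind]:
    """Cue -> condition bijection from row (participant_index mod n) of the square."""
    square = np.asarray(square)
    n = square.shape[0]
    if square.shape != (n, n):
        raise ValueError("square must be n x n")
    if len(cue_ids) != n or len(conditions) != n:
        raise ValueError(
            f"need {n} cue_ids and {n} conditions, got {len(cue_ids)} and {len(conditions)}"
        )
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    row = square[participant_index % n]
    return {cue_ids[j]: conditions[row[j]] for j in range(n)}


def _layout_trials(
    config: DesignConfig,
    pairing: Mapping[str, ReinforcerKind],
    rng: np.random.Generator,
    button_green_side: Optional[str],
) -> list[TrialSpec]:
    cue_by_condition = {cond: cue for cue, cond in pairing.items()}
    conditions = list(pairing.values())
    if len(conditions) != config.n_conditions:
        raise ValueError(
            f"pairing has {len(conditions)} conditions, config expects {config.n_conditions}"
        )

    order = np.repeat(np.arange(config.n_conditions), config.trials_per_condition)
    rng.shuffle(order)

    # Outcome flags per condition, either independent Bernoulli draws or an
    # exact round(p * trials) ratio shuffled over that condition's trials.
    flags: dict[ReinforcerKind, list[bool]] = {}
    for cond in conditions:
        m = config.trials_per_condition
        if cond.valence == 0:
            flags[cond] = [False] * m
        elif config.exact_ratio:
            k = int(round(config.p_reinforce * m))
            arr = np.array([True] * k + [False] * (m - k))
            rng.shuffle(arr)
            flags[cond] = list(arr)
        else:
            flags[cond] = list(rng.random(m) < config.p_reinforce)

    itis = rng.uniform(*config.iti_range_s, size=len(order))
    used: dict[ReinforcerKind, int] = {c: 0 for c in conditions}
    trials: list[TrialSpec] = []
    t = 0.0
    for i, ci in enumerate(order):
        cond = conditions[ci]
        reinforced = flags[cond][used[cond]]
        used[cond] += 1
        cue_onset = t
        # Full 1.5 s response window is used for onset bookkeeping; actual RTs
        # are produced by the agent and do not alter the schedule.
        outcome_onset = cue_onset + config.cue_duration_s + config.delay_s
        trials.append(
            TrialSpec(
                index=i,
                condition=cond,
                cue_id=cue_by_condition[cond],
                outcome=Outcome.REINFORCER if reinforced else Outcome.SCRAMBLED,
                cue_onset_s=cue_onset,
                outcome_onset_s=outcome_onset,
                iti_s=float(itis[i]),
                button_green_side=button_green_side,
            )
        )
        t = outcome_onset + config.outcome_duration_s + itis[i]
    return trials


def make_conditioning_schedule(
    config: DesignConfig,
    pairing: Mapping[str, ReinforcerKind],
    seed: int,
) -> SessionSchedule:
    """Randomized conditioning session: 70 trials by default, reproducible by seed."""
    rng = np.random.default_rng(seed)
    trials = _layout_trials(config, pairing, rng, button_green_side=None)
    return SessionSchedule(trials=trials, config=config, pairing=dict(pairing), seed=seed)


def make_choice_schedule(
    config: DesignConfig,
    pairing: Mapping[str, ReinforcerKind],
    participant_index: int,
    seed: int,
) -> SessionSchedule:
    """Behavioral-choice session; green/red button sides counterbalanced by participant parity."""
    rng = np.random.default_rng(seed)
    side = "left" if participant_index % 2 == 0 else "right"
    trials = _layout_trials(config, pairing, rng, button_green_side=side)
    return SessionSchedule(
        trials=trials, config=config, pairing=dict(pairing), seed=seed, task="choice"
    )
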