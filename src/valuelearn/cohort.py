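"""Synthetic study cohorts with a planted 2x2 learn-expression x use mixture.

Every participant shares the same learning rate (the group value 0.2), but
phenotypes differ in how learning is *expressed*: the rating gain
(vas_gain) governs the evidence of learning visible in the conditioning
task, and the choice inverse temperature (beta_choice) governs how sharply
learned value drives approach/avoid behavior. Crossing low/high bands of
the two gains plants the four HH/HL/LH/LL subgroups that the clustering
pipeline is expected to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .agents import (
    AgentParams,
    generate_vas_ratings,
    simulate_choice_session,
    simulate_conditioning_session,
    simulate_ibi_series,
    simulate_recall,
)
from .design import (
    DEFAULT_CUE_IDS,
    DesignConfig,
    ReinforcerKind,
    assign_pairings,
    build_latin_square,
    make_choice_schedule,
    make_conditioning_schedule,
)

__all__ = [
    "PhenotypeSpec",
    "CohortDataset",
    "DatasetValidationError",
    "default_phenotypes",
    "sample_phenotype_labels",
    "sample_cohort",
    "write_dataset",
    "read_dataset",
]

REQUIRED_TABLES = (
    "participants",
    "conditioning_trials",
    "choice_trials",
    "ratings",
    "recall",
    "beats",
)


class DatasetValidationError(ValueError):
    """A table failed schema or invariant checks; the message names it."""


@dataclass(frozen=True)
class PhenotypeSpec:
    """One cell of the planted mixture.

    Parameter bands are (low, high) tuples sampled uniformly; degenerate
    bands pin the parameter. 'high' expression bands must sit strictly
    above 'low' bands across the phenotype set.
    """

    label: str  # HH, HL, LH, LL
    weight: float
    alpha_band: tuple[float, float] = (0.2, 0.2)
    vas_gain_band: tuple[float, float] = (30.0, 30.0)
    beta_choice_band: tuple[float, float] = (6.0, 6.0)


def default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    """Equal-weight 2x2 mixture: vas_gain in {2, 30}, beta_choice in {0.3, 6}.

    First letter = learning expression (rating gain), second = use
    (choice inverse temperature).
    """
    lo_g, hi_g = (2.0, 2.0), (30.0, 30.0)
    lo_b, hi_b = (0.3, 0.3), (6.0, 6.0)
    return (
        PhenotypeSpec("HH", 0.25, vas_gain_band=hi_g, beta_choice_band=hi_b),
        PhenotypeSpec("HL", 0.25, vas_gain_band=hi_g, beta_choice_band=lo_b),
        PhenotypeSpec("LH", 0.25, vas_gain_band=lo_g, beta_choice_band=hi_b),
        PhenotypeSpec("LL", 0.25, vas_gain_band=lo_g, beta_choice_band=lo_b),
    )


@dataclass
class CohortDataset:
    """All tidy tables of one simulated study plus ground truth and manifest."""

    participants: pd.DataFrame
    conditioning_trials: pd.DataFrame
    choice_trials: pd.DataFrame
    ratings: pd.DataFrame
    recall: pd.DataFrame
    beats: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _sample_nuisance(rng: np.random.Generator) -> dict:
    # Plausible ranges for 8-9-year-olds: simple-RT baselines around 600 ms,
    # resting heart rate near 75 bpm (IBI ~ 800 ms).
    rt_base = rng.uniform(550.0, 700.0)
    return {
        "rt_base_ms": rt_base,
        "rt_gain_ms": rng.uniform(250.0, 350.0),
        "rt_sd_ms": rng.uniform(50.0, 80.0),
        "vas_sd": rng.uniform(5.0, 10.0),
        "p_recall": rng.uniform(0.8, 0.95),
        "ibi_base_ms": rng.uniform(700.0, 900.0),
        "ibi_react_ms": 50.0,
        "ibi_sd_ms": 20.0,
    }


def _sample_agent(spec: PhenotypeSpec, rng: np.random.Generator) -> AgentParams:
    return AgentParams(
        alpha=rng.uniform(*spec.alpha_band),
        vas_gain=rng.uniform(*spec.vas_gain_band),
        beta_choice=rng.uniform(*spec.beta_choice_band),
        **_sample_nuisance(rng),
    )


def sample_phenotype_labels(
    n: int,
    phenotypes: Sequence[PhenotypeSpec],
    seed_seq: np.random.SeedSequence,
) -> np.ndarray:
    """Indices into `phenotypes` drawn from the mixture weights."""
    weights = np.array([p.weight for p in phenotypes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"phenotype weights must sum to 1, got {weights.sum()}")
    rng = np.random.default_rng(seed_seq)
    return rng.choice(len(phenotypes), size=n, p=weights)


def sample_cohort(
    n: int = 72,
    phenotypes: Sequence[PhenotypeSpec] = None,
    config: DesignConfig = None,
    seed: int = 0,
    simulate_beats: bool = True,
) -> CohortDataset:
    """Simulate a full study: conditioning, ratings, choice, recall, IBI.

    Per-participant randomness is drawn from SeedSequence(seed).spawn(n),
    so cohorts are reproducible and participants independent.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    phenotypes = tuple(phenotypes) if phenotypes is not None else default_phenotypes()
    config = config if config is not None else DesignConfig()

    master = np.random.SeedSequence(seed)
    labels_idx = sample_phenotype_labels(n, phenotypes, master.spawn(1)[0])
    square = build_latin_square(config.n_conditions)
    conditions = tuple(ReinforcerKind)
    cue_ids = DEFAULT_CUE_IDS[: config.n_conditions]

    part_rows = []
    cond_tables, choice_tables, rating_tables, recall_tables, beat_rows = [], [], [], [], []
    for i, ss in enumerate(master.spawn(n + 1)[1:]):
        rng = np.random.default_rng(ss)
        spec = phenotypes[labels_idx[i]]
        agent = _sample_agent(spec, rng)
        pid = f"s{i:03d}"
        pairing = assign_pairings(i, square, cue_ids, conditions)

        cond_sched = make_conditioning_schedule(config, pairing, seed=int(rng.integers(2**31)))
        trials, trace = simulate_conditioning_session(agent, cond_sched, rng)
        trials.insert(0, "participant_id", pid)
        cond_tables.append(trials)

        ratings = generate_vas_ratings(agent, trace.final, pairing, rng)
        ratings.insert(0, "participant_id", pid)
        rating_tables.append(ratings)

        choice_sched = make_choice_schedule(
            config, pairing, participant_index=i, seed=int(rng.integers(2**31))
        )
        choices = simulate_choice_session(agent, choice_sched, trace.final, rng)
        choices.insert(0, "participant_id", pid)
        choice_tables.append(choices)

        recall = simulate_recall(agent, pairing, rng, block_order=i)
        recall.insert(0, "participant_id", pid)
        recall_tables.append(recall)

        if simulate_beats:
            beats = simulate_ibi_series(agent, cond_sched, rng)
            beat_rows.append(
                pd.DataFrame({"participant_id": pid, "beat_time_ms": beats})
            )

        row = {
            "participant_id": pid,
            "phenotype": spec.label,
            "alpha": agent.alpha,
            "vas_gain": agent.vas_gain,
            "beta_choice": agent.beta_choice,
            "rt_base_ms": agent.rt_base_ms,
            "rt_gain_ms": agent.rt_gain_ms,
            "rt_sd_ms": agent.rt_sd_ms,
            "vas_sd": agent.vas_sd,
            "p_recall": agent.p_recall,
            "ibi_base_ms": agent.ibi_base_ms,
            "ibi_react_ms": agent.ibi_react_ms,
            "ibi_sd_ms": agent.ibi_sd_ms,
        }
        part_rows.append(row)

    manifest = {
        "n": n,
        "seed": seed,
        "phenotypes": [
            {
                "label": p.label,
                "weight": p.weight,
                "alpha_band": list(p.alpha_band),
                "vas_gain_band": list(p.vas_gain_band),
                "beta_choice_band": list(p.beta_choice_band),
            }
            for p in phenotypes
        ],
        "design": {
            "n_conditions": config.n_conditions,
            "trials_per_condition": config.trials_per_condition,
            "p_reinforce": config.p_reinforce,
            "cue_duration_s": config.cue_duration_s,
            "delay_s": config.delay_s,
            "outcome_duration_s": config.outcome_duration_s,
            "iti_min_s": config.iti_range_s[0],
            "iti_max_s": config.iti_range_s[1],
            "exact_ratio": config.exact_ratio,
        },
        "rng": "numpy PCG64 via SeedSequence(seed).spawn per participant",
    }
    return CohortDataset(
        participants=pd.DataFrame(part_rows),
        conditioning_trials=pd.concat(cond_tables, ignore_index=True),
        choice_trials=pd.concat(choice_tables, ignore_index=True),
        ratings=pd.concat(rating_tables, ignore_index=True),
        recall=pd.concat(recall_tables, ignore_index=True),
        beats=(
            pd.concat(beat_rows, ignore_index=True)
            if beat_rows
            else pd.DataFrame(columns=["participant_id", "beat_time_ms"])
        ),
        manifest=manifest,
    )


def write_dataset(dataset: CohortDataset, directory) -> list[Path]:
    """Write all tables as CSV plus a YAML manifest; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in REQUIRED_TABLES:
        path = directory / f"{name}.csv"
        dataset.table(name).to_csv(path, index=False)
        written.append(path)
    mpath = directory / "manifest.yaml"
    with open(mpath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataset.manifest, fh, sort_keys=False)
    written.append(mpath)
    return written


_REQUIRED_COLUMNS = {
    "participants": {"participant_id", "phenotype", "alpha", "vas_gain", "beta_choice"},
    "conditioning_trials": {
        "participant_id",
        "trial_index",
        "condition",
        "cue_id",
        "outcome",
        "rt_ms",
    },
    "choice_trials": {"participant_id", "trial_index", "condition", "cue_id", "approach"},
    "ratings": {"participant_id", "cue_id", "condition", "pre_rating", "post_rating"},
    "recall": {"participant_id", "block", "prompt", "correct_option", "response", "correct"},
    "beats": {"participant_id", "beat_time_ms"},
}


def _validate(dataset: CohortDataset) -> None:
    for name in REQUIRED_TABLES:
        df = dataset.table(name)
        if name != "beats" and df.empty:
            raise DatasetValidationError(f"missing required table: {name} is empty")
        missing = _REQUIRED_COLUMNS[name] - set(df.columns)
        if missing:
            raise DatasetValidationError(f"table {name} lacks columns {sorted(missing)}")

    ids = set(dataset.participants["participant_id"])
    for name in ("conditioning_trials", "choice_trials", "ratings", "recall"):
        extra = set(dataset.table(name)["participant_id"]) - ids
        if extra:
            raise DatasetValidationError(
                f"table {name} has unknown participant ids: {sorted(extra)[:5]}"
            )

    r = dataset.ratings
    for col in ("pre_rating", "post_rating"):
        bad = r.index[(r[col] < 0) | (r[col] > 100)]
        if len(bad):
            raise DatasetValidationError(
                f"table ratings: {col} outside [0, 100] at rows {list(bad[:5])}"
            )

    # cue->condition must be a bijection within each participant
    for pid, grp in dataset.conditioning_trials.groupby("participant_id"):
        pairs = grp[["cue_id", "condition"]].drop_duplicates()
        if pairs["cue_id"].duplicated().any() or pairs["condition"].duplicated().any():
            raise DatasetValidationError(
                f"table conditioning_trials: non-bijective cue-condition pairing for {pid}"
            )


def read_dataset(directory) -> CohortDataset:
    """Load and validate a dataset directory written by write_dataset."""
    directory = Path(directory)
    tables = {}
    for name in REQUIRED_TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise DatasetValidationError(f"missing required table: {name}.csv")
        tables[name] = pd.read_csv(path)
    mpath = directory / "manifest.yaml"
    manifest = {}
    if mpath.exists():
        with open(mpath, encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh) or {}
    ds = CohortDataset(manifest=manifest, **tables)
    _validate(ds)
    return ds
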