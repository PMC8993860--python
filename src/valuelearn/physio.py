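"""Cardiac inter-beat-interval processing.

Beat timestamps are converted to an instantaneous IBI series (the interval
ending at each beat), screened for physiologically implausible values,
linearly interpolated onto an equal-interval 4 Hz grid, and averaged over
per-trial anticipation and reinforcer epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SessionSchedule

__all__ = [
    "IBISeries",
    "resample_ibi",
    "epoch_means",
    "epoch_means_from_frame",
    "ARTIFACT_BOUNDS_MS",
]

#: beats implying an IBI outside these bounds are treated as artifacts
ARTIFACT_BOUNDS_MS = (300.0, 2000.0)


@dataclass
class IBISeries:
    """Equal-interval IBI series: timestamps (s) at a fixed rate, values in ms."""

    timestamps_s: np.ndarray
    ibi_ms: np.ndarray
    rate_hz: float = 4.0
    n_artifacts: int = 0

    def __post_init__(self) -> None:
        step = 1.0 / self.rate_hz
        if len(self.timestamps_s) > 1:
            diffs = np.diff(self.timestamps_s)
            if not np.allclose(diffs, step):
                raise ValueError("timestamps must advance by exactly 1/rate_hz")
        if np.any(self.ibi_ms <= 0):
            raise ValueError("ibi_ms must be positive")


def resample_ibi(beat_times_ms: np.ndarray, rate_hz: float = 4.0) -> IBISeries:
    """Interpolate instantaneous IBIs onto an equal-interval grid.

    The IBI ending at beat k (t_k - t_{k-1}) is placed at t_k; samples
    outside the 300-2000 ms plausibility bounds are flagged as artifacts
    and excluded before linear interpolation. The grid spans the first to
    the last valid IBI timestamp; no extrapolation is performed.
    """
    t = np.asarray(beat_times_ms, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 beat times")
    if np.any(np.diff(t) <= 0):
        raise ValueError("beat times must be strictly increasing")
    ibis = np.diff(t)
    loc = t[1:]
    lo, hi = ARTIFACT_BOUNDS_MS
    valid = (ibis >= lo) & (ibis <= hi)
    n_artifacts = int((~valid).sum())
    if valid.sum() < 2:
        raise ValueError("fewer than 2 plausible IBIs after artifact screening")
    ibis, loc = ibis[valid], loc[valid]

    step_s = 1.0 / rate_hz
    start_s = loc[0] / 1000.0
    span_s = (loc[-1] - loc[0]) / 1000.0
    n = int(np.floor(span_s / step_s + 1e-9)) + 1
    grid_s = start_s + np.arange(n) * step_s
    values = np.interp(grid_s * 1000.0, loc, ibis)
    return IBISeries(timestamps_s=grid_s, ibi_ms=values, rate_hz=rate_hz, n_artifacts=n_artifacts)


def epoch_means(series: IBISeries, schedule: SessionSchedule) -> pd.DataFrame:
    """Mean IBI per trial epoch.

    ANTICIPATION covers [cue_onset, cue_onset + delay) — the 6 s window
    between cue presentation and reinforcer presentation. REINFORCER covers
    [outcome_onset, next cue onset): the outcome display plus the jittered
    ITI (4-7 s with the default design). Windows are half-open so grid
    samples are never double-counted; epochs with fewer than 2 samples are
    flagged and epochs outside the series span get a missing mean.
    """
    trials = schedule.to_frame()
    return epoch_means_from_frame(
        series,
        trials,
        delay_s=schedule.config.delay_s,
        outcome_duration_s=schedule.config.outcome_duration_s,
    )


def epoch_means_from_frame(
    series: IBISeries,
    trials: pd.DataFrame,
    delay_s: float = 6.0,
    outcome_duration_s: float = 1.5,
) -> pd.DataFrame:
    """epoch_means for a tidy trial table (trial_index, condition, onsets, iti_s)."""
    ts = series.timestamps_s
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    rows = []
    n = len(trials)
    for i, trial in trials.iterrows():
        if i + 1 < n:
            next_cue = float(trials.loc[i + 1, "cue_onset_s"])
        else:
            next_cue = float(trial["outcome_onset_s"]) + outcome_duration_s + float(trial["iti_s"])
        windows = (
            ("anticipation", float(trial["cue_onset_s"]), float(trial["cue_onset_s"]) + delay_s),
            ("reinforcer", float(trial["outcome_onset_s"]), next_cue),
        )
        for kind, start, end in windows:
            mask = (ts >= start) & (ts < end)
            n_samples = int(mask.sum())
            mean = float(series.ibi_ms[mask].mean()) if n_samples else float("nan")
            rows.append(
                {
                    "trial_index": int(trial["trial_index"]),
                    "condition": str(trial["condition"]),
                    "window": kind,
                    "start_s": start,
                    "end_s": end,
                    "mean_ibi_ms": mean,
                    "n_samples": n_samples,
                    "flagged": n_samples < 2,
                }
            )
    return pd.DataFrame(rows)
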