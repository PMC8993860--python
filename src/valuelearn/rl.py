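"""Learning-rate estimation from conditioning-task reaction times.

For each candidate learning rate alpha on a fixed grid, the realized
outcome sequence is replayed through the delta rule to produce a per-trial
salience predictor S_t = |V_t| (value before the trial's update). RT is
regressed on S_t by ordinary least squares and the residual sum of squares
recorded; the fitted alpha is the grid argmin. Group-level pooling sums
SSE profiles across identifiable subjects (fixed-effects pooling) and
takes the argmin of the summed profile; the median of per-subject
estimates is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .design import ReinforcerKind, Outcome

__all__ = [
    "FitResult",
    "GroupFit",
    "DEFAULT_ALPHA_GRID",
    "predict_salience_series",
    "salience_profile",
    "fit_subject",
    "group_learning_rate",
    "fit_cohort",
]

#: alpha in {0.01, 0.02, ..., 1.00}
DEFAULT_ALPHA_GRID = np.round(np.arange(0.01, 1.0001, 0.01), 2)

FLAT_TOL = 1e-6  # profile declared flat when (max-min)/min < FLAT_TOL


@dataclass
class FitResult:
    subject_id: str
    alpha_hat: float
    beta0_hat: float  # intercept, ms
    beta1_hat: float  # ms per unit salience (negative = speeding)
    sigma_hat: float  # residual SD at alpha_hat, ms
    grid: np.ndarray
    sse_profile: np.ndarray
    identifiable: bool
    n_trials_used: int


@dataclass
class GroupFit:
    pooled_alpha: float
    median_alpha: float
    n_identifiable: int
    grid: np.ndarray
    sse_total: np.ndarray


def _reward_codes(trials: pd.DataFrame) -> np.ndarray:
    valence = trials["condition"].map(lambda c: ReinforcerKind(c).valence).to_numpy(float)
    reinforced = (trials["outcome"] == Outcome.REINFORCER.value).to_numpy()
    return np.where(reinforced, valence, 0.0)


def predict_salience_series(
    alpha: float,
    trials: pd.DataFrame,
    cue_ids: Optional[Iterable[str]] = None,
) -> np.ndarray:
    """Deterministic forward pass: S_t = |V_t(cue_t)| before trial t's update."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return salience_profile(trials, np.array([alpha]), cue_ids)[:, 0]


def salience_profile(
    trials: pd.DataFrame,
    grid: np.ndarray,
    cue_ids: Optional[Iterable[str]] = None,
) -> np.ndarray:
    """Salience series for every grid alpha at once; shape (n_trials, n_alpha)."""
    grid = np.asarray(grid, dtype=float)
    cues = pd.unique(trials["cue_id"])
    if cue_ids is not None:
        known = set(cue_ids)
        unknown = [c for c in cues if c not in known]
        if unknown:
            raise KeyError(f"unknown cue id(s): {unknown}")
    idx = {c: k for k, c in enumerate(cues)}
    cue_idx = trials["cue_id"].map(idx).to_numpy()
    r = _reward_codes(trials)

    v = np.zeros((len(cues), len(grid)))
    s = np.empty((len(trials), len(grid)))
    for t in range(len(trials)):
        ci = cue_idx[t]
        s[t] = np.abs(v[ci])
        v[ci] += grid * (r[t] - v[ci])
    return s


def _ols_sse(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form simple regression of y on each column of x.

    Returns (intercepts, slopes, sse) over columns. Zero-variance columns
    get slope 0 and SSE equal to the total sum of squares of y.
    """
    n = len(y)
    ybar = y.mean()
    xbar = x.mean(axis=0)
    xc = x - xbar
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ (y - ybar)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    intercept = ybar - slope * xbar
    sst = ((y - ybar) ** 2).sum()
    sse = sst - slope * sxy
    return intercept, slope, np.maximum(sse, 0.0)


def fit_subject(
    trials: pd.DataFrame,
    grid: np.ndarray = DEFAULT_ALPHA_GRID,
    subject_id: str = "",
    min_trials: int = 10,
) -> FitResult:
    """Grid-profile fit of one subject's conditioning RTs.

    Trials with missing RT (no keypress within the response window) are
    excluded from the regression but still drive value updates, since the
    outcome was displayed regardless of the response.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid must have >= 2 points within [0, 1]")
    rt = trials["rt_ms"].to_numpy(float)
    valid = np.isfinite(rt)
    if valid.sum() == 0:
        raise ValueError("all RTs missing")
    if valid.sum() < min_trials:
        raise ValueError(f"need >= {min_trials} valid RT trials, got {int(valid.sum())}")

    s = salience_profile(trials, grid)[valid]
    y = rt[valid]
    intercept, slope, sse = _ols_sse(s, y)

    lo, hi = float(sse.min()), float(sse.max())
    flat = (hi - lo) <= FLAT_TOL * max(lo, 1e-12)
    if flat:
        k = len(grid) // 2  # midpoint, flagged unidentifiable
        identifiable = False
    else:
        k = int(np.argmin(sse))  # first (= smallest) alpha on ties
        identifiable = True
    n_used = int(valid.sum())
    dof = max(n_used - 2, 1)
    return FitResult(
        subject_id=subject_id,
        alpha_hat=float(grid[k]),
        beta0_hat=float(intercept[k]),
        beta1_hat=float(slope[k]),
        sigma_hat=float(np.sqrt(sse[k] / dof)),
        grid=grid,
        sse_profile=sse,
        identifiable=identifiable,
        n_trials_used=n_used,
    )


def group_learning_rate(fits: Sequence[FitResult]) -> GroupFit:
    """Pool subjects: argmin of summed SSE profiles over identifiable fits."""
    usable = [f for f in fits if f.identifiable]
    if not usable:
        raise ValueError("no identifiable fits to pool")
    grid = usable[0].grid
    for f in usable[1:]:
        if not np.array_equal(f.grid, grid):
            raise ValueError("fits were computed on different grids")
    total = np.sum([f.sse_profile for f in usable], axis=0)
    k = int(np.argmin(total))
    return GroupFit(
        pooled_alpha=float(grid[k]),
        median_alpha=float(np.median([f.alpha_hat for f in usable])),
        n_identifiable=len(usable),
        grid=grid,
        sse_total=total,
    )


def fit_cohort(
    conditioning_trials: pd.DataFrame,
    grid: np.ndarray = DEFAULT_ALPHA_GRID,
) -> tuple[list[FitResult], GroupFit]:
    """Fit every participant in a tidy conditioning-trials table and pool."""
    fits = [
        fit_subject(grp.sort_values("trial_index"), grid, subject_id=str(pid))
        for pid, grp in conditioning_trials.groupby("participant_id", sort=True)
    ]
    return fits, group_learning_rate(fits)


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [f.subject_id for f in fits],
            "alpha_hat": [f.alpha_hat for f in fits],
            "beta0_hat": [f.beta0_hat for f in fits],
            "beta1_hat": [f.beta1_hat for f in fits],
            "sigma_hat": [f.sigma_hat for f in fits],
            "sse_min": [float(f.sse_profile.min()) for f in fits],
            "identifiable": [f.identifiable for f in fits],
            "n_trials_used": [f.n_trials_used for f in fits],
        }
    )
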