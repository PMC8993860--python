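"""Analysis chain: learn/use features, clustering, recall, concordance.

Learning on the conditioning task is measured as the unstandardized
residualized change in 0-100 valence ratings (post minus pre, with the
component linearly predictable from pre regressed out). Use of learned
information is the fraction of expected responses — approach appetitive,
avoid aversive — over the first few choice trials, before within-task
re-learning can blur the dissociation. The two features, standardized
within condition, feed a per-condition k-means that labels clusters by
centroid quadrant (high/low learning x high/low use).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .design import NON_NEUTRAL_CONDITIONS, ReinforcerKind

__all__ = [
    "ClusterResult",
    "ConcordanceResult",
    "residualized_change",
    "expected_use_score",
    "build_features",
    "cluster_learn_use",
    "select_k",
    "score_recall",
    "concordance",
    "permutation_conditioning_test",
]

QUADRANT_LABELS = ("HH", "HL", "LH", "LL")
NO_STRUCTURE_SILHOUETTE = 0.25


def residualized_change(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Unstandardized residualized change scores.

    change = post - pre is regressed on pre (simple OLS with intercept);
    the residuals are returned. They sum to zero and are uncorrelated with
    pre by the normal equations. With zero variance in pre the regression
    is degenerate: centered change is returned with a RuntimeWarning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D vectors")
    if len(pre) < 3:
        raise ValueError("need at least 3 paired ratings")
    if np.any((pre < 0) | (pre > 100) | (post < 0) | (post > 100)):
        raise ValueError("ratings must lie in [0, 100]")
    change = post - pre
    if np.var(pre) == 0:
        warnings.warn(
            "pre-ratings have zero variance; returning centered change",
            RuntimeWarning,
            stacklevel=2,
        )
        return change - change.mean()
    fit = stats.linregress(pre, change)
    return change - (fit.intercept + fit.slope * pre)


def expected_use_score(
    choices: pd.DataFrame,
    condition: ReinforcerKind | str,
    first_k: int = 5,
    scope: str = "per_condition",
) -> float:
    """Fraction of expected responses for one subject and condition.

    Expected response = approach for appetitive conditions (+1 valence),
    avoid for aversive (-1). scope="per_condition" uses the condition's
    first `first_k` trials; scope="whole_task" uses the condition's trials
    falling within the first `first_k` trials of the entire task (NaN when
    none qualify).
    """
    condition = ReinforcerKind(condition)
    if condition.valence == 0:
        raise ValueError("no expected response is defined for the neutral condition")
    if scope not in ("per_condition", "whole_task"):
        raise ValueError(f"unknown scope {scope!r}")
    df = choices.sort_values("trial_index")
    if scope == "whole_task":
        df = df.head(first_k)
        df = df[df["condition"] == condition.value]
        if df.empty:
            return float("nan")
    else:
        df = df[df["condition"] == condition.value].head(first_k)
        if len(df) < first_k:
            raise ValueError(
                f"need {first_k} trials of {condition.value}, found {len(df)}"
            )
    approach = df["approach"].astype(bool).to_numpy()
    expected = approach if condition.valence > 0 else ~approach
    return float(expected.mean())


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def build_features(
    ratings: pd.DataFrame,
    choices: pd.DataFrame,
    condition: ReinforcerKind | str,
    sign_align: bool = True,
    first_k: int = 5,
    scope: str = "per_condition",
) -> pd.DataFrame:
    """Per-subject learn/use features for one non-neutral condition.

    learn_score: residualized rating change, multiplied by the condition's
    valence when sign_align so that larger always means more learning
    (aversive conditions express learning as more *negative* change).
    use_score: expected_use_score. Both are z-standardized within the
    condition into learn_z / use_z.
    """
    condition = ReinforcerKind(condition)
    r = ratings[ratings["condition"] == condition.value].sort_values("participant_id")
    subj_r = list(r["participant_id"])
    subj_c = set(choices["participant_id"])
    missing = sorted(set(subj_r) ^ subj_c)
    if missing:
        raise ValueError(f"subjects missing from one table: {missing}")

    resid = residualized_change(r["pre_rating"].to_numpy(), r["post_rating"].to_numpy())
    learn = resid * condition.valence if sign_align else resid
    use = np.array(
        [
            expected_use_score(
                choices[choices["participant_id"] == pid], condition, first_k, scope
            )
            for pid in subj_r
        ]
    )
    return pd.DataFrame(
        {
            "participant_id": subj_r,
            "condition": condition.value,
            "learn_score": learn,
            "use_score": use,
            "learn_z": _zscore(learn),
            "use_z": _zscore(use),
        }
    )


@dataclass
class ClusterResult:
    condition: str
    k: int
    assignments: pd.Series  # participant_id -> cluster index
    centroids: np.ndarray  # (k, 2) in standardized (learn_z, use_z) space
    quadrant_labels: dict[int, str]
    inertia: float
    seed: int
    restarts: int
    quadrants_complete: bool = False
    ari_vs_truth: Optional[float] = None


def _quadrant(learn: float, use: float) -> str:
    if learn >= 0:
        return "HH" if use >= 0 else "HL"
    return "LH" if use >= 0 else "LL"


def cluster_learn_use(
    features: pd.DataFrame,
    k: int = 4,
    restarts: int = 10,
    seed: int = 0,
    truth: Optional[Mapping[str, str]] = None,
) -> ClusterResult:
    """k-means on standardized learn x use, best of `restarts` random inits.

    Clusters are labeled by the quadrant of their centroid; with k=4 and a
    genuine 2x2 structure the labels cover all four quadrants
    (quadrants_complete). When ground-truth phenotype labels are supplied
    the adjusted Rand index against them is recorded.
    """
    X = features[["learn_z", "use_z"]].to_numpy()
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} subjects")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct points")
    km = KMeans(n_clusters=k, init="random", n_init=restarts, algorithm="lloyd", random_state=seed)
    labels = km.fit_predict(X)
    quadrants = {c: _quadrant(*km.cluster_centers_[c]) for c in range(k)}
    ari = None
    if truth is not None:
        true_labels = [truth[pid] for pid in features["participant_id"]]
        ari = float(adjusted_rand_score(true_labels, labels))
    return ClusterResult(
        condition=str(features["condition"].iloc[0]) if "condition" in features else "",
        k=k,
        assignments=pd.Series(labels, index=features["participant_id"], name="cluster"),
        centroids=km.cluster_centers_,
        quadrant_labels=quadrants,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
        quadrants_complete=(set(quadrants.values()) == set(QUADRANT_LABELS)),
        ari_vs_truth=ari,
    )


def select_k(
    features: pd.DataFrame,
    k_range: Sequence[int] = range(2, 7),
    seed: int = 0,
    restarts: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Mean-silhouette model selection over k; flags absence of structure."""
    X = features[["learn_z", "use_z"]].to_numpy()
    rows = []
    for k in k_range:
        if not 2 <= k <= len(X) - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        km = KMeans(
            n_clusters=k, init="random", n_init=restarts, algorithm="lloyd", random_state=seed
        )
        labels = km.fit_predict(X)
        sil = float(silhouette_score(X, labels)) if len(set(labels)) > 1 else float("nan")
        rows.append({"k": k, "silhouette": sil, "inertia": float(km.inertia_)})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["silhouette"].idxmax(), "k"])
    table["no_structure"] = table["silhouette"].max() < NO_STRUCTURE_SILHOUETTE
    return best, table


def score_recall(recall: pd.DataFrame) -> pd.DataFrame:
    """Per-subject accuracy per recall block and overall; chance = 0.25."""
    if not set(recall["correct"].astype(int).unique()) <= {0, 1}:
        raise ValueError("malformed correct column")
    per_block = (
        recall.groupby(["participant_id", "block"])["correct"].mean().unstack()
    )
    per_block["overall"] = recall.groupby("participant_id")["correct"].mean()
    per_block["chance"] = 0.25
    return per_block.reset_index()


@dataclass
class ConcordanceResult:
    table: np.ndarray  # 2x2: rows learn (high, low), cols use (high, low)
    kappa: float
    chi2: float
    degenerate: bool


def _dichotomize(x: np.ndarray, split: str, seed: int = 0) -> np.ndarray:
    """True = high. Median split sends values at the median to low."""
    if split == "median":
        return x > np.median(x)
    if split == "cluster":
        km = KMeans(n_clusters=2, init="random", n_init=10, algorithm="lloyd", random_state=seed)
        lab = km.fit_predict(x.reshape(-1, 1))
        hi = int(np.argmax(km.cluster_centers_.ravel()))
        return lab == hi
    raise ValueError(f"unknown split {split!r}")


def concordance(features: pd.DataFrame, split: str = "median", seed: int = 0) -> ConcordanceResult:
    """Cross-tabulate dichotomized learn vs use; Cohen's kappa and chi-square."""
    if len(features) < 4:
        raise ValueError("need at least 4 subjects")
    learn_hi = _dichotomize(features["learn_z"].to_numpy(), split, seed)
    use_hi = _dichotomize(features["use_z"].to_numpy(), split, seed)
    table = np.array(
        [
            [(learn_hi & use_hi).sum(), (learn_hi & ~use_hi).sum()],
            [(~learn_hi & use_hi).sum(), (~learn_hi & ~use_hi).sum()],
        ],
        dtype=float,
    )
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    degenerate = bool(np.any(row == 0) or np.any(col == 0))
    if degenerate:
        kappa = float("nan")
        chi2 = float("nan")
    else:
        p_o = (table[0, 0] + table[1, 1]) / n
        p_e = (row[0] * col[0] + row[1] * col[1]) / n**2
        kappa = float((p_o - p_e) / (1 - p_e)) if p_e < 1 else 1.0
        chi2 = float(stats.chi2_contingency(table, correction=False)[0])
    return ConcordanceResult(table=table.astype(int), kappa=kappa, chi2=chi2, degenerate=degenerate)


def permutation_conditioning_test(
    pre: np.ndarray,
    post: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Sign-flip permutation test of the mean rating change.

    Returns (p_value, observed mean change). The null randomly flips the
    sign of each subject's change; two-sided
    p = (1 + #{|perm| >= |obs|}) / (n_perm + 1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or len(pre) < 5:
        raise ValueError("need paired vectors with n >= 5")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    d = post - pre
    obs = float(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    perm = (signs * d).mean(axis=1)
    p = (1.0 + np.sum(np.abs(perm) >= abs(obs) - 1e-12)) / (n_perm + 1.0)
    return float(p), obs
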