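import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from valuelearn.analysis import (
    build_features,
    cluster_learn_use,
    concordance,
    expected_use_score,
    permutation_conditioning_test,
    residualized_change,
    score_recall,
    select_k,
)
from valuelearn.design import ReinforcerKind


class TestResidualizedChange:
    def test_zero_change_gives_zero_residuals(self):
        pre = np.array([10.0, 50.0, 90.0, 30.0])
        assert np.allclose(residualized_change(pre, pre), 0.0)

    def test_constant_pre_returns_centered_change(self):
        pre = np.full(5, 50.0)
        post = np.array([40.0, 60.0, 50.0, 55.0, 45.0])
        with pytest.warns(RuntimeWarning, match="zero variance"):
            r = residualized_change(pre, post)
        assert np.allclose(r, (post - pre) - (post - pre).mean())

    def test_input_validation(self):
        with pytest.raises(ValueError):
            residualized_change(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            residualized_change(np.array([0.0, 50.0, 101.0]), np.array([0.0, 50.0, 90.0]))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_normal_equations_hold(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 40)
        pre = rng.uniform(1, 99, n)
        post = np.clip(pre + rng.normal(0, 10, n), 0, 100)
        if np.var(pre) == 0:
            return
        r = residualized_change(pre, post)
        assert abs(r.sum()) < 1e-9
        assert abs(np.dot(r - r.mean(), pre - pre.mean())) < 1e-7


def _choices(approaches, condition="points"):
    return pd.DataFrame(
        {
            "trial_index": range(len(approaches)),
            "condition": condition,
            "approach": approaches,
        }
    )


class TestExpectedUse:
    def test_perfect_and_anti_expected(self):
        assert expected_use_score(_choices([True] * 5), "points") == 1.0
        assert expected_use_score(_choices([True] * 5, "aversive_noise"), "aversive_noise") == 0.0

    def test_counting(self):
        assert expected_use_score(_choices([True, True, True, False, False]), "points") == 0.6

    def test_neutral_rejected(self):
        with pytest.raises(ValueError, match="neutral"):
            expected_use_score(_choices([True] * 5, "neutral"), "neutral")

    def test_whole_task_scope_windows_by_task_position(self):
        df = pd.DataFrame(
            {
                "trial_index": range(6),
                "condition": ["points", "neutral", "points", "neutral", "points", "points"],
                "approach": [True, True, False, True, True, True],
            }
        )
        # first 5 task trials contain 3 points trials: approach on 2 of 3
        assert expected_use_score(df, "points", first_k=5, scope="whole_task") == pytest.approx(2 / 3)


class TestBuildFeatures:
    def test_sign_alignment_by_valence(self, midsize_cohort):
        ds = midsize_cohort
        aligned = build_features(ds.ratings, ds.choice_trials, "aversive_noise", sign_align=True)
        raw = build_features(ds.ratings, ds.choice_trials, "aversive_noise", sign_align=False)
        assert np.allclose(aligned["learn_score"], -raw["learn_score"])
        app = build_features(ds.ratings, ds.choice_trials, "points", sign_align=True)
        app_raw = build_features(ds.ratings, ds.choice_trials, "points", sign_align=False)
        assert np.allclose(app["learn_score"], app_raw["learn_score"])

    def test_standardized_columns(self, midsize_cohort):
        f = build_features(midsize_cohort.ratings, midsize_cohort.choice_trials, "points")
        assert abs(f["learn_z"].mean()) < 1e-10
        assert f["learn_z"].std(ddof=1) == pytest.approx(1.0)
        assert abs(f["use_z"].mean()) < 1e-10
        assert f["use_z"].std(ddof=1) == pytest.approx(1.0)

    def test_missing_subject_reported(self, midsize_cohort):
        choices = midsize_cohort.choice_trials
        choices = choices[choices["participant_id"] != "s000"]
        with pytest.raises(ValueError, match="s000"):
            build_features(midsize_cohort.ratings, choices, "points")


def _blobs(centers, per=20, spread=0.15, seed=0, condition="points"):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(c, spread, (per, 2)) for c in centers])
    n = len(pts)
    return pd.DataFrame(
        {
            "participant_id": [f"s{i:03d}" for i in range(n)],
            "condition": condition,
            "learn_z": pts[:, 0],
            "use_z": pts[:, 1],
        }
    )


QUAD_CENTERS = [(1.5, 1.5), (1.5, -1.5), (-1.5, 1.5), (-1.5, -1.5)]
QUAD_NAMES = ["HH", "HL", "LH", "LL"]


class TestClustering:
    def test_planted_quadrants_recovered(self):
        hits = 0
        for seed in range(20):
            f = _blobs(QUAD_CENTERS, seed=seed)
            truth = {f.loc[i, "participant_id"]: QUAD_NAMES[i // 20] for i in range(80)}
            res = cluster_learn_use(f, k=4, restarts=10, seed=seed, truth=truth)
            # match clusters to truth via quadrant labels
            pred = res.assignments.map(res.quadrant_labels)
            agree = np.mean([pred[p] == truth[p] for p in pred.index])
            hits += agree >= 0.95
        assert hits >= 19

    def test_degenerate_distinct_points(self):
        pts = [(0.0, 0.0)] * 8 + [(3.0, 3.0), (-3.0, -3.0)]
        f = pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(10)],
                "condition": "points",
                "learn_z": [p[0] for p in pts],
                "use_z": [p[1] for p in pts],
            }
        )
        res = cluster_learn_use(f, k=3, restarts=20, seed=0)
        cents = {tuple(np.round(c, 6)) for c in res.centroids}
        assert (3.0, 3.0) in cents and (-3.0, -3.0) in cents

    def test_k_exceeding_subjects(self):
        with pytest.raises(ValueError):
            cluster_learn_use(_blobs(QUAD_CENTERS, per=1, spread=0.0), k=5)

    def test_too_few_distinct_points(self):
        f = _blobs([(0, 0)], per=10, spread=0.0)
        with pytest.raises(ValueError, match="distinct"):
            cluster_learn_use(f, k=4)

    def test_best_of_restarts_no_worse_than_single(self):
        f = _blobs(QUAD_CENTERS, seed=3)
        multi = cluster_learn_use(f, k=4, restarts=20, seed=0)
        single = cluster_learn_use(f, k=4, restarts=1, seed=0)
        assert multi.inertia <= single.inertia + 1e-9


class TestSelectK:
    def test_four_blobs_select_four(self):
        best, table = select_k(_blobs(QUAD_CENTERS, seed=1), range(2, 7), seed=1)
        assert best == 4
        assert not table["no_structure"].iloc[0]

    def test_two_blobs_select_two(self):
        best, _ = select_k(_blobs([(2, 2), (-2, -2)], per=30, seed=2), range(2, 6), seed=2)
        assert best == 2

    def test_single_blob_scores_below_planted_structure(self):
        # an unstructured cloud scores well under four separated blobs, and
        # the no-structure flag mirrors the 0.25 threshold on max silhouette
        _, null_tab = select_k(_blobs([(0, 0)], per=60, spread=1.0, seed=3), range(2, 6), seed=3)
        _, blob_tab = select_k(_blobs(QUAD_CENTERS, seed=3), range(2, 6), seed=3)
        assert null_tab["silhouette"].max() < blob_tab["silhouette"].max() - 0.2
        assert null_tab["no_structure"].iloc[0] == (null_tab["silhouette"].max() < 0.25)


class TestScoreRecall:
    def test_extremes(self):
        rec = pd.DataFrame(
            {
                "participant_id": ["a"] * 4 + ["b"] * 4,
                "block": ["shape_to_outcome", "outcome_to_shape"] * 4,
                "correct": [True] * 4 + [False] * 4,
            }
        )
        out = score_recall(rec).set_index("participant_id")
        assert out.loc["a", "overall"] == 1.0
        assert out.loc["b", "overall"] == 0.0
        assert (out["chance"] == 0.25).all()


def _features_from_counts(hh, hl, lh, ll):
    rows = []
    for n, (l, u) in zip(
        (hh, hl, lh, ll), [(1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0)]
    ):
        rows += [(l, u)] * n
    df = pd.DataFrame(rows, columns=["learn_z", "use_z"])
    df.insert(0, "participant_id", [f"s{i}" for i in range(len(df))])
    return df


class TestConcordance:
    def test_perfect_agreement(self):
        res = concordance(_features_from_counts(10, 0, 0, 10))
        assert res.kappa == pytest.approx(1.0)

    def test_hand_computed_half_kappa(self):
        # table [[30,10],[10,30]]: p_o=0.75, p_e=0.5 -> kappa=0.5
        res = concordance(_features_from_counts(30, 10, 10, 30))
        assert res.table.tolist() == [[30, 10], [10, 30]]
        assert res.kappa == pytest.approx(0.5)
        assert res.chi2 == pytest.approx(20.0)

    def test_pure_dissociation_is_maximally_negative(self):
        res = concordance(_features_from_counts(0, 20, 20, 0))
        assert res.kappa == pytest.approx(-1.0)

    def test_independence_gives_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(2000)],
                "learn_z": rng.normal(size=2000),
                "use_z": rng.normal(size=2000),
            }
        )
        assert abs(concordance(f).kappa) < 0.05

    def test_degenerate_margin_flagged(self):
        f = _features_from_counts(8, 0, 8, 0)  # everyone high use
        res = concordance(f)
        assert res.degenerate and np.isnan(res.kappa)

    def test_cluster_split(self):
        res = concordance(_features_from_counts(30, 10, 10, 30), split="cluster")
        assert res.kappa == pytest.approx(0.5)


class TestPermutationTest:
    def test_no_change_gives_p_one(self):
        pre = np.array([50.0, 40.0, 60.0, 55.0, 45.0])
        p, obs = permutation_conditioning_test(pre, pre, n_perm=500, seed=0)
        assert p == 1.0 and obs == 0.0

    def test_strong_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for rep in range(20):
            pre = rng.uniform(30, 70, 72)
            post = np.clip(pre + 15 + rng.normal(0, 5, 72), 0, 100)
            p, _ = permutation_conditioning_test(pre, post, n_perm=999, seed=rep)
            rejections += p < 0.01
        assert rejections == 20

    def test_small_n_perm_warns(self):
        pre = np.arange(5, dtype=float) + 40
        with pytest.warns(UserWarning):
            permutation_conditioning_test(pre, pre + 1, n_perm=50, seed=0)

    def test_requires_five_pairs(self):
        with pytest.raises(ValueError):
            permutation_conditioning_test(np.ones(3), np.ones(3))
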