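"""Trajectory scaling, stability screening, clustering, merging, labelling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import resptyper as rt
from resptyper.errors import (
    ConstantTrajectoryError,
    KTooLargeError,
    TooFewItemsError,
)
from resptyper.response_types import (
    ResponseTypeClassifier,
    build_trajectories,
    cluster_trajectories,
    merge_and_label,
    scale_trajectory,
    screen_stability,
    suggest_k,
)
from resptyper.simulate import archetype_template, scaled_templates

DAYS = (0, 4, 8, 16, 32)


class TestScaling:
    def test_hand_zscore(self):
        got = scale_trajectory([1, 2, 3, 4, 5])
        np.testing.assert_allclose(
            got, [-1.2649111, -0.6324555, 0.0, 0.6324555, 1.2649111], atol=1e-6)
        assert got.mean() == pytest.approx(0.0, abs=1e-12)
        assert got.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotence(self):
        v = scale_trajectory([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_allclose(scale_trajectory(v), v, atol=1e-12)

    def test_constant_raises(self):
        with pytest.raises(ConstantTrajectoryError):
            scale_trajectory([2.0] * 5)


class TestStabilityScreen:
    def test_constant_is_stable(self):
        assert screen_stability([5.0] * 5)

    @pytest.mark.parametrize("values,theta,expected", [
        ((100, 101, 99, 100, 100), 0.25, True),    # range 2 < 25
        ((100, 300, 100, 100, 100), 0.25, False),  # range 200 >= 25
    ])
    def test_range_vs_median_rule(self, values, theta, expected):
        assert screen_stability(values, theta) is expected


class TestClustering:
    def test_determinism_and_planted_recovery(self):
        rng = np.random.default_rng(0)
        templates = scaled_templates(DAYS).to_numpy()
        truth = np.repeat(np.arange(5), 30)
        X = templates[truth] + rng.normal(0, 0.1, size=(150, 5))
        l1, c1 = cluster_trajectories(X, k=5, nstart=25, seed=7)
        l2, _ = cluster_trajectories(X, k=5, nstart=25, seed=7)
        assert (l1 == l2).all()
        assert adjusted_rand_score(truth, l1) == 1.0

    def test_k_too_large(self):
        X = np.tile([[0.0, 1, 0, -1, 0]], (10, 1))
        with pytest.raises(KTooLargeError):
            cluster_trajectories(X, k=3)

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5))
        from sklearn.cluster import KMeans

        inertia1 = KMeans(6, n_init=1, random_state=0).fit(X).inertia_
        inertia25 = KMeans(6, n_init=25, random_state=0).fit(X).inertia_
        assert inertia25 <= inertia1 + 1e-9


class TestSuggestK:
    def test_silhouette_finds_three_planted_clusters(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 0.3, size=(30, 5)) for c in (0, 5, 10)])
        rep = suggest_k(X, kmax=8, nboot=20, nstart=10, seed=1)
        assert rep.silhouette_k == 3

    def test_gap_single_cluster(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 0.2, size=(40, 5))
        rep = suggest_k(X, kmax=6, nboot=20, nstart=10, seed=1)
        assert rep.gap_k == 1

    def test_wss_curve_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        rep = suggest_k(X, kmax=6, nboot=5, nstart=10, seed=0)
        diffs = rep.wss_curve.diff().dropna()
        assert (diffs <= 1e-6).all()

    def test_too_few_items(self):
        with pytest.raises(TooFewItemsError):
            suggest_k(np.zeros((5, 5)), kmax=12)


class TestMergeAndLabel:
    def test_identity_labelling_of_pure_templates(self):
        T = scaled_templates(DAYS)
        mapping = merge_and_label(T.to_numpy(), DAYS, n_final=5)
        assert [mapping[i] for i in range(5)] == list(T.index)

    def test_nine_centroids_with_duplicates_merge_to_five(self):
        rng = np.random.default_rng(4)
        T = scaled_templates(DAYS).to_numpy()
        dups = T[[0, 1, 3, 4]] + rng.normal(0, 0.05, size=(4, 5))
        C = np.vstack([T, dups])
        mapping = merge_and_label(C, DAYS, n_final=5)
        labels = scaled_templates(DAYS).index
        assert [mapping[i] for i in range(5)] == list(labels)
        assert mapping[5] == "A" and mapping[6] == "B"
        assert mapping[7] == "D" and mapping[8] == "E"

    def test_manual_map_override(self):
        C = np.zeros((3, 5))
        manual = {0: "E", 1: "A", 2: "B"}
        assert merge_and_label(C, DAYS, manual_map=manual) == manual


class TestEndToEnd:
    def test_output_cardinality_and_stable_invariant(self, small_dataset,
                                                     small_abund):
        ds, _ = small_dataset
        sel = sorted(ds.counts.index[:20])
        assign, clf = rt.assign_response_types(
            small_abund, ds.meta, ds.design, sel, seed=3)
        assert len(assign) == len(sel) * 4
        stable = assign["response_type"] == "STABLE"
        assert assign.loc[stable, "cluster_id"].isna().all()
        assert assign.loc[~stable, "cluster_id"].notna().all()

    def test_all_stable_input_bypasses_clustering(self):
        rng = np.random.default_rng(0)
        X = 100.0 + rng.normal(0, 0.5, size=(12, 5))
        clf = ResponseTypeClassifier(days=DAYS).fit(X)
        assert (clf.labels_ == "STABLE").all()
        assert clf.centroids_.shape[0] == 0

    def test_build_trajectories_replicate_mean(self, small_dataset,
                                               small_abund):
        ds, _ = small_dataset
        traj = build_trajectories(small_abund, ds.meta, ds.design,
                                  [ds.counts.index[0], ds.counts.index[1]])
        assert traj.shape == (8, 5)
        from resptyper.design import samples_for_cell
        ids = samples_for_cell(ds.meta, True, True, 8)
        expect = small_abund.loc[ds.counts.index[0], ids].mean()
        assert traj.loc[(ds.counts.index[0], "+A/+M"), 8] == pytest.approx(expect)

    def test_label_semantics_on_planted_types(self):
        """Assigned labels carry their temporal meaning: the median scaled
        trajectory of each label peaks/dips on its nominal day, and so do
        most individual trajectories.

        Per-trajectory argmax is a noisy statistic: for E the day-4 value of
        the template is 0.78 of the day-8 peak, a 0.33 log-unit gap against
        a ~0.2-0.3 sd on the day-mean difference (replicate, qPCR and read
        noise combined), so 10-20% of true-E trajectories peak at day 4 by
        chance (mirrored for B); D's day-4/day-8 gap is wider. The
        per-trajectory bounds below follow from that error propagation.
        """
        ds, truth = rt.simulate_dataset(rt.SimConfig(s_asvs=150, depth=10_000),
                                        seed=21)
        ab = rt.to_absolute(ds.counts, ds.qpcr)
        rep = rt.select_responsive_asvs(ab, ds.counts, ds.meta, ds.design)
        assign, clf = rt.assign_response_types(
            ab, ds.meta, ds.design, sorted(rep.responsive_set), seed=5)
        traj = build_trajectories(ab, ds.meta, ds.design,
                                  sorted(rep.responsive_set))
        days = np.array(ds.design.days)
        checks = (("D", 4, "max", 0.95), ("E", 8, "max", 0.75),
                  ("B", 8, "min", 0.75))
        for label, day, op, bound in checks:
            sub = assign[assign["response_type"] == label]
            assert len(sub) >= 5, label
            shapes, hits = [], 0
            for _, row in sub.iterrows():
                v = traj.loc[(row["asv_id"], row["treatment"])].to_numpy()
                shapes.append(scale_trajectory(v))
                arg = np.argmax(v) if op == "max" else np.argmin(v)
                hits += days[arg] == day
            med = np.median(np.vstack(shapes), axis=0)
            arg_med = np.argmax(med) if op == "max" else np.argmin(med)
            assert days[arg_med] == day, (label, med)
            assert hits / len(sub) >= bound, label
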