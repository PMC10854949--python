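"""Candidate enumeration, entropy scoring, validity index and seasonal selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barnsense.core_io import PipelineConfig, SensorSample
from barnsense.clustering import ThreeWayCluster, ThreeWayClustering
from barnsense.placement import (
    PlacementCandidate,
    PlacementReport,
    candidates_from_clusters,
    conditional_entropy,
    enumerate_combinations,
    entropy,
    evaluate_combination,
    fuse_seasonal,
    joint_entropy,
    mape,
    rmse,
    select_placement,
    total_entropy,
    twcvi,
)
from barnsense.recluster import SimilarityWeights
from barnsense.synthetic import SceneSpec, generate

W = SimilarityWeights()


def brute_force_joint_entropy(x, y):
    """Independent oracle: explicit 2-D histogram over observed levels."""
    x = np.asarray(x)
    y = np.asarray(y)
    levels_x = {v: i for i, v in enumerate(sorted(set(x.tolist())))}
    levels_y = {v: i for i, v in enumerate(sorted(set(y.tolist())))}
    hist = np.zeros((len(levels_x), len(levels_y)))
    for a, b in zip(x, y):
        hist[levels_x[a], levels_y[b]] += 1
    p = hist.ravel() / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestCandidates:
    def make_clustering(self, groups, X, ids):
        by_id = {sid: X[i] for i, sid in enumerate(ids)}
        clusters = []
        for g in groups:
            pts = np.stack([by_id[s] for s in g])
            clusters.append(ThreeWayCluster(center=pts.mean(axis=0),
                                            core_ids=list(g)))
        return ThreeWayClustering(clusters=clusters)

    def test_five_clusters_give_32_combinations(self, rng):
        X = rng.random((10, 3))
        ids = [f"L-{i+1}" for i in range(10)]
        samples = [SensorSample(ids[i], X[i], np.zeros(3, dtype=int))
                   for i in range(10)]
        groups = [ids[i:i + 2] for i in range(0, 10, 2)]
        tw = self.make_clustering(groups, X, ids)
        cands = candidates_from_clusters(tw, samples)
        assert [len(c) for c in cands] == [2] * 5
        assert len(enumerate_combinations(cands)) == 32

    def test_singleton_cluster_halves_the_pool(self, rng):
        X = rng.random((9, 3))
        ids = [f"L-{i+1}" for i in range(9)]
        samples = [SensorSample(ids[i], X[i], np.zeros(3, dtype=int))
                   for i in range(9)]
        groups = [ids[0:2], ids[2:4], ids[4:6], ids[6:8], ids[8:9]]
        tw = self.make_clustering(groups, X, ids)
        assert len(enumerate_combinations(candidates_from_clusters(tw, samples))) == 16

    def test_nearest_two_sensors_selected(self):
        X = np.array([[0.0], [1.0], [10.0]])
        ids = ["L-1", "L-2", "L-3"]
        samples = [SensorSample(ids[i], X[i], np.zeros(1, dtype=int))
                   for i in range(3)]
        tw = ThreeWayClustering(clusters=[
            ThreeWayCluster(center=np.array([0.2]), core_ids=ids)])
        assert candidates_from_clusters(tw, samples) == [["L-1", "L-2"]]


class TestEntropy:
    def test_uniform_eight_levels_is_three_bits(self):
        assert entropy(np.arange(8)) == pytest.approx(3.0)

    def test_constant_is_zero_bits(self):
        assert entropy(np.zeros(16)) == 0.0

    def test_two_balanced_levels_one_bit(self):
        assert entropy(np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_joint_of_independent_uniforms_adds(self):
        x = np.repeat(np.arange(4), 4)
        y = np.tile(np.arange(4), 4)
        assert joint_entropy(x, y) == pytest.approx(4.0)

    def test_joint_with_self_equals_marginal(self):
        x = np.array([0, 1, 1, 2, 2, 2])
        assert joint_entropy(x, x) == pytest.approx(entropy(x))

    def test_diagonal_pairs_one_bit(self):
        x = np.array([0, 1, 0, 1])
        assert joint_entropy(x, x.copy()) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_entropy(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_chain_rule_and_bounds_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        x = rng.integers(0, 5, size=n)
        y = rng.integers(0, 5, size=n)
        hxy = joint_entropy(x, y)
        assert hxy == pytest.approx(entropy(x) + conditional_entropy(y, x),
                                    abs=1e-9)
        assert hxy >= max(entropy(x), entropy(y)) - 1e-12
        assert hxy <= entropy(x) + entropy(y) + 1e-12
        assert hxy == pytest.approx(brute_force_joint_entropy(x, y), abs=1e-9)


class TestTotalEntropy:
    def test_full_selection_reduces_to_sum_of_singles(self, rng):
        ids = ["L-1", "L-2", "L-3"]
        series = {s: rng.integers(0, 4, size=40) for s in ids}
        expected = sum(entropy(series[s]) for s in ids)
        assert total_entropy(ids, ids, series) == pytest.approx(expected)

    def test_duplicate_unselected_sensor_contributes_its_marginal(self, rng):
        x = rng.integers(0, 4, size=50)
        series = {"L-1": x, "L-2": x.copy()}
        # H(L-1) + H(L-2, L-1) = H + H since the joint of a copy adds nothing
        assert total_entropy(["L-1"], ["L-1", "L-2"], series) == \
            pytest.approx(2 * entropy(x))

    def test_matches_brute_force_oracle_on_toy_sequences(self):
        series = {
            "L-1": np.array([0, 0, 1, 1, 2, 2]),
            "L-2": np.array([0, 1, 0, 1, 0, 1]),
            "L-3": np.array([2, 2, 2, 1, 1, 0]),
        }
        ids = ["L-1", "L-2", "L-3"]
        sel = ["L-2"]
        expected = (entropy(series["L-2"])
                    + brute_force_joint_entropy(series["L-1"], series["L-2"])
                    + brute_force_joint_entropy(series["L-3"], series["L-2"]))
        assert total_entropy(sel, ids, series) == pytest.approx(expected, abs=1e-9)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            total_entropy([], ["L-1"], {"L-1": np.zeros(3)})


class TestTwcvi:
    def sample(self, sid, bins):
        bins = np.asarray(bins, dtype=int)
        return SensorSample(sid, bins.astype(float), bins)

    def test_tight_separated_clusters_score_i1(self):
        samples = [self.sample("L-1", [1, 1]), self.sample("L-2", [1, 1]),
                   self.sample("L-3", [5, 5]), self.sample("L-4", [5, 5])]
        tw = ThreeWayClustering(clusters=[
            ThreeWayCluster(center=np.zeros(2), core_ids=["L-1", "L-2"]),
            ThreeWayCluster(center=np.zeros(2), core_ids=["L-3", "L-4"]),
        ])
        assert twcvi(tw, samples, W) == pytest.approx(0.5)

    def test_identical_samples_any_split_scores_zero(self):
        samples = [self.sample(f"L-{i+1}", [2, 2]) for i in range(4)]
        tw = ThreeWayClustering(clusters=[
            ThreeWayCluster(center=np.zeros(2), core_ids=["L-1", "L-2"]),
            ThreeWayCluster(center=np.zeros(2), core_ids=["L-3", "L-4"]),
        ])
        assert twcvi(tw, samples, W) == pytest.approx(0.0)

    def test_single_cluster_rejected(self):
        samples = [self.sample("L-1", [1]), self.sample("L-2", [1])]
        tw = ThreeWayClustering(clusters=[
            ThreeWayCluster(center=np.zeros(1), core_ids=["L-1", "L-2"])])
        with pytest.raises(ValueError):
            twcvi(tw, samples, W)

    def test_bounded_on_random_instances(self, rng):
        for _ in range(10):
            bins = rng.integers(0, 4, size=(6, 5))
            samples = [self.sample(f"L-{i+1}", bins[i]) for i in range(6)]
            tw = ThreeWayClustering(clusters=[
                ThreeWayCluster(center=np.zeros(5), core_ids=[f"L-{i+1}" for i in range(3)]),
                ThreeWayCluster(center=np.zeros(5), core_ids=[f"L-{i+1}" for i in range(3, 6)]),
            ])
            assert -1.0 <= twcvi(tw, samples, W) <= 1.0


class TestValidationMetrics:
    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([1.5, 2.5], [1.0, 2.0]) == pytest.approx(0.5)
        assert rmse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(math.sqrt(2.5))

    def test_mape_examples(self):
        assert mape([2.0], [2.0]) == 0.0
        assert mape([1.0], [2.0]) == pytest.approx(50.0)
        with pytest.raises(ValueError, match="index 1"):
            mape([1.0, 1.0], [1.0, 0.0])

    def test_duplicate_of_selected_sensor_leaves_rmse_unchanged(self, rng):
        from barnsense.core_io import EnvMatrix
        import pandas as pd

        ts = pd.date_range("2022-01-01", periods=20, freq="30min")
        base = 20 + rng.random((20, 3))
        env = EnvMatrix(ts, ["L-1", "L-2", "L-3"], base, 70 + base / 10)
        dup = EnvMatrix(ts, ["L-1", "L-2", "L-3", "L-4"],
                        np.column_stack([base, base[:, 0]]),
                        np.column_stack([70 + base / 10, 70 + base[:, 0] / 10]))
        m1 = evaluate_combination(env, ["L-1"])
        # reference changes with the pool, but the combination trend does not
        com_t = dup.temperature[:, [0]].mean(axis=1)
        assert np.allclose(com_t, env.temperature[:, 0])
        assert m1["rmse_temp"] >= 0.0


class TestSelectPlacement:
    @pytest.fixture(scope="class")
    def tiny_run(self):
        spec = SceneSpec(days=7, seed=5, start="2022-06-01 00:00")
        env, truth = generate(spec)
        cfg = PipelineConfig(seed=5, k_min=2, k_max=4, ensemble_size=8,
                             pso_max_iter=40)
        window = ("2022-06-01", "2022-06-07 23:59")
        report = select_placement(env, window, "pso", cfg,
                                  season="summer", stride=2)
        return env, truth, cfg, window, report

    def test_report_covers_every_k(self, tiny_run):
        _, _, cfg, _, report = tiny_run
        assert [r["k"] for r in report.per_k] == [2, 3, 4]
        assert report.chosen_k in (2, 3, 4)

    def test_chosen_combination_is_enumerated_and_scored(self, tiny_run):
        _, _, _, _, report = tiny_run
        matching = [r for r in report.per_k if r["k"] == report.chosen_k]
        assert matching[0]["best_combo"] == report.chosen.sensor_ids
        assert report.chosen.rmse_temp >= 0.0
        assert report.chosen.mape_humi >= 0.0

    def test_single_k_range_yields_single_record(self, tiny_run):
        env, _, cfg, window, _ = tiny_run
        cfg1 = cfg.replace(k_min=3, k_max=3)
        report = select_placement(env, window, "pso", cfg1,
                                  season="summer", stride=2)
        assert len(report.per_k) == 1
        assert report.chosen_k == 3

    def test_unknown_algorithm_rejected(self, tiny_run):
        env, _, cfg, window, _ = tiny_run
        with pytest.raises(ValueError, match="algorithm"):
            select_placement(env, window, "annealing", cfg)

    def test_placement_covers_planted_zones(self, tiny_run):
        _, truth, _, _, report = tiny_run
        zones = {truth["zones"][s] for s in report.chosen.sensor_ids}
        assert len(zones) >= 4  # sensors spread over the planted structure

    def test_five_zone_scenes_fully_covered_across_seeds(self):
        """The chosen combination holds a sensor from every planted zone in
        at least 80% of 20 seeded scenes."""
        hits = 0
        for seed in range(20):
            spec = SceneSpec(days=7, seed=seed, start="2022-06-01 00:00")
            env, truth = generate(spec)
            cfg = PipelineConfig(seed=seed, k_min=2, k_max=6,
                                 ensemble_size=10, pso_max_iter=60)
            report = select_placement(env, ("2022-06-01", "2022-06-07 23:59"),
                                      "pso", cfg, stride=2)
            zones = {truth["zones"][s] for s in report.chosen.sensor_ids}
            hits += len(zones) == 5
        assert hits >= 16


class TestFuseSeasonal:
    def report_with(self, sensors, season):
        return PlacementReport(season=season, algo="pso",
                               chosen=PlacementCandidate(sensor_ids=sensors))

    def test_union_is_sorted_by_label(self):
        a = self.report_with(["L-2", "L-8", "L-10", "L-19", "L-28"], "summer")
        b = self.report_with(["L-2", "L-8", "L-10", "L-22", "L-24", "L-28"], "winter")
        fused = fuse_seasonal(a, b)
        assert fused == ["L-2", "L-8", "L-10", "L-19", "L-22", "L-24", "L-28"]

    def test_identical_reports_fuse_to_themselves(self):
        a = self.report_with(["L-1", "L-5"], "summer")
        assert fuse_seasonal(a, a) == ["L-1", "L-5"]

    def test_disjoint_sets_concatenate(self):
        a = self.report_with([f"L-{i}" for i in range(1, 6)], "summer")
        b = self.report_with([f"L-{i}" for i in range(6, 12)], "winter")
        assert len(fuse_seasonal(a, b)) == 11
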