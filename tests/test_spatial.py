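"""Spatial statistics, kNN determinism and permutation-test behavior."""

import numpy as np
import pytest

from excluscope import (
    SpatialSimSpec,
    SpotGrid,
    build_knn,
    exclusion_report,
    neighborhood_statistic,
    nn_distance_statistic,
    permutation_test,
    simulate_spot_grid,
    threshold_spots,
)


def random_grid(n=100, seed=0, with_signals=True):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 50, (n, 2))
    signals = {}
    if with_signals:
        signals = {"marker": rng.normal(size=n), "immune": rng.normal(size=n)}
    return SpotGrid(spot_ids=[f"s{i}" for i in range(n)], coords=coords,
                    signals=signals)


def brute_force_knn(coords, k):
    n = coords.shape[0]
    out = np.empty((n, k), int)
    for i in range(n):
        pairs = sorted(
            (float(np.hypot(*(coords[i] - coords[j]))), j)
            for j in range(n) if j != i
        )
        out[i] = [j for _, j in pairs[:k]]
    return out


class TestBuildKnn:
    def test_collinear_tie_breaks_to_lower_index(self):
        grid = SpotGrid(spot_ids=["a", "b", "c"],
                        coords=np.array([[0.0, 0], [1, 0], [2, 0]]))
        graph = build_knn(grid, k=1)
        assert graph.neighbor_indices[1, 0] == 0  # middle spot: both flanks at d=1

    def test_no_self_loops(self):
        grid = random_grid(50, seed=1)
        graph = build_knn(grid, k=6)
        for i in range(50):
            assert i not in graph.neighbor_indices[i]

    def test_too_few_spots(self):
        grid = SpotGrid(spot_ids=["a", "b"], coords=np.array([[0.0, 0], [1, 0]]))
        with pytest.raises(ValueError, match="k"):
            build_knn(grid, k=6)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_full_sort_oracle(self, seed):
        grid = random_grid(200, seed=seed)
        graph = build_knn(grid, k=6)
        np.testing.assert_array_equal(
            graph.neighbor_indices, brute_force_knn(grid.coords, 6)
        )

    def test_lattice_ties_deterministic(self):
        grid = simulate_spot_grid(SpatialSimSpec(n_side=8, seed=0))
        a = build_knn(grid, k=6).neighbor_indices
        b = build_knn(grid, k=6).neighbor_indices
        np.testing.assert_array_equal(a, b)
        # on a unit lattice every interior spot has 4 equidistant neighbors:
        # the chosen order must be ascending index within the tie
        d = build_knn(grid, k=6).distances
        assert np.all(np.diff(d, axis=1) >= -1e-12)


class TestThresholdSpots:
    def test_upper_quartile_masks_top_value(self):
        grid = SpotGrid(spot_ids=list("abcd"),
                        coords=np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]),
                        signals={"s": np.array([1.0, 2, 3, 4])})
        mask = threshold_spots(grid, "s", 0.75)
        np.testing.assert_array_equal(mask, [False, False, False, True])

    def test_quantile_zero_excludes_only_min(self):
        grid = SpotGrid(spot_ids=list("abcd"),
                        coords=np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]),
                        signals={"s": np.array([1.0, 2, 3, 4])})
        mask = threshold_spots(grid, "s", 0.0)
        np.testing.assert_array_equal(mask, [False, True, True, True])

    def test_constant_signal_warns_all_false(self):
        grid = SpotGrid(spot_ids=list("abcd"),
                        coords=np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]),
                        signals={"s": np.ones(4)})
        with pytest.warns(UserWarning):
            mask = threshold_spots(grid, "s", 0.75)
        assert not mask.any()

    def test_matches_brute_force_quantile_rule(self):
        grid = random_grid(80, seed=9)
        mask = threshold_spots(grid, "immune", 0.6)
        cut = np.quantile(grid.signals["immune"], 0.6)
        np.testing.assert_array_equal(mask, grid.signals["immune"] > cut)


class TestStatistics:
    def test_constant_signal_gives_constant_statistic(self):
        grid = random_grid(60, seed=3, with_signals=False)
        grid.signals["c"] = np.full(60, 2.5)
        graph = build_knn(grid, k=6)
        mask = np.zeros(60, bool)
        mask[[1, 5, 9]] = True
        assert neighborhood_statistic(grid, graph, mask, "c") == pytest.approx(2.5)

    def test_single_source_arithmetic(self):
        # source at the origin, 6 nearest spots carry {0,0,0,0,0,6} -> mean 1
        coords = np.array([[0.0, 0]] + [[np.cos(t), np.sin(t)]
                                        for t in np.linspace(0, 5, 6)]
                          + [[10.0, 10]])
        grid = SpotGrid(spot_ids=[f"s{i}" for i in range(8)], coords=coords,
                        signals={"v": np.array([99.0, 0, 0, 0, 0, 0, 6, 50])})
        graph = build_knn(grid, k=6)
        mask = np.zeros(8, bool)
        mask[0] = True
        assert neighborhood_statistic(grid, graph, mask, "v") == pytest.approx(1.0)

    def test_345_triangle_distance(self):
        grid = SpotGrid(spot_ids=["a", "b"],
                        coords=np.array([[0.0, 0], [3.0, 4.0]]))
        src = np.array([True, False])
        tgt = np.array([False, True])
        assert nn_distance_statistic(grid, src, tgt) == pytest.approx(5.0)

    def test_source_subset_of_target_gives_zero(self):
        grid = random_grid(30, seed=4, with_signals=False)
        tgt = np.ones(30, bool)
        src = np.zeros(30, bool)
        src[:10] = True
        assert nn_distance_statistic(grid, src, tgt) == 0.0

    def test_empty_masks_error(self):
        grid = random_grid(30, seed=4)
        with pytest.raises(ValueError):
            nn_distance_statistic(grid, np.zeros(30, bool), np.ones(30, bool))
        with pytest.raises(ValueError):
            nn_distance_statistic(grid, np.ones(30, bool), np.zeros(30, bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_both_statistics_match_double_loop_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 300))
        grid = random_grid(n, seed=seed + 100)
        graph = build_knn(grid, k=6)
        src = rng.random(n) < 0.3
        tgt = rng.random(n) < 0.3
        src[0] = tgt[1] = True  # keep masks non-empty

        vals = grid.signals["immune"]
        acc = [np.mean([vals[j] for j in graph.neighbor_indices[i]])
               for i in range(n) if src[i]]
        expected_nb = float(np.mean(acc))
        got_nb = neighborhood_statistic(grid, graph, src, "immune")
        assert got_nb == pytest.approx(expected_nb, abs=1e-12)

        dists = []
        for i in np.nonzero(src)[0]:
            dists.append(min(
                float(np.hypot(*(grid.coords[i] - grid.coords[j])))
                for j in np.nonzero(tgt)[0]
            ))
        got_nn = nn_distance_statistic(grid, src, tgt)
        assert got_nn == pytest.approx(float(np.mean(dists)), abs=1e-12)

    def test_translation_rotation_invariance_and_scaling(self):
        grid = random_grid(80, seed=6)
        graph = build_knn(grid, k=6)
        src = threshold_spots(grid, "marker", 0.7)
        tgt = threshold_spots(grid, "immune", 0.7)
        nb0 = neighborhood_statistic(grid, graph, src, "immune")
        nn0 = nn_distance_statistic(grid, src, tgt)

        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = SpotGrid(spot_ids=grid.spot_ids,
                         coords=grid.coords @ rot.T + np.array([13.0, -4.0]),
                         signals=dict(grid.signals))
        graph_m = build_knn(moved, k=6)
        assert neighborhood_statistic(moved, graph_m, src, "immune") == \
            pytest.approx(nb0, abs=1e-9)
        assert nn_distance_statistic(moved, src, tgt) == pytest.approx(nn0, abs=1e-9)

        scaled = SpotGrid(spot_ids=grid.spot_ids, coords=grid.coords * 3.0,
                          signals=dict(grid.signals))
        graph_s = build_knn(scaled, k=6)
        assert neighborhood_statistic(scaled, graph_s, src, "immune") == \
            pytest.approx(nb0, abs=1e-9)  # neighbor sets unchanged
        assert nn_distance_statistic(scaled, src, tgt) == pytest.approx(3 * nn0, abs=1e-9)


class TestPermutationTest:
    def test_constant_signal_pval_one(self):
        grid = random_grid(40, seed=7, with_signals=False)
        grid.signals["c"] = np.full(40, 1.0)
        mask = np.zeros(40, bool)
        mask[:5] = True
        res = permutation_test(grid, "neighborhood", mask, "c", B=50,
                               alternative="less", seed=1)
        assert res.pval == 1.0

    def test_plus_one_correction_floor(self):
        grid = random_grid(40, seed=8)
        mask = threshold_spots(grid, "marker", 0.75)
        res = permutation_test(grid, "neighborhood", mask, "immune", B=10,
                               alternative="less", seed=2)
        assert res.pval >= 1 / 11
        assert res.pval <= 1.0

    def test_deterministic_given_seed(self):
        grid = random_grid(60, seed=9)
        mask = threshold_spots(grid, "marker", 0.75)
        a = permutation_test(grid, "neighborhood", mask, "immune", B=99,
                             alternative="less", seed=5)
        b = permutation_test(grid, "neighborhood", mask, "immune", B=99,
                             alternative="less", seed=5)
        assert a.pval == b.pval
        np.testing.assert_array_equal(a.null_draws, b.null_draws)

    def test_matches_naive_reimplementation_same_rng_stream(self):
        grid = random_grid(60, seed=10)
        graph = build_knn(grid, k=6)
        mask = threshold_spots(grid, "marker", 0.75)
        res = permutation_test(grid, "neighborhood", mask, "immune", B=99,
                               alternative="less", seed=11, graph=graph)

        vals = grid.signals["immune"]
        rng = np.random.default_rng(11)
        null = []
        for _ in range(99):
            perm = rng.permutation(60)
            pv = vals[perm]
            per_spot = [np.mean([pv[j] for j in graph.neighbor_indices[i]])
                        for i in np.nonzero(mask)[0]]
            null.append(float(np.mean(per_spot)))
        null = np.array(null)
        np.testing.assert_allclose(res.null_draws, null, atol=1e-12)
        obs = neighborhood_statistic(grid, graph, mask, "immune")
        assert res.pval == (1 + int(np.sum(null <= obs))) / 100

    def test_label_permutation_scheme(self):
        grid = random_grid(60, seed=12)
        src = threshold_spots(grid, "marker", 0.75)
        tgt = threshold_spots(grid, "immune", 0.75)
        grid.labels["immune_high"] = tgt
        res = permutation_test(grid, "nn_distance", src, "immune_high", B=99,
                               alternative="greater", seed=13)
        assert 1 / 100 <= res.pval <= 1.0
        # every null draw keeps the number of target spots fixed
        assert res.null_draws.size == 99

    def test_invalid_arguments(self):
        grid = random_grid(30, seed=14)
        mask = np.ones(30, bool)
        with pytest.raises(ValueError):
            permutation_test(grid, "neighborhood", mask, "immune", B=0, seed=1)
        with pytest.raises(ValueError):
            permutation_test(grid, "neighborhood", mask, "immune", B=10,
                             alternative="both", seed=1)


class TestExclusionReport:
    def test_planted_exclusion_detected(self):
        grid = simulate_spot_grid(
            SpatialSimSpec(n_side=16, pattern="exclusion", effect=2.0,
                           noise_sd=0.5, seed=0)
        )
        rep = exclusion_report(grid, "marker_score", "immune_score",
                               B=499, seed=0)
        assert rep["neighborhood"].pval <= 0.05
        assert rep["nn_distance"].pval <= 0.05

    def test_colocalization_gives_high_exclusion_pval(self):
        grid = simulate_spot_grid(
            SpatialSimSpec(n_side=16, pattern="colocalized", effect=2.0, seed=1)
        )
        rep = exclusion_report(grid, "marker_score", "immune_score",
                               B=199, seed=1)
        assert rep["neighborhood"].pval > 0.5

    def test_monotone_power_in_effect_size(self):
        """Stronger planted exclusion yields smaller mean p-values."""
        means = []
        for effect in (0.3, 0.8, 2.0):
            ps = []
            for s in range(25):
                grid = simulate_spot_grid(
                    SpatialSimSpec(n_side=12, pattern="exclusion",
                                   effect=effect, seed=s)
                )
                mask = threshold_spots(grid, "marker_score", 0.75)
                ps.append(permutation_test(grid, "neighborhood", mask,
                                           "immune_score", B=99,
                                           alternative="less", seed=s).pval)
            means.append(np.mean(ps))
        assert means[0] >= means[1] >= means[2]
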