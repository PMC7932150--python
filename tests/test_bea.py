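import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from zooregion.bea import (
    RangeDistanceMatrix,
    cluster_elements,
    clustering_test,
    distratio,
    element_maps,
    nmds,
    range_distance,
    simulate_null_ranges,
)
from zooregion.incidence import AdjacencyGraph, IncidenceMatrix
from zooregion.synthetic import generate_species, scenario


def matrix_from_ranges(ranges, ogus):
    cells = np.zeros((len(ranges), len(ogus)), dtype=np.int8)
    for i, r in enumerate(ranges):
        for o in r:
            cells[i, ogus.index(o)] = 1
    return IncidenceMatrix([f"s{i}" for i in range(len(ranges))], ogus, cells)


class TestRangeDistance:
    def test_kulczynski_half(self):
        m = matrix_from_ranges([{"1", "2"}, {"2", "3"}], ["1", "2", "3"])
        d = range_distance(m, "kulczynski")
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_kulczynski_nested(self):
        m = matrix_from_ranges([{"1"}, {"1", "2"}], ["1", "2"])
        d = range_distance(m, "kulczynski")
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_identical_ranges_zero(self):
        m = matrix_from_ranges([{"1", "2"}, {"1", "2"}], ["1", "2"])
        assert range_distance(m).values[0, 1] == 0.0

    def test_jaccard_variant(self):
        m = matrix_from_ranges([{"1", "2"}, {"2", "3"}], ["1", "2", "3"])
        d = range_distance(m, "jaccard")
        assert d.values[0, 1] == pytest.approx(2 / 3)

    def test_empty_range_errors(self):
        m = IncidenceMatrix(["x", "y"], ["A"], np.array([[0], [1]]))
        with pytest.raises(ValueError, match="x"):
            range_distance(m)


class TestDistratio:
    def test_four_distances_direct_sort(self):
        assert distratio(np.array([1.0, 2.0, 3.0, 4.0]), 0.25) == pytest.approx(0.25)

    def test_all_equal_gives_one(self):
        assert distratio(np.array([0.5] * 8), 0.25) == 1.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            distratio(np.zeros(8), 0.25)

    def test_prop_bounds(self):
        with pytest.raises(ValueError):
            distratio(np.array([1.0, 2.0, 3.0, 4.0]), 0.6)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0))
    def test_scale_invariant_and_bounded(self, seed, scale):
        rng = np.random.default_rng(seed)
        vals = rng.random(20) + 1e-6
        t = distratio(vals, 0.25)
        assert 0 < t <= 1
        assert distratio(vals * scale, 0.25) == pytest.approx(t)


class TestNullModel:
    def _setup(self):
        ogus = [f"U{i}" for i in range(9)]
        edges = [(f"U{i}", f"U{i+1}") for i in range(8)]
        g = AdjacencyGraph(ogus, edges)
        rng = np.random.default_rng(0)
        cells = np.zeros((6, 9), dtype=np.int8)
        for i, size in enumerate([1, 1, 2, 3, 3, 5]):
            start = rng.integers(0, 9 - size)
            cells[i, start:start + size] = 1
        return IncidenceMatrix([f"s{i}" for i in range(6)], ogus, cells), g

    def test_range_sizes_conserved(self):
        m, g = self._setup()
        for rep in simulate_null_ranges(m, g, 5, seed=1):
            assert sorted(rep.range_sizes()) == sorted(m.range_sizes())
            assert rep.shape == m.shape

    def test_ranges_connected(self):
        m, g = self._setup()
        for rep in simulate_null_ranges(m, g, 5, seed=2):
            for sid in rep.species_ids:
                assert g.is_contiguous(rep.range_of(sid))

    def test_deterministic_for_seed(self):
        m, g = self._setup()
        a = simulate_null_ranges(m, g, 3, seed=9)
        b = simulate_null_ranges(m, g, 3, seed=9)
        assert all(x == y for x, y in zip(a, b))

    def test_oversized_range_errors(self):
        ogus = ["A", "B"]
        m = IncidenceMatrix(["s"], ogus + ["C"], np.array([[1, 1, 1]]))
        g = AdjacencyGraph(ogus, [("A", "B")])
        with pytest.raises(ValueError):
            simulate_null_ranges(m, g, 1, seed=0)

    def test_uniform_occupancy_on_complete_graph(self):
        ogus = [f"U{i}" for i in range(6)]
        edges = [(a, b) for i, a in enumerate(ogus) for b in ogus[i + 1:]]
        g = AdjacencyGraph(ogus, edges)
        m = matrix_from_ranges([{"U0"}], ogus)
        counts = np.zeros(6)
        for rep in simulate_null_ranges(m, g, 500, seed=3):
            counts += rep.cells[0]
        assert chisquare(counts).pvalue > 0.01


class TestClusteringTest:
    def test_planted_blocks_detected(self):
        m, g, _ = generate_species(scenario("vicariant_clean", seed=1))
        res = clustering_test(m, g, n_sim=200, seed=11)
        assert res.p_value <= 0.05

    def test_p_never_zero(self):
        m, g, _ = generate_species(scenario("null_random", seed=2))
        res = clustering_test(m, g, n_sim=20, seed=3)
        assert res.p_value >= 1 / 21

    def test_observed_t_below_null_mean_on_planted(self):
        m, g, _ = generate_species(scenario("vicariant_clean", seed=4))
        res = clustering_test(m, g, n_sim=100, seed=5)
        assert res.t_observed < float(np.mean(res.t_simulated))

    def test_report_json(self):
        m, g, _ = generate_species(scenario("null_random", seed=6))
        res = clustering_test(m, g, n_sim=10, seed=7)
        js = res.to_json()
        assert '"p_value"' in js and '"null_mean"' in js


class TestNmds:
    def test_three_equidistant_points_zero_stress(self):
        d = RangeDistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
            "kulczynski",
        )
        res = nmds(d, dims=2, seed=0)
        assert res.stress < 1e-3

    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.random((12, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dist = dist / dist.max()
        d = RangeDistanceMatrix([f"s{i}" for i in range(12)], dist, "jaccard")
        res = nmds(d, dims=2, n_restarts=8, seed=2)
        assert res.stress < 0.01

    def test_too_few_points_errors(self):
        d = RangeDistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]), "jaccard")
        with pytest.raises(ValueError):
            nmds(d, dims=2)


class TestClusterElements:
    def test_two_blobs_plus_outliers(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal([0, 0], 0.05, (20, 2))
        blob2 = rng.normal([3, 3], 0.05, (20, 2))
        outliers = np.array([[10.0, -6.0], [-8.0, 9.0], [12.0, 12.0]])
        coords = np.vstack([blob1, blob2, outliers])
        res = cluster_elements(coords, max_k=5, seed=1)
        assert res.n_elements == 2
        assert [a for a in res.assignments[-3:]] == ["noise"] * 3
        # blob members share a label
        assert len(set(res.assignments[:20])) == 1
        assert len(set(res.assignments[20:40])) == 1

    def test_single_tight_cloud(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 0.05, (25, 2))
        res = cluster_elements(coords, max_k=4, seed=3)
        assert res.n_elements == 1
        assert "noise" not in res.assignments

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cluster_elements(np.array([[0.0, np.nan]]))

    def test_every_species_assigned_once(self):
        rng = np.random.default_rng(4)
        coords = rng.random((30, 2))
        res = cluster_elements(coords, max_k=4, seed=5)
        assert len(res.assignments) == 30


class TestElementMaps:
    def _elements(self, m):
        from zooregion.bea import BioticElementSet

        return BioticElementSet(
            m.species_ids, [1] * len(m.species_ids), np.zeros((len(m.species_ids), 2)), 1
        )

    def test_full_presence_top_class(self):
        m = matrix_from_ranges([{"A"}, {"A"}], ["A", "B"])
        maps = element_maps(self._elements(m), m)
        assert maps[1]["A"]["class"] == 4
        assert maps[1]["A"]["proportion"] == 1.0

    def test_half_presence_class_two(self):
        m = matrix_from_ranges([{"A"}, {"B"}], ["A", "B"])
        maps = element_maps(self._elements(m), m)
        assert maps[1]["A"]["class"] == 2  # 0.5 > 0.45 but not > 0.60

    def test_absent_unshaded(self):
        m = matrix_from_ranges([{"A"}, {"A"}], ["A", "B"])
        maps = element_maps(self._elements(m), m)
        assert maps[1]["B"]["class"] == 0
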