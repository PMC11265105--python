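import numpy as np
import pytest

from oracles import brute_hetero_joins, enumerate_join_null
from spatialcoloc import synthgen
from spatialcoloc.errors import DegenerateNullError, ValidationError
from spatialcoloc.spot_scoring import PositivityCalls
from spatialcoloc.spatial_joincount import (
    LABEL_A,
    LABEL_B,
    LABEL_BG,
    JoinCountConfig,
    LabeledLattice,
    analytic_null,
    assign_pair_labels,
    build_adjacency,
    joincount_z,
    observed_joins,
    pairwise_joincount_matrix,
    permutation_null,
)


def make_labels(grid, codes):
    return LabeledLattice(
        grid_ref=grid,
        pair=("A", "B"),
        labels=np.asarray(codes, dtype=int),
        assignment_record=tuple("direct" for _ in codes),
    )


def make_calls(grid, positive, cell_types=("A", "B")):
    positive = np.asarray(positive, dtype=bool)
    return PositivityCalls(
        spots=tuple(grid.spot_ids),
        cell_types=tuple(cell_types),
        positive=positive,
        quantile=0.75,
        thresholds=tuple(0.0 for _ in cell_types),
    )


class TestBuildAdjacency:
    def test_1x2_rook_single_edge(self):
        graph = build_adjacency(synthgen.gen_spot_lattice(1, 2), "rook")
        assert graph.n_edges == 1

    def test_3x3_rook_edge_count(self, grid_3x3):
        assert build_adjacency(grid_3x3, "rook").n_edges == 12

    def test_3x3_queen_brute_force(self, grid_3x3):
        # oracle: enumerate all spot pairs at Chebyshev distance 1
        coords = grid_3x3.coords()
        expected = sum(
            1
            for i in range(9)
            for j in range(i + 1, 9)
            if max(abs(coords[i] - coords[j])) == 1
        )
        assert expected == 20
        assert build_adjacency(grid_3x3, "queen").n_edges == expected

    @pytest.mark.parametrize("rows,cols", [(2, 2), (3, 4), (5, 2)])
    def test_rook_closed_form(self, rows, cols):
        grid = synthgen.gen_spot_lattice(rows, cols)
        graph = build_adjacency(grid, "rook")
        assert graph.n_edges == rows * (cols - 1) + cols * (rows - 1)

    def test_unknown_scheme(self, grid_3x3):
        with pytest.raises(ValidationError):
            build_adjacency(grid_3x3, "bishop")

    def test_deterministic_edge_order(self, grid_3x3):
        g1 = build_adjacency(grid_3x3, "rook")
        g2 = build_adjacency(grid_3x3, "rook")
        np.testing.assert_array_equal(g1.edge_index, g2.edge_index)


class TestAssignPairLabels:
    def test_copositive_even_gets_a(self):
        grid = synthgen.gen_spot_lattice(1, 1)
        calls = make_calls(grid, [[True, True]])
        labels = assign_pair_labels(calls, ("A", "B"), grid, even_gets="A")
        assert labels.labels[0] == LABEL_A  # (0,0): x+y even
        assert labels.assignment_record[0] == "both_even"

    def test_copositive_odd_parity_gets_b(self):
        grid = synthgen.gen_spot_lattice(4, 4)
        positive = np.ones((16, 2), dtype=bool)
        calls = make_calls(grid, positive)
        labels = assign_pair_labels(calls, ("A", "B"), grid)
        for lab, (sid, x, y) in zip(labels.labels, grid.spots):
            expected = LABEL_A if (x + y) % 2 == 0 else LABEL_B
            assert lab == expected
        # spot at (2,3): x+y = 5, odd -> B
        idx = grid.spot_ids.index(synthgen.spot_id(2, 3))
        assert labels.labels[idx] == LABEL_B

    def test_only_and_neither_cases(self):
        grid = synthgen.gen_spot_lattice(1, 4)
        calls = make_calls(
            grid, [[True, False], [False, True], [False, False], [True, True]]
        )
        labels = assign_pair_labels(calls, ("A", "B"), grid)
        assert labels.labels[0] == LABEL_A
        assert labels.labels[1] == LABEL_B
        assert labels.labels[2] == LABEL_BG
        assert labels.assignment_record[:3] == ("only_a", "only_b", "neither")

    def test_even_gets_b_flips_copositive_only(self):
        grid = synthgen.gen_spot_lattice(2, 2)
        calls = make_calls(grid, np.ones((4, 2), dtype=bool))
        la = assign_pair_labels(calls, ("A", "B"), grid, even_gets="A")
        lb = assign_pair_labels(calls, ("A", "B"), grid, even_gets="B")
        assert np.all((la.labels == LABEL_A) == (lb.labels == LABEL_B))

    def test_absent_type_rejected(self, grid_3x3):
        calls = make_calls(grid_3x3, np.zeros((9, 2), dtype=bool))
        with pytest.raises(ValidationError):
            assign_pair_labels(calls, ("A", "Z"), grid_3x3)


class TestObservedJoins:
    def test_all_a_is_zero(self, grid_3x3):
        labels = make_labels(grid_3x3, [LABEL_A] * 9)
        graph = build_adjacency(grid_3x3, "rook")
        assert observed_joins(labels, graph) == 0

    def test_1x2_heterogeneous(self):
        grid = synthgen.gen_spot_lattice(1, 2)
        labels = make_labels(grid, [LABEL_A, LABEL_B])
        assert observed_joins(labels, build_adjacency(grid, "rook")) == 1

    def test_4x4_checkerboard_all_edges_mixed(self):
        grid = synthgen.gen_spot_lattice(4, 4)
        codes = [
            LABEL_A if (x + y) % 2 == 0 else LABEL_B for _, x, y in grid.spots
        ]
        labels = make_labels(grid, codes)
        graph = build_adjacency(grid, "rook")
        assert graph.n_edges == 24
        assert observed_joins(labels, graph) == 24

    def test_matches_brute_force(self, grid_3x3):
        rng = np.random.default_rng(4)
        graph = build_adjacency(grid_3x3, "rook")
        edges = [tuple(e) for e in graph.edge_index]
        for _ in range(25):
            codes = rng.integers(0, 3, size=9)
            labels = make_labels(grid_3x3, codes)
            assert observed_joins(labels, graph) == brute_hetero_joins(codes, edges)

    def test_conservation(self, grid_3x3):
        """J_AB + J_AA + J_BB + joins touching BG = |edges|."""
        rng = np.random.default_rng(11)
        graph = build_adjacency(grid_3x3, "rook")
        e = graph.edge_index
        for _ in range(20):
            codes = rng.integers(0, 3, size=9)
            la, lb = codes[e[:, 0]], codes[e[:, 1]]
            j_ab = np.sum(((la == 1) & (lb == 2)) | ((la == 2) & (lb == 1)))
            j_aa = np.sum((la == 1) & (lb == 1))
            j_bb = np.sum((la == 2) & (lb == 2))
            j_bg = np.sum((la == 0) | (lb == 0))
            assert j_ab + j_aa + j_bb + j_bg == graph.n_edges


class TestPermutationNull:
    def test_forced_outcome_degenerate(self):
        grid = synthgen.gen_spot_lattice(1, 2)
        labels = make_labels(grid, [LABEL_A, LABEL_B])
        graph = build_adjacency(grid, "rook")
        with pytest.raises(DegenerateNullError):
            permutation_null(labels, graph, n_perm=99, seed=0)

    def test_single_label_degenerate(self, grid_3x3):
        labels = make_labels(grid_3x3, [LABEL_A] * 9)
        graph = build_adjacency(grid_3x3, "rook")
        with pytest.raises(DegenerateNullError):
            permutation_null(labels, graph, n_perm=99, seed=0)

    def test_mean_matches_exhaustive_enumeration(self, grid_3x3):
        graph = build_adjacency(grid_3x3, "rook")
        labels = make_labels(grid_3x3, [1, 1, 1, 2, 2, 2, 0, 0, 0])
        edges = [tuple(e) for e in graph.edge_index]
        exact_mean, exact_sd, n_labelings = enumerate_join_null(3, 3, 3, edges)
        assert n_labelings == 1680
        mean, sd, _ = permutation_null(labels, graph, n_perm=10000, seed=1)
        mc_se = exact_sd / np.sqrt(10000)
        assert abs(mean - exact_mean) <= 3 * mc_se

    def test_determinism(self, grid_3x3):
        graph = build_adjacency(grid_3x3, "rook")
        labels = make_labels(grid_3x3, [1, 1, 2, 2, 0, 0, 0, 1, 2])
        r1 = permutation_null(labels, graph, n_perm=199, seed=5)
        r2 = permutation_null(labels, graph, n_perm=199, seed=5)
        assert r1 == r2

    def test_n_perm_minimum(self, grid_3x3):
        graph = build_adjacency(grid_3x3, "rook")
        labels = make_labels(grid_3x3, [1, 1, 2, 2, 0, 0, 0, 1, 2])
        with pytest.raises(ValidationError):
            permutation_null(labels, graph, n_perm=10, seed=0)


class TestAnalyticNull:
    def test_1x2_closed_form_collapses(self):
        grid = synthgen.gen_spot_lattice(1, 2)
        labels = make_labels(grid, [LABEL_A, LABEL_B])
        mean, sd = analytic_null(labels, build_adjacency(grid, "rook"))
        assert mean == 1.0
        assert sd == 0.0

    def test_3x3_plugin_mean(self, grid_3x3):
        labels = make_labels(grid_3x3, [1, 1, 1, 2, 2, 2, 0, 0, 0])
        mean, sd = analytic_null(labels, build_adjacency(grid_3x3, "rook"))
        assert mean == pytest.approx(2 * 12 * 3 * 3 / (9 * 8))
        assert mean == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "rows,cols,n_a,n_b",
        [
            (1, 2, 1, 1),
            (1, 3, 1, 1),
            (2, 2, 1, 2),
            (2, 3, 2, 2),
            (3, 3, 3, 3),
            (3, 3, 2, 4),
            (2, 4, 3, 3),
            (1, 9, 4, 4),
        ],
    )
    def test_moments_match_exhaustive_enumeration(self, rows, cols, n_a, n_b):
        grid = synthgen.gen_spot_lattice(rows, cols)
        n = grid.n_spots
        n_bg = n - n_a - n_b
        codes = [1] * n_a + [2] * n_b + [0] * n_bg
        labels = make_labels(grid, codes)
        graph = build_adjacency(grid, "rook")
        edges = [tuple(e) for e in graph.edge_index]
        exact_mean, exact_sd, _ = enumerate_join_null(n_a, n_b, n_bg, edges)
        mean, sd = analytic_null(labels, graph)
        assert mean == pytest.approx(exact_mean, abs=1e-12)
        assert sd == pytest.approx(exact_sd, abs=1e-10)

    def test_queen_scheme_also_exact(self, grid_3x3):
        labels = make_labels(grid_3x3, [1, 1, 2, 2, 2, 0, 0, 0, 0])
        graph = build_adjacency(grid_3x3, "queen")
        edges = [tuple(e) for e in graph.edge_index]
        exact_mean, exact_sd, _ = enumerate_join_null(2, 3, 4, edges)
        mean, sd = analytic_null(labels, graph)
        assert mean == pytest.approx(exact_mean, abs=1e-12)
        assert sd == pytest.approx(exact_sd, abs=1e-10)

    def test_agrees_with_permutation_on_random_configs(self):
        rng = np.random.default_rng(21)
        for trial in range(10):
            rows, cols = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            grid = synthgen.gen_spot_lattice(rows, cols)
            n = grid.n_spots
            n_a = int(rng.integers(2, n // 2))
            n_b = int(rng.integers(2, n - n_a - 1))
            codes = rng.permutation(
                [1] * n_a + [2] * n_b + [0] * (n - n_a - n_b)
            )
            labels = make_labels(grid, codes)
            graph = build_adjacency(grid, "rook")
            a_mean, a_sd = analytic_null(labels, graph)
            p_mean, _, _ = permutation_null(labels, graph, n_perm=4000, seed=trial)
            assert abs(p_mean - a_mean) <= 3 * a_sd / np.sqrt(4000)


class TestJoincountZ:
    def test_dispersed_negative_z(self, grid_20x20):
        fa = synthgen.gen_celltype_field(grid_20x20, "A", "dispersed", {"side": "low"}, seed=0)
        fb = synthgen.gen_celltype_field(grid_20x20, "B", "dispersed", {"side": "high"}, seed=0)
        calls = synthgen.positivity_from_fields([fa, fb])
        res = joincount_z(calls, grid_20x20, ("A", "B"), JoinCountConfig(seed=0))
        assert res.z is not None and res.z < 0

    def test_aggregated_positive_z(self, grid_20x20, shared_blob_params):
        fa = synthgen.gen_celltype_field(
            grid_20x20, "A", "aggregated", dict(shared_blob_params), seed=0
        )
        fb = synthgen.gen_celltype_field(
            grid_20x20, "B", "aggregated", dict(shared_blob_params), seed=1
        )
        calls = synthgen.positivity_from_fields([fa, fb])
        res = joincount_z(calls, grid_20x20, ("A", "B"), JoinCountConfig(seed=0))
        assert res.z is not None and res.z > 3

    def test_degenerate_null_reported_not_silent(self):
        grid = synthgen.gen_spot_lattice(1, 2)
        calls = make_calls(grid, [[True, False], [False, True]])
        res = joincount_z(calls, grid, ("A", "B"), JoinCountConfig(seed=0))
        assert res.z is None
        assert res.p_perm is None
        assert not res.significant
        assert "degenerate" in res.note

    def test_analytic_method(self, grid_20x20):
        fa = synthgen.gen_celltype_field(grid_20x20, "A", "dispersed", {"side": "low"}, seed=0)
        fb = synthgen.gen_celltype_field(grid_20x20, "B", "dispersed", {"side": "high"}, seed=0)
        calls = synthgen.positivity_from_fields([fa, fb])
        res = joincount_z(
            calls, grid_20x20, ("A", "B"),
            JoinCountConfig(null_method="analytic", seed=0),
        )
        assert res.method == "analytic"
        assert res.z < 0 and res.p_perm is None

    def test_positive_only_null_option(self, grid_20x20):
        fa = synthgen.gen_celltype_field(grid_20x20, "A", "dispersed", {"side": "low"}, seed=0)
        fb = synthgen.gen_celltype_field(grid_20x20, "B", "dispersed", {"side": "high"}, seed=0)
        calls = synthgen.positivity_from_fields([fa, fb])
        res = joincount_z(
            calls, grid_20x20, ("A", "B"),
            JoinCountConfig(permute_bg=False, seed=0),
        )
        assert res.z is not None and res.z < 0

    def test_determinism(self, grid_20x20, shared_blob_params):
        fa = synthgen.gen_celltype_field(
            grid_20x20, "A", "aggregated", dict(shared_blob_params), seed=0
        )
        fb = synthgen.gen_celltype_field(grid_20x20, "B", "random", seed=1)
        calls = synthgen.positivity_from_fields([fa, fb], quantile=0.75)
        config = JoinCountConfig(seed=9)
        r1 = joincount_z(calls, grid_20x20, ("A", "B"), config)
        r2 = joincount_z(calls, grid_20x20, ("A", "B"), config)
        assert r1 == r2


class TestPairwiseMatrix:
    def _calls(self, grid, n_types, seed=0):
        fields = [
            synthgen.gen_celltype_field(grid, f"T{chr(65 + i)}", "random", seed=seed + i)
            for i in range(n_types)
        ]
        return synthgen.positivity_from_fields(fields, quantile=0.75)

    def test_two_types_one_result(self, grid_20x20):
        results = pairwise_joincount_matrix(
            self._calls(grid_20x20, 2), grid_20x20, JoinCountConfig(seed=0)
        )
        assert len(results) == 1

    def test_four_types_six_results(self, grid_20x20):
        results = pairwise_joincount_matrix(
            self._calls(grid_20x20, 4), grid_20x20, JoinCountConfig(seed=0)
        )
        assert len(results) == 6
        assert [r.pair for r in results] == sorted(r.pair for r in results)

    def test_single_type_rejected(self, grid_20x20):
        with pytest.raises(ValidationError):
            pairwise_joincount_matrix(
                self._calls(grid_20x20, 1), grid_20x20, JoinCountConfig(seed=0)
            )

    def test_swap_symmetry_with_even_gets(self, grid_20x20, shared_blob_params):
        """|z| identical when pair order and even_gets flip together."""
        fa = synthgen.gen_celltype_field(
            grid_20x20, "A", "aggregated", dict(shared_blob_params), seed=0
        )
        fb = synthgen.gen_celltype_field(
            grid_20x20, "B", "aggregated", dict(shared_blob_params), seed=1
        )
        calls = synthgen.positivity_from_fields([fa, fb])
        r1 = joincount_z(
            calls, grid_20x20, ("A", "B"), JoinCountConfig(even_gets="A", seed=3)
        )
        r2 = joincount_z(
            calls, grid_20x20, ("B", "A"), JoinCountConfig(even_gets="B", seed=3)
        )
        assert r1.j_obs == r2.j_obs
        assert abs(r1.z) == pytest.approx(abs(r2.z))
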