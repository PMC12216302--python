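import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import networkx as nx

from thalamap.domains import (
    ConnectivityGridMatrix,
    GridSpec,
    InjectionGridRow,
    aggregate_matrix,
    detect_domains,
    grid_label,
    parse_grid_label,
    render_domain_map,
    reorder_matrix,
    tabulate_grid,
)
from thalamap.synthetic import generate_grid_cases
from trees import set_partitions


def two_block_matrix():
    """4 injections x 4 grids, all-ones 2x2 diagonal blocks."""
    frame = pd.DataFrame(
        [
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
        ],
        index=["injA", "injB", "injC", "injD"],
        columns=["r0c0", "r0c1", "r0c2", "r0c3"],
    )
    return ConnectivityGridMatrix(frame, GridSpec())


def brute_force_best_modularity(graph, gamma):
    nodes = list(graph.nodes)
    best, best_part = -np.inf, None
    for part in set_partitions(nodes):
        q = nx.community.modularity(graph, part, weight="weight",
                                    resolution=gamma)
        if q > best:
            best, best_part = q, part
    return best, best_part


class TestTabulate:
    def test_fully_labeled_grid(self):
        spec = GridSpec(grid_px=10)
        mask = np.ones((10, 10), dtype=bool)
        row = tabulate_grid(mask, spec, "anterograde")
        assert row.values[(0, 0)] == pytest.approx(100.0)

    def test_partial_coverage_percentage(self):
        # 2205 labeled pixels of a 105x105 grid -> 20%
        spec = GridSpec(grid_px=105)
        mask = np.zeros((105, 105), dtype=bool)
        mask.flat[:2205] = True
        row = tabulate_grid(mask, spec, "anterograde")
        assert row.values[(0, 0)] == pytest.approx(20.0)

    def test_retrograde_point_counts(self):
        spec = GridSpec(grid_px=105)
        points = [(150.0, 50.0), (160.0, 60.0), (170.0, 20.0)]  # grid (0, 1)
        row = tabulate_grid(points, spec, "retrograde")
        assert row.values == {(0, 1): 3.0}

    def test_empty_mask_warns(self):
        spec = GridSpec(grid_px=10)
        with pytest.warns(UserWarning, match="empty"):
            row = tabulate_grid(np.zeros((10, 10), dtype=bool), spec,
                                "anterograde")
        assert all(v == 0 for v in row.values.values())

    def test_nucleus_mask_drops_outside_grids(self):
        nucleus = np.zeros((20, 20), dtype=bool)
        nucleus[:10, :10] = True
        spec = GridSpec(grid_px=10, nucleus_mask=nucleus)
        mask = np.ones((20, 20), dtype=bool)
        row = tabulate_grid(mask, spec, "anterograde")
        assert set(row.values) == {(0, 0)}


class TestAggregate:
    def test_row_max_scaling(self):
        spec = GridSpec()
        row = InjectionGridRow(
            "a", "anterograde", {(0, 0): 50.0, (0, 1): 25.0}, spec
        )
        matrix = aggregate_matrix([row])
        assert matrix.frame.loc["a"].max() == pytest.approx(1.0)
        assert matrix.frame.loc["a", "r0c1"] == pytest.approx(0.5)

    def test_mixed_kinds_commensurate(self):
        spec = GridSpec()
        rows = [
            InjectionGridRow("ant", "anterograde", {(0, 0): 80.0}, spec),
            InjectionGridRow("ret", "retrograde", {(0, 1): 37.0}, spec),
        ]
        matrix = aggregate_matrix(rows)
        assert (matrix.frame.max(axis=1) == 1.0).all()

    def test_matches_rescaling_oracle(self):
        case_set = generate_grid_cases(
            n_injections=6, planted_domains=2, grid_shape=(4, 10), seed=5
        )
        matrix = aggregate_matrix(case_set.rows)
        for row in case_set.rows:
            peak = max(row.values.values())
            for grid, value in row.values.items():
                assert matrix.frame.loc[
                    row.injection_id, grid_label(*grid)
                ] == pytest.approx(value / peak)

    def test_inconsistent_spec_rejected(self):
        rows = [
            InjectionGridRow("a", "anterograde", {(0, 0): 1.0}, GridSpec()),
            InjectionGridRow(
                "b", "anterograde", {(0, 0): 1.0}, GridSpec(grid_px=50)
            ),
        ]
        with pytest.raises(ValueError, match="GridSpec"):
            aggregate_matrix(rows)

    def test_all_zero_row_dropped_with_warning(self):
        spec = GridSpec()
        rows = [
            InjectionGridRow("a", "anterograde", {(0, 0): 1.0}, spec),
            InjectionGridRow("z", "anterograde", {(0, 0): 0.0}, spec),
        ]
        with pytest.warns(UserWarning, match="all-zero"):
            matrix = aggregate_matrix(rows)
        assert matrix.injections == ["a"]


class TestDetect:
    def test_two_block_matches_exhaustive_oracle(self):
        matrix = two_block_matrix()
        partition = detect_domains(matrix, gamma=0.75, seed=0)
        inj = partition.injection_communities()
        grid = partition.grid_communities()
        assert inj["injA"] == inj["injB"] == grid["r0c0"] == grid["r0c1"]
        assert inj["injC"] == inj["injD"] == grid["r0c2"] == grid["r0c3"]
        assert inj["injA"] != inj["injC"]
        from thalamap.domains import _bipartite_graph

        graph = _bipartite_graph(matrix)
        best_q, _ = brute_force_best_modularity(graph, 0.75)
        assert partition.modularity == pytest.approx(best_q, abs=1e-12)

    def test_single_cell(self):
        frame = pd.DataFrame([[1.0]], index=["inj"], columns=["r0c0"])
        partition = detect_domains(
            ConnectivityGridMatrix(frame, GridSpec()), seed=0
        )
        assert len(set(partition.community_of.values())) == 1

    def test_planted_four_block_recovery(self):
        for seed in range(3):
            case_set = generate_grid_cases(seed=seed)
            matrix = aggregate_matrix(case_set.rows)
            partition = detect_domains(matrix, gamma=0.75, seed=seed)
            inj = partition.injection_communities()
            planted = [case_set.planted_domain_of[i] for i in matrix.injections]
            found = [inj[i] for i in matrix.injections]
            assert adjusted_rand_score(planted, found) == pytest.approx(1.0)

    def test_permutation_invariance(self):
        case_set = generate_grid_cases(seed=7)
        matrix = aggregate_matrix(case_set.rows)
        rng = np.random.default_rng(0)
        shuffled = ConnectivityGridMatrix(
            matrix.frame.iloc[
                rng.permutation(len(matrix.frame)),
                rng.permutation(matrix.frame.shape[1]),
            ],
            matrix.grid,
        )
        a = detect_domains(matrix, seed=1)
        b = detect_domains(shuffled, seed=1)
        groups_a = {}
        for node, cid in a.community_of.items():
            groups_a.setdefault(cid, set()).add(node)
        groups_b = {}
        for node, cid in b.community_of.items():
            groups_b.setdefault(cid, set()).add(node)
        assert set(map(frozenset, groups_a.values())) == set(
            map(frozenset, groups_b.values())
        )

    def test_all_zero_matrix_rejected(self):
        frame = pd.DataFrame([[0.0]], index=["inj"], columns=["r0c0"])
        with pytest.raises(ValueError, match="all-zero"):
            detect_domains(ConnectivityGridMatrix(frame, GridSpec()))

    @pytest.mark.parametrize("seed", range(2))
    def test_louvain_near_exhaustive_optimum(self, seed):
        # 3 injections x 2 + 2 grids: 10 vertices max for brute force
        case_set = generate_grid_cases(
            n_injections=4, planted_domains=2, grid_shape=(1, 4),
            noise_sd=0.02, seed=seed, repeats=1,
        )
        matrix = aggregate_matrix(case_set.rows)
        from thalamap.domains import _bipartite_graph

        graph = _bipartite_graph(matrix)
        assert graph.number_of_nodes() <= 10
        best_q, _ = brute_force_best_modularity(graph, 0.75)
        partition = detect_domains(matrix, gamma=0.75, seed=seed)
        assert partition.modularity >= 0.95 * best_q


class TestReorder:
    def test_already_ordered_unchanged(self):
        matrix = two_block_matrix()
        partition = detect_domains(matrix, seed=0)
        reordered = reorder_matrix(matrix, partition)
        pd.testing.assert_frame_equal(reordered.frame, matrix.frame)

    def test_restores_block_diagonal(self):
        matrix = two_block_matrix()
        permuted = ConnectivityGridMatrix(
            matrix.frame.iloc[[0, 2, 1, 3], [1, 3, 0, 2]], matrix.grid
        )
        partition = detect_domains(permuted, seed=0)
        reordered = reorder_matrix(permuted, partition)
        values = reordered.frame.to_numpy()
        assert (values[:2, :2] == 1.0).all()
        assert (values[2:, 2:] == 1.0).all()
        assert (values[:2, 2:] == 0.0).all()
        assert (values[2:, :2] == 0.0).all()

    def test_sum_preserved(self):
        case_set = generate_grid_cases(seed=2)
        matrix = aggregate_matrix(case_set.rows)
        partition = detect_domains(matrix, seed=2)
        reordered = reorder_matrix(matrix, partition)
        assert reordered.frame.to_numpy().sum() == pytest.approx(
            matrix.frame.to_numpy().sum()
        )

    def test_mismatch_rejected(self):
        matrix = two_block_matrix()
        partition = detect_domains(matrix, seed=0)
        other = ConnectivityGridMatrix(
            matrix.frame.rename(index={"injA": "unknown"}), matrix.grid
        )
        with pytest.raises(ValueError, match="cover"):
            reorder_matrix(other, partition)


class TestRenderMap:
    def test_two_community_2x2(self):
        frame = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]],
            index=["a", "b"],
            columns=["r0c0", "r0c1", "r1c0", "r1c1"],
        )
        partition = detect_domains(
            ConnectivityGridMatrix(frame, GridSpec()), seed=0
        )
        table = render_domain_map(partition, GridSpec())
        assert table.shape == (2, 2)
        assert len(set(table.to_numpy().ravel())) == 2

    def test_stable_across_reruns(self):
        matrix = two_block_matrix()
        t1 = render_domain_map(detect_domains(matrix, seed=4), GridSpec())
        t2 = render_domain_map(detect_domains(matrix, seed=4), GridSpec())
        pd.testing.assert_frame_equal(t1, t2)

    def test_matches_partition_mapping(self):
        matrix = two_block_matrix()
        partition = detect_domains(matrix, seed=0)
        table = render_domain_map(partition, GridSpec())
        for label, cid in partition.grid_communities().items():
            r, c = parse_grid_label(label)
            assert table.loc[r, c] == cid


def test_grid_label_round_trip():
    assert parse_grid_label(grid_label(3, 17)) == (3, 17)
    with pytest.raises(ValueError):
        parse_grid_label("x1y2")


def test_grid_um_default_side():
    assert GridSpec().grid_um == pytest.approx(63.0)
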