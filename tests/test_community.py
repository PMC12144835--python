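"""Community detection: CPM quality, Leiden wrapper, iterative partitioning."""

import numpy as np
import pytest

from bigpicc.community import (
    Community,
    InvalidPartitionError,
    Partition,
    build_candidate_pool,
    cpm_quality,
    iterative_partition,
    optimize_partition,
    subgraph_density,
)
from bigpicc.matrix import MutationMatrix, build_graph
from bigpicc.simulate import make_toy_fixture

from conftest import all_set_partitions, brute_force_cpm


def _matrix_from(D, n_tumor=None):
    D = np.asarray(D, dtype=np.uint8)
    n_g, n_s = D.shape
    n_tumor = n_s if n_tumor is None else n_tumor
    return MutationMatrix(
        [f"g{i}" for i in range(n_g)],
        [f"s{j}" for j in range(n_s)],
        ["tumor"] * n_tumor + ["normal"] * (n_s - n_tumor),
        D,
    )


def _partition_from_membership(mat, membership):
    """Vertex membership (genes then samples) -> list of Community."""
    n_g = mat.n_genes
    comms = {}
    for v, cid in enumerate(membership):
        comms.setdefault(cid, (set(), set()))
        if v < n_g:
            comms[cid][0].add(mat.gene_ids[v])
        else:
            comms[cid][1].add(mat.sample_ids[v - n_g])
    return [Community(frozenset(g), frozenset(s)) for g, s in comms.values()]


class TestCpmQuality:
    def test_agrees_with_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            D = (rng.random((6, 6)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            mat = _matrix_from(D)
            graph = build_graph(mat)
            membership = rng.integers(0, 4, size=12)
            gamma = float(rng.uniform(0, 1))
            part = _partition_from_membership(mat, membership)
            oracle = brute_force_cpm(
                D,
                [
                    (
                        [i for i in range(6) if membership[i] == c],
                        [j for j in range(6) if membership[6 + j] == c],
                    )
                    for c in set(membership)
                ],
                gamma,
            )
            assert cpm_quality(graph, part, gamma) == pytest.approx(oracle)

    def test_all_singleton_partition_scores_zero(self, toy_matrix):
        graph = build_graph(toy_matrix)
        singles = [Community(frozenset([g]), frozenset()) for g in toy_matrix.gene_ids]
        singles += [
            Community(frozenset(), frozenset([s])) for s in toy_matrix.sample_ids
        ]
        assert cpm_quality(graph, singles, 0.7) == 0.0

    def test_gamma_zero_counts_internal_edges(self):
        mat = _matrix_from(np.ones((2, 2)))
        graph = build_graph(mat)
        whole = [Community(frozenset(mat.gene_ids), frozenset(mat.sample_ids))]
        assert cpm_quality(graph, whole, 0.0) == 4.0

    def test_biclique_single_community_is_exhaustive_optimum(self):
        mat = _matrix_from(np.ones((2, 2)))
        graph = build_graph(mat)
        whole = [Community(frozenset(mat.gene_ids), frozenset(mat.sample_ids))]
        assert cpm_quality(graph, whole, 0.5) == 2.0
        vertices = list(range(4))
        best = max(
            brute_force_cpm(
                mat.data,
                [
                    ([v for v in blk if v < 2], [v - 2 for v in blk if v >= 2])
                    for blk in part
                ],
                0.5,
            )
            for part in all_set_partitions(vertices)
        )
        assert best == 2.0

    def test_overlapping_communities_rejected(self, toy_matrix):
        graph = build_graph(toy_matrix)
        comm = Community(frozenset(toy_matrix.gene_ids), frozenset(toy_matrix.sample_ids))
        dup = Community(frozenset([toy_matrix.gene_ids[0]]), frozenset())
        with pytest.raises(InvalidPartitionError):
            cpm_quality(graph, [comm, dup], 0.5)

    def test_non_covering_partition_rejected(self, toy_matrix):
        graph = build_graph(toy_matrix)
        partial = [Community(frozenset([toy_matrix.gene_ids[0]]), frozenset())]
        with pytest.raises(InvalidPartitionError):
            cpm_quality(graph, partial, 0.5)


class TestSubgraphDensity:
    def test_complete_biclique(self):
        mat = _matrix_from(np.ones((3, 3)))
        graph = build_graph(mat)
        assert subgraph_density(graph, mat.gene_ids, mat.sample_ids) == 1.0

    def test_edgeless(self):
        mat = _matrix_from(np.zeros((2, 3)))
        graph = build_graph(mat)
        assert subgraph_density(graph, mat.gene_ids, mat.sample_ids) == 0.0

    def test_partial_block(self):
        D = np.zeros((3, 4), dtype=np.uint8)
        D[0, :2] = 1
        D[1, 1:3] = 1
        D[2, 3] = 1
        mat = _matrix_from(D)
        graph = build_graph(mat)
        assert subgraph_density(graph, mat.gene_ids, mat.sample_ids) == pytest.approx(
            5 / 12
        )

    def test_empty_set_rejected(self, toy_matrix):
        graph = build_graph(toy_matrix)
        with pytest.raises(ValueError):
            subgraph_density(graph, [], toy_matrix.sample_ids)


class TestOptimizePartition:
    def test_two_disjoint_bicliques_are_separated(self):
        D = np.zeros((6, 6), dtype=np.uint8)
        D[:3, :3] = 1
        D[3:, 3:] = 1
        mat = _matrix_from(D)
        graph = build_graph(mat)
        part = optimize_partition(graph, gamma=0.5, seed=0)
        nontrivial = sorted(
            (sorted(c.genes), sorted(c.samples))
            for c in part.communities
            if c.genes and c.samples
        )
        assert nontrivial == [
            (["g0", "g1", "g2"], ["s0", "s1", "s2"]),
            (["g3", "g4", "g5"], ["s3", "s4", "s5"]),
        ]

    def test_single_edge_merges_below_gamma_one(self):
        mat = _matrix_from(np.ones((1, 1)))
        graph = build_graph(mat)
        part = optimize_partition(graph, gamma=0.5, seed=1)
        assert any(c.genes and c.samples for c in part.communities)

    def test_quality_never_negative(self):
        rng = np.random.default_rng(7)
        for seed in range(10):
            D = (rng.random((5, 5)) < 0.4).astype(np.uint8)
            mat = _matrix_from(D)
            graph = build_graph(mat)
            gamma = float(rng.uniform(0.05, 1.0))
            part = optimize_partition(graph, gamma, seed=seed)
            assert cpm_quality(graph, part, gamma) >= -1e-12

    def test_deterministic_for_fixed_seed(self):
        D = (np.random.default_rng(3).random((8, 8)) < 0.4).astype(np.uint8)
        mat = _matrix_from(D)
        graph = build_graph(mat)
        a = optimize_partition(graph, 0.3, seed=11)
        b = optimize_partition(graph, 0.3, seed=11)
        assert sorted(map(repr, a.communities)) == sorted(map(repr, b.communities))

    def test_reaches_exhaustive_optimum_on_small_graphs(self):
        # Leiden only promises local optimality; require >= 80% global hits.
        rng = np.random.default_rng(13)
        hits = 0
        trials = 10
        for t in range(trials):
            D = (rng.random((4, 4)) < rng.uniform(0.3, 0.7)).astype(np.uint8)
            mat = _matrix_from(D)
            graph = build_graph(mat)
            gamma = float(rng.uniform(0.2, 0.8))
            achieved = cpm_quality(
                graph, optimize_partition(graph, gamma, seed=t), gamma
            )
            best = max(
                brute_force_cpm(
                    D,
                    [
                        ([v for v in blk if v < 4], [v - 4 for v in blk if v >= 4])
                        for blk in part
                    ],
                    gamma,
                )
                for part in all_set_partitions(range(8))
            )
            hits += achieved == pytest.approx(best)
        assert hits >= 0.8 * trials


class TestIterativePartition:
    def test_small_dense_graph_yields_single_combination(self):
        # One missing edge keeps the density below 1, so the dense core
        # scores above the all-singleton partition and is returned whole.
        D = np.ones((4, 6), dtype=np.uint8)
        D[3, 5] = 0
        mat = _matrix_from(D)
        res = iterative_partition(mat, 3, 8, seed=0)
        assert res.combinations == {frozenset(mat.gene_ids)}
        assert res.optimizer_calls == 1

    def test_complete_biclique_at_density_one_yields_nothing(self):
        # gamma = density = 1 makes every community contribute <= 0; the
        # all-singleton outcome is accepted and no candidate is emitted.
        res = iterative_partition(_matrix_from(np.ones((4, 6))), 3, 8, seed=0)
        assert res.combinations == set()

    def test_planted_biclique_recovered(self):
        mat = make_toy_fixture("planted_biclique_4x30")
        planted = frozenset(["g00", "g01", "g02", "g03"])
        res = iterative_partition(mat, 4, 4, seed=0)
        assert planted in res.combinations

    def test_planted_biclique_contained_with_loose_bounds(self):
        mat = make_toy_fixture("planted_biclique_4x30")
        planted = frozenset(["g00", "g01", "g02", "g03"])
        res = iterative_partition(mat, 3, 8, seed=0)
        assert any(planted <= combo for combo in res.combinations)

    def test_oversized_community_triggers_refinement_within_call_budget(self):
        # 20-gene dense block forces at least one refinement with u=8.
        rng = np.random.default_rng(5)
        D = (rng.random((40, 50)) < 0.03).astype(np.uint8)
        D[:20, :40] |= (rng.random((20, 40)) < 0.9).astype(np.uint8)
        mat = _matrix_from(D)
        res = iterative_partition(mat, 3, 8, seed=1)
        assert res.optimizer_calls >= 2
        assert res.optimizer_calls <= mat.n_genes
        assert all(3 <= len(c) <= 8 for c in res.combinations)

    def test_call_counter_bounded_by_gene_count_across_seeds(
        self, random_matrix_factory
    ):
        for seed in range(5):
            mat = random_matrix_factory(30, 40, 40, 0.15, seed=seed)
            res = iterative_partition(mat, 2, 4, seed=seed)
            assert res.optimizer_calls <= mat.n_genes
            assert all(2 <= len(c) <= 4 for c in res.combinations)

    def test_invalid_hit_range_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            iterative_partition(toy_matrix, 5, 3, seed=0)


class TestCandidatePool:
    def test_single_pass_pool_equals_iterative_partition(self):
        mat = make_toy_fixture("planted_biclique_4x30")
        pool = build_candidate_pool(mat, 3, 8, p=1, base_seed=9)
        direct = iterative_partition(mat, 3, 8, seed=9)
        assert set(pool.combinations) == direct.combinations
        assert all(n == 1 for n in pool.combinations.values())

    def test_pool_is_deterministic(self):
        mat = make_toy_fixture("planted_biclique_4x30")
        a = build_candidate_pool(mat, 3, 8, p=5, base_seed=2)
        b = build_candidate_pool(mat, 3, 8, p=5, base_seed=2)
        assert a.combinations == b.combinations

    def test_provenance_counts_accumulate_with_passes(self):
        mat = make_toy_fixture("planted_biclique_4x30")
        small = build_candidate_pool(mat, 4, 4, p=5, base_seed=0)
        large = build_candidate_pool(mat, 4, 4, p=20, base_seed=0)
        planted = frozenset(["g00", "g01", "g02", "g03"])
        assert large.combinations.get(planted, 0) >= small.combinations.get(planted, 0)

    def test_pool_serialization_round_trip(self, tmp_path):
        import pandas as pd

        from bigpicc.community import write_pool

        mat = make_toy_fixture("planted_biclique_4x30")
        pool = build_candidate_pool(mat, 4, 4, p=2, base_seed=0)
        path = tmp_path / "pool.tsv"
        write_pool(pool, path)
        table = pd.read_csv(path, sep="\t")
        assert list(table.columns) == ["genes", "h", "n_passes_found"]
        assert len(table) == len(pool)
        assert (table["h"] == table["genes"].str.split(",").str.len()).all()
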