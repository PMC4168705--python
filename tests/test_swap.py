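"""Edge merging, operation-set enumeration, scheduling, reduction."""

import math

import pytest

from msgasm.graph import ZERO_EDGE, BiEdge, ZeroEdge, check_edge, dump_graph
from msgasm.kmers import oriented, reverse_complement
from msgasm.swap import (
    Activity,
    MergePair,
    SchedulerConfig,
    ScheduleOverrunError,
    enumerate_sigma,
    merge,
    reduce_graph,
    run_swap,
    schedule_cost,
    select_independent,
)

from conftest import chain_graph, random_read_graph


def spelled(g, e):
    return oriented(e.from_key, e.d_from) + e.label


def consecutive_edges(s, k):
    """All 1-step edges of a string, already consecutive and mergeable."""
    from msgasm.kmers import representative

    out = []
    for i in range(len(s) - k):
        a, b = s[i : i + k], s[i + 1 : i + 1 + k]
        (ka, da), (kb, db) = representative(a), representative(b)
        out.append(BiEdge(ka, kb, da, db, b[-1], coverage=float(i + 1)))
    return out


class TestMerge:
    def test_label_concatenation(self):
        e = merge(
            BiEdge("TAG", "AGT", "+", "+", "T"), BiEdge("AGT", "GTC", "+", "+", "C")
        )
        assert e.key == ("TAG", "GTC", "+", "+", "TC")
        assert e.step == 2
        check_edge(e, 3)

    def test_zero_is_absorbing(self):
        e = BiEdge("TAG", "AGT", "+", "+", "T")
        assert merge(ZERO_EDGE, e) is ZERO_EDGE
        assert merge(e, ZERO_EDGE) is ZERO_EDGE

    def test_direction_mismatch_is_zero(self):
        e1 = BiEdge("TAG", "AGT", "+", "+", "T")
        e2 = BiEdge("AGT", "TAG", "-", "-", "A")  # enters AGT on the other strand
        assert isinstance(merge(e1, e2), ZeroEdge)

    def test_endpoint_mismatch_is_zero(self):
        e1 = BiEdge("TAG", "AGT", "+", "+", "T")
        e3 = BiEdge("GTC", "TCG", "+", "+", "G")
        assert isinstance(merge(e1, e3), ZeroEdge)

    def test_coverage_is_length_weighted_mean(self):
        e1 = BiEdge("TAG", "AGT", "+", "+", "T", coverage=10.0)
        e2 = BiEdge("AGT", "GTC", "+", "+", "C", coverage=4.0)
        assert merge(e1, e2).coverage == pytest.approx(7.0)

    def test_associativity_on_random_triples(self):
        """(e1 x e2) x e3 == e1 x (e2 x e3) field for field, for every
        consecutive triple drawn from random repeat-free strings."""
        from msgasm.simulate import repeat_free_genome

        checked = 0
        seed = 0
        while checked < 1000:
            s = repeat_free_genome(5 + 30, 5, seed)
            seed += 1
            edges = consecutive_edges(s, 5)
            for e1, e2, e3 in zip(edges, edges[1:], edges[2:]):
                left = merge(merge(e1, e2), e3)
                right = merge(e1, merge(e2, e3))
                assert left.key == right.key
                assert left.coverage == pytest.approx(right.coverage)
                checked += 1

    def test_spelled_string_conserved_by_merge(self):
        edges = consecutive_edges("TAGTCGAGG", 3)
        acc = edges[0]
        for e in edges[1:]:
            acc = merge(acc, e)
        assert oriented(acc.from_key, acc.d_from) + acc.label == "TAGTCGAGG"


class TestEnumerateSigma:
    def test_worked_graph_centers(self, worked_graph):
        centers = {p.center for p in enumerate_sigma(worked_graph)}
        # degree-4 palindromic junction TCG is not mergeable; terminals are not
        assert centers == {"AGT", "GTC", "GAG"}

    def test_reduced_chain_has_empty_sigma(self):
        g = chain_graph(8)
        reduce_graph(g)
        assert enumerate_sigma(g) == []

    def test_merge_pairs_are_valid(self, worked_graph):
        for p in enumerate_sigma(worked_graph):
            assert p.left.d_to == p.right.d_from
            assert p.left.to_key == p.center == p.right.from_key
            assert not isinstance(merge(p.left, p.right), ZeroEdge)


class TestSelectIndependent:
    def test_chain_of_four_edges_selects_at_most_half(self):
        g = chain_graph(4)
        pairs = enumerate_sigma(g)
        assert len(pairs) == 3
        sel = select_independent(pairs, SchedulerConfig())
        assert len(sel) == 2  # at most half of the edges merge per round

    def test_single_pair_selected(self):
        g = chain_graph(2)
        pairs = enumerate_sigma(g)
        assert len(pairs) == 1
        assert select_independent(pairs, SchedulerConfig()) == pairs

    def test_conflicting_pairs_pick_one(self):
        g = chain_graph(3)
        pairs = [p for p in enumerate_sigma(g)]
        assert len(pairs) == 2  # share the middle edge
        for mode, seed in [("deterministic", 0), ("randomized", 7)]:
            sel = select_independent(pairs, SchedulerConfig(mode, seed))
            assert len(sel) == 1

    def test_selection_is_maximal(self):
        g = random_read_graph(3)
        pairs = enumerate_sigma(g)
        sel = select_independent(pairs, SchedulerConfig("randomized", 5))
        locked = frozenset().union(*(p.small_world() for p in sel)) if sel else set()
        for p in pairs:
            assert p in sel or (p.small_world() & locked)


class TestReduceGraph:
    def test_five_node_path_reduces_in_two_rounds(self):
        g = chain_graph(4)  # 5 k-molecules, 4 one-step edges
        _, report = reduce_graph(g)
        assert report.rounds == 2
        assert g.n_edges() == 1
        assert next(iter(g.edges.values())).step == 4

    def test_already_reduced_graph_is_noop(self):
        g = chain_graph(6)
        reduce_graph(g)
        _, report = reduce_graph(g)
        assert report.rounds == 0 and report.operations_applied == 0

    @pytest.mark.parametrize("n_edges", [2, 3, 5, 8, 16, 33, 100, 256])
    def test_halving_bound_on_pure_paths(self, n_edges):
        g = chain_graph(n_edges, seed=n_edges)
        _, report = reduce_graph(g)
        assert report.rounds == math.ceil(math.log2(n_edges))
        assert g.n_edges() == 1

    def test_spelled_sequence_conserved(self):
        from msgasm.simulate import repeat_free_genome

        genome = repeat_free_genome(120, 15, 9)
        g = chain_graph(105, seed=9)  # same genome: length 15 + 105
        _, _ = reduce_graph(g)
        (e,) = g.edges.values()
        seq = spelled(g, e)
        assert seq in (genome, reverse_complement(genome))

    def test_interior_molecules_removed(self):
        g = chain_graph(5)
        n_before = g.n_molecules()
        reduce_graph(g)
        assert g.n_molecules() == 2  # only the two path ends remain
        assert n_before == 6

    def test_cycle_terminates_with_circular_self_loop(self):
        from msgasm import build_graph
        from msgasm.simulate import repeat_free_genome, tile_reads

        genome = repeat_free_genome(150, 15, 4)
        reads = tile_reads(genome + genome[:20], 50, 5)  # wraps around
        g = build_graph(reads, 15)
        _, report = reduce_graph(g)  # must not loop forever
        assert g.n_edges() == 1
        (e,) = g.edges.values()
        assert e.from_key == e.to_key and e.d_from == e.d_to

    def test_merge_order_invariance(self):
        configs = [
            SchedulerConfig("deterministic", 0, 1),
            SchedulerConfig("deterministic", 0, 8),
            SchedulerConfig("randomized", 1, 1),
            SchedulerConfig("randomized", 2, 4),
            SchedulerConfig("randomized", 3, 8),
        ]
        for seed in range(4):
            dumps = set()
            for cfg in configs:
                g = random_read_graph(seed)
                reduce_graph(g, cfg)
                g.audit()
                dumps.add(dump_graph(g))
            assert len(dumps) == 1


class TestRunSwap:
    def test_partition_invariance_on_edge_merging(self):
        outputs = []
        for p in (1, 8):
            g = random_read_graph(11)
            _, report = reduce_graph(g, SchedulerConfig(partitions=p))
            outputs.append((dump_graph(g), report.operations_applied))
        assert outputs[0] == outputs[1]

    def test_generic_driver_matches_reduce(self, worked_graph):
        g1 = worked_graph.copy()
        g2 = worked_graph.copy()
        reduce_graph(g1)
        from msgasm.swap import MergePair, apply_merge

        activity = Activity(
            enumerate_ops=enumerate_sigma,
            small_world=MergePair.small_world,
            apply=apply_merge,
            sort_key=lambda p: p.sort_key,
        )
        run_swap(g2, activity)
        assert dump_graph(g1) == dump_graph(g2)

    def test_empty_operation_set_is_zero_rounds(self):
        activity = Activity(
            enumerate_ops=lambda s: [],
            small_world=lambda op: frozenset(),
            apply=lambda s, op: None,
        )
        report = run_swap(None, activity)
        assert report.rounds == 0

    def test_non_terminating_activity_is_caught(self):
        activity = Activity(
            enumerate_ops=lambda s: [1],
            small_world=lambda op: frozenset([op]),
            apply=lambda s, op: None,
            sort_key=lambda op: (op,),
        )
        with pytest.raises(ScheduleOverrunError):
            run_swap(None, activity, max_rounds=10)


class TestScheduleCost:
    @pytest.mark.parametrize(
        "paths,strategy,expected",
        [
            ([3, 5], "sequential", 6),
            ([3, 5], "per_path_parallel", 4),
            ([3, 5], "swap", 2),
            ([5], "sequential", 4),
            ([3], "sequential", 2),
            ([2], "swap", 0),
        ],
    )
    def test_two_linked_paths_costs(self, paths, strategy, expected):
        assert schedule_cost(paths, strategy) == expected

    def test_swap_cost_matches_actual_reduction_rounds(self):
        for n_nodes in (3, 5, 9, 17):
            g = chain_graph(n_nodes - 1, seed=n_nodes)
            _, report = reduce_graph(g)
            assert report.rounds == schedule_cost([n_nodes], "swap")

    def test_single_node_path_rejected(self):
        with pytest.raises(ValueError):
            schedule_cost([1], "sequential")

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            schedule_cost([3], "pointer_jumping")
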