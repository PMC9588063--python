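"""Breakpoint-graph construction, coverage annotation, path enumeration."""

import itertools
import random

import numpy as np
import pytest

from svkit.bpgraph import (
    annotate_coverage,
    build_graph,
    enumerate_paths_dfs,
    find_anchored_paths,
)
from svkit.sv_io import classify_simple_status
from svkit.simulate import SimCohort, simulate_simple_cohort

from conftest import make_sv


def prepared(svs):
    return classify_simple_status(svs)


class TestBuildGraph:
    def test_compatible_breakends_get_seq_edge(self):
        # two translocations with a '-' / '+' pair 100 kb apart on chr3
        svs = prepared([
            make_sv("t1", "chr1", 1_000_000, "+", "chr3", 5_000_000, "-"),
            make_sv("t2", "chr2", 2_000_000, "-", "chr3", 5_100_000, "+"),
        ])
        g = build_graph(svs)
        assert len(g.seq_edges) == 1
        e = g.seq_edges[0]
        assert (e.chrom, e.span) == ("chr3", (5_000_000, 5_100_000))

    def test_span_beyond_limit_no_edge(self):
        svs = prepared([
            make_sv("t1", "chr1", 1_000_000, "+", "chr3", 5_000_000, "-"),
            make_sv("t2", "chr2", 2_000_000, "-", "chr3", 11_000_000, "+"),
        ])
        assert build_graph(svs).seq_edges == []

    def test_incompatible_orientations_no_edge(self):
        svs = prepared([
            make_sv("t1", "chr1", 1_000_000, "+", "chr3", 5_000_000, "+"),
            make_sv("t2", "chr2", 2_000_000, "-", "chr3", 5_100_000, "-"),
        ])
        assert build_graph(svs).seq_edges == []

    def test_simple_td_and_del_released(self):
        svs = prepared([
            make_sv("d1", "chr1", 1_000_000, "+", "chr1", 1_050_000, "-"),
            make_sv("d2", "chr1", 2_000_000, "-", "chr1", 2_050_000, "+"),
        ])
        g = build_graph(svs)
        assert g.nodes == [] and g.seq_edges == []

    def test_unset_simple_status_rejected(self):
        with pytest.raises(ValueError, match="simple_status"):
            build_graph([make_sv("a", "chr1", 10, "+", "chr1", 99, "-")])

    def test_degree_constraints_on_random_cohorts(self, genome):
        for seed in range(10):
            cohort = simulate_simple_cohort(
                genome, n_samples=1,
                counts={"deletion_type": 10, "td_type": 10, "head_to_head": 10,
                        "tail_to_tail": 10, "translocation": 10},
                seed=seed,
            )
            g = build_graph(prepared(cohort.svs))
            for n in g.nodes:
                assert g.sv_mate(n) is not None
                assert len(g.seq_edges_of(n)) <= 2
            for e in g.seq_edges:
                assert e.low.orient == "-" and e.high.orient == "+"
                assert 0 < e.length < 5e6

    def test_order_invariance(self, genome):
        cohort = simulate_simple_cohort(genome, n_samples=1, seed=3)
        svs = prepared(cohort.svs)
        ref = build_graph(list(svs))
        ref_edges = {(e.low, e.high) for e in ref.seq_edges}
        rng = random.Random(1)
        for _ in range(3):
            shuffled = list(svs)
            rng.shuffle(shuffled)
            g = build_graph(shuffled)
            assert {(e.low, e.high) for e in g.seq_edges} == ref_edges


class TestAnnotateCoverage:
    def test_flat_track_gives_flat_annotations(self, flat_track):
        svs = prepared([
            make_sv("t1", "chr1", 1_000_000, "+", "chr3", 5_000_000, "-"),
            make_sv("t2", "chr2", 2_000_000, "-", "chr3", 5_100_000, "+"),
        ])
        g = annotate_coverage(build_graph(svs), flat_track)
        for left, right in g.node_flank_cov.values():
            for v in (left, right):
                assert np.isnan(v) or v == 1.0
        assert all(e.mean_cov == 1.0 for e in g.seq_edges)

    def test_flank_truncated_at_neighbouring_breakend(self, flat_track):
        svs = prepared([
            make_sv("t1", "chr1", 1_000_000, "+", "chr3", 5_000_000, "-"),
            make_sv("t2", "chr2", 2_000_000, "-", "chr3", 5_002_000, "+"),
        ])
        g = annotate_coverage(build_graph(svs), flat_track, flank=10_000)
        node = [n for n in g.nodes if n.chrom == "chr3" and n.pos == 5_002_000][0]
        left, _ = g.node_flank_cov[node]
        # window [5_000_000, 5_002_000): only bin 500 -> still 1.0 but truncated
        assert left == 1.0

    def test_missing_chromosome_is_error(self, flat_track):
        svs = prepared([make_sv("t", "chr1", 100, "+", "chr9", 100, "-")])
        with pytest.raises(ValueError, match="chr9"):
            annotate_coverage(build_graph(svs), flat_track)

    def test_planted_tsi_edge_coverage_above_baseline(self, genome):
        co = SimCohort(genome=genome)
        co.plant("tsi_cycle", "S1", seed=2)
        g = build_graph(prepared(co.sample_svs("S1")))
        annotate_coverage(g, co.coverage("S1"))
        assert any(e.mean_cov is not None and e.mean_cov > 1.2 for e in g.seq_edges)


def brute_force_alternating_paths(graph, a, b, min_n=4, max_n=12):
    """Exhaustive alternating-simple-path oracle via node permutations
    checked edge-by-edge (viable only on small graphs)."""
    found = set()

    def edge_type(u, v):
        types = []
        if graph.sv_mate(u) == v:
            types.append("sv")
        for e in graph.seq_edges_of(u):
            if e.low == v or e.high == v:
                types.append("seq")
        return types

    def rec(path, used_types):
        node = path[-1]
        if node == b and len(path) >= min_n:
            fwd = tuple(path)
            found.add(min(fwd, tuple(reversed(fwd))))
        if len(path) >= max_n or node == b:
            return
        for nxt in graph.nodes:
            if nxt in path:
                continue
            for t in edge_type(node, nxt):
                if used_types and t == used_types[-1]:
                    continue
                rec(path + [nxt], used_types + [t])

    rec([a], [])
    return found


class TestPaths:
    def _chain_graph(self):
        # A-B (sv), seq B..C, C-D (sv): one 4-breakpoint path A->D
        svs = prepared([
            make_sv("s1", "chr1", 1_000_000, "+", "chr2", 3_000_000, "-"),
            make_sv("s2", "chr2", 3_200_000, "+", "chr1", 8_000_000, "-"),
        ])
        return build_graph(svs)

    def test_single_chain_one_anchored_path(self):
        g = self._chain_graph()
        a = [n for n in g.nodes if n.chrom == "chr1" and n.pos == 1_000_000][0]
        d = [n for n in g.nodes if n.chrom == "chr1" and n.pos == 8_000_000][0]
        paths = find_anchored_paths(g, a, d)
        assert len(paths) == 1 and paths[0].n_breakpoints == 4

    def test_disconnected_anchors_empty(self):
        svs = prepared([
            make_sv("s1", "chr1", 1_000_000, "+", "chr2", 3_000_000, "-"),
            make_sv("s2", "chr1", 20_000_000, "+", "chr3", 3_000_000, "-"),
        ])
        g = build_graph(svs)
        a = [n for n in g.nodes if n.pos == 1_000_000][0]
        b = [n for n in g.nodes if n.pos == 20_000_000][0]
        assert find_anchored_paths(g, a, b) == []

    def test_anchor_not_in_graph_rejected(self):
        g = self._chain_graph()
        from svkit.records import Breakpoint

        with pytest.raises(ValueError, match="anchor"):
            find_anchored_paths(g, Breakpoint("chrX", 5, "+"), g.nodes[0])

    def test_agrees_with_bruteforce_oracle_random_graphs(self):
        from svkit.simulate import make_toy_genome

        dense = make_toy_genome(n_chrom=2, length=20_000_000)
        checked = 0
        for seed in range(8):
            cohort = simulate_simple_cohort(
                dense, n_samples=1,
                counts={"head_to_head": 2, "tail_to_tail": 2, "translocation": 2},
                seed=seed,
            )
            g = build_graph(prepared(cohort.svs))
            if len(g.nodes) > 12 or not g.seq_edges:
                continue
            nodes = sorted(g.nodes, key=lambda n: (n.chrom, n.pos))
            for a, b in itertools.combinations(nodes, 2):
                mine = {p.canonical() for p in find_anchored_paths(g, a, b)}
                oracle = brute_force_alternating_paths(g, a, b)
                assert len(mine) == len(oracle), (seed, a, b)
                checked += 1
        assert checked > 0

    def test_cycle_detected(self, genome):
        co = SimCohort(genome=genome)
        co.plant("tsi_cycle", "S1", seed=4)
        g = build_graph(prepared(co.sample_svs("S1")))
        paths = enumerate_paths_dfs(g)
        assert any(p.is_cycle for p in paths)

    def test_isolated_sv_edges_yield_nothing(self):
        svs = prepared([
            make_sv("t", "chr1", 1_000_000, "+", "chr2", 30_000_000, "-"),
        ])
        assert enumerate_paths_dfs(build_graph(svs)) == []

    def test_dfs_enumeration_deterministic(self, genome):
        co = SimCohort(genome=genome)
        co.plant("bridge_deletion", "S1", seed=6, params={"n_tsis": 2})
        g = build_graph(prepared(co.sample_svs("S1")))
        a = [p.canonical() for p in enumerate_paths_dfs(g)]
        b = [p.canonical() for p in enumerate_paths_dfs(g)]
        assert a == b and a
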