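"""Breakpoint graph for complex-rearrangement reconstruction.

Every breakend of a genome's non-simple junctions is a node.  Two edge
classes exist:

* an *SV edge* joins the two breakends of one junction;
* a *sequence edge* joins breakends of two distinct junctions on the same
  chromosome when the intervening reference segment can be traversed into
  both junctions: the lower-coordinate breakend must be '-' oriented
  (right flank joined) and the higher one '+' (left flank joined), and the
  span must be short (< 5 Mb by default).

Breakends of simple tandem duplications and simple deletions are released
before construction so isolated simple events do not contaminate complex
paths.  Each node keeps at most two sequence edges (the nearest compatible
partners); every node has exactly one SV edge.

A *path* alternates SV and sequence edges; alternating paths or cycles with
four or more breakpoints are the complex-rearrangement candidates that the
:mod:`svkit.complex_events` classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import Breakpoint, CoverageTrack, SVRecord

__all__ = [
    "SeqEdge",
    "GraphPath",
    "BreakpointGraph",
    "build_graph",
    "annotate_coverage",
    "find_anchored_paths",
    "enumerate_paths_dfs",
]


@dataclass
class SeqEdge:
    """Reference segment between a '-' node (lower coord) and a '+' node."""

    low: Breakpoint
    high: Breakpoint
    mean_cov: float | None = None

    @property
    def chrom(self) -> str:
        return self.low.chrom

    @property
    def span(self) -> tuple[int, int]:
        return (self.low.pos, self.high.pos)

    @property
    def length(self) -> int:
        return self.high.pos - self.low.pos

    @property
    def key(self) -> tuple:
        return (self.low, self.high)


@dataclass
class GraphPath:
    """An alternating walk through the graph.

    ``edge_types[i]`` is the type ('sv' or 'seq') of the edge between
    ``nodes[i]`` and ``nodes[i+1]``; for cycles one extra closing edge type
    is appended.
    """

    nodes: tuple[Breakpoint, ...]
    edge_types: tuple[str, ...]
    is_cycle: bool = False

    @property
    def n_breakpoints(self) -> int:
        return len(self.nodes)

    @property
    def anchors(self) -> tuple[Breakpoint, Breakpoint]:
        return (self.nodes[0], self.nodes[-1])

    def seq_edges(self, graph: "BreakpointGraph") -> list[SeqEdge]:
        """Sequence edges traversed by this path, in order."""
        out = []
        pairs = list(zip(self.nodes, self.nodes[1:]))
        if self.is_cycle:
            pairs.append((self.nodes[-1], self.nodes[0]))
        for (u, v), et in zip(pairs, self.edge_types):
            if et == "seq":
                out.append(graph.seq_edge_between(u, v))
        return out

    def canonical(self) -> tuple:
        def node_key(n: Breakpoint):
            return (n.chrom, n.pos, n.orient, n.sv_id, n.mate_index)

        fwd = tuple(node_key(n) for n in self.nodes)
        rev = tuple(reversed(fwd))
        if self.is_cycle:
            # canonical rotation + direction for cycles
            best = None
            seqs = [fwd, rev]
            for seq in seqs:
                for i in range(len(seq)):
                    rot = seq[i:] + seq[:i]
                    if best is None or rot < best:
                        best = rot
            return ("cycle", best)
        return ("path", min(fwd, rev))


class BreakpointGraph:
    """Nodes, SV edges, sequence edges and coverage annotations."""

    def __init__(self, sample: str = ""):
        self.sample = sample
        self.nodes: list[Breakpoint] = []
        self.records: dict[str, SVRecord] = {}
        self._mate: dict[Breakpoint, Breakpoint] = {}
        self._seq_adj: dict[Breakpoint, list[SeqEdge]] = {}
        self._seq_by_pair: dict[frozenset, SeqEdge] = {}
        self.node_flank_cov: dict[Breakpoint, tuple[float, float]] = {}
        self.track: CoverageTrack | None = None
        self.flank: float = 1e4

    # -- construction ------------------------------------------------------
    def add_sv(self, rec: SVRecord) -> None:
        self.records[rec.id] = rec
        for bp in rec.breakends:
            self.nodes.append(bp)
            self._seq_adj[bp] = []
        self._mate[rec.bp1] = rec.bp2
        self._mate[rec.bp2] = rec.bp1

    def add_seq_edge(self, edge: SeqEdge) -> None:
        self._seq_adj[edge.low].append(edge)
        self._seq_adj[edge.high].append(edge)
        self._seq_by_pair[frozenset((edge.low, edge.high))] = edge

    # -- access ------------------------------------------------------------
    def sv_mate(self, node: Breakpoint) -> Breakpoint:
        return self._mate[node]

    def seq_edges_of(self, node: Breakpoint) -> list[SeqEdge]:
        return self._seq_adj[node]

    def seq_edge_between(self, u: Breakpoint, v: Breakpoint) -> SeqEdge:
        return self._seq_by_pair[frozenset((u, v))]

    @property
    def seq_edges(self) -> list[SeqEdge]:
        return list(self._seq_by_pair.values())

    def __contains__(self, node: Breakpoint) -> bool:
        return node in self._seq_adj

    def nodes_on(self, chrom: str) -> list[Breakpoint]:
        return sorted(
            (n for n in self.nodes if n.chrom == chrom), key=lambda n: n.pos
        )

    def adjacent_on_chrom(self, a: Breakpoint, b: Breakpoint) -> bool:
        """True if no other graph node lies strictly between a and b."""
        if a.chrom != b.chrom:
            return False
        lo, hi = sorted((a.pos, b.pos))
        return not any(
            lo < n.pos < hi for n in self.nodes if n.chrom == a.chrom
        )

    # -- coverage helpers --------------------------------------------------
    def local_baseline(
        self,
        chrom: str,
        start: float,
        end: float,
        exclude: list[tuple[str, float, float]],
        window: float = 1e6,
    ) -> float:
        """Median coverage of the locally non-affected region: bins within
        ``window`` of [start, end) that fall outside all excluded spans."""
        if self.track is None:
            raise ValueError("graph has no coverage annotation")
        return self.track.median_excluding(
            chrom, start - window, end + window, exclude
        )


def build_graph(
    svs: list[SVRecord],
    max_span: float = 5e6,
    max_seq_edges: int = 2,
    release_simple: bool = True,
    sample: str | None = None,
) -> BreakpointGraph:
    """Build the breakpoint graph for one genome.

    Simple tandem duplications and simple deletions are released first
    (``release_simple=False`` keeps them, used for amplicon-local cycle
    tests).  Sequence edges obey the orientation rule and ``max_span``;
    when a node has more than ``max_seq_edges`` compatible partners only
    the nearest survive, and an edge is kept only if both ends keep it.
    Construction is invariant to input order.
    """
    svs = sorted(svs, key=lambda r: (r.bp1.chrom, r.bp1.pos, r.bp2.chrom, r.bp2.pos, r.id))
    if release_simple:
        for r in svs:
            if r.simple_status == "unset":
                raise ValueError(
                    f"{r.id}: simple_status unset; run classify_simple_status first"
                )
        svs = [
            r
            for r in svs
            if not (r.simple_status == "simple" and r.svtype in ("td_type", "deletion_type"))
        ]
    g = BreakpointGraph(sample=sample or (svs[0].sample if svs else ""))
    for r in svs:
        g.add_sv(r)

    # candidate sequence edges: '-' at lower coord -> '+' at higher coord
    chroms = sorted({n.chrom for n in g.nodes})
    candidates: list[SeqEdge] = []
    for chrom in chroms:
        nodes = g.nodes_on(chrom)
        for i, u in enumerate(nodes):
            if u.orient != "-":
                continue
            for v in nodes[i + 1 :]:
                if v.pos - u.pos >= max_span:
                    break
                if v.orient != "+" or v.sv_id == u.sv_id or v.pos <= u.pos:
                    continue
                candidates.append(SeqEdge(low=u, high=v))

    # prune to the nearest max_seq_edges per node, kept only if mutual
    keep: dict[Breakpoint, set] = {n: set() for n in g.nodes}
    by_node: dict[Breakpoint, list[SeqEdge]] = {n: [] for n in g.nodes}
    for e in candidates:
        by_node[e.low].append(e)
        by_node[e.high].append(e)
    for n, edges in by_node.items():
        edges.sort(key=lambda e: (e.length, e.span))
        for e in edges[:max_seq_edges]:
            keep[n].add(e.key)
    for e in candidates:
        if e.key in keep[e.low] and e.key in keep[e.high]:
            g.add_seq_edge(e)
    return g


def annotate_coverage(
    graph: BreakpointGraph, track: CoverageTrack, flank: float = 1e4
) -> BreakpointGraph:
    """Attach per-node flank coverages and per-sequence-edge mean coverage.

    Flank windows are truncated at the nearest other breakend so a node's
    flank never reaches across a neighbouring junction.
    """
    missing = sorted({n.chrom for n in graph.nodes if n.chrom not in track})
    if missing:
        raise ValueError(f"coverage track missing chromosomes: {missing}")
    pos_by_chrom: dict[str, list[int]] = {}
    for n in graph.nodes:
        pos_by_chrom.setdefault(n.chrom, []).append(n.pos)
    for v in pos_by_chrom.values():
        v.sort()
    for n in graph.nodes:
        positions = pos_by_chrom[n.chrom]
        left_neighbors = [p for p in positions if p < n.pos]
        right_neighbors = [p for p in positions if p > n.pos]
        left_lo = max(n.pos - flank, left_neighbors[-1] if left_neighbors else 0)
        right_hi = min(
            n.pos + flank,
            right_neighbors[0] if right_neighbors else n.pos + flank,
        )
        left = track.mean(n.chrom, left_lo, n.pos) if n.pos > left_lo else float("nan")
        right = track.mean(n.chrom, n.pos, right_hi) if right_hi > n.pos else float("nan")
        graph.node_flank_cov[n] = (left, right)
    for e in graph.seq_edges:
        e.mean_cov = track.mean(e.chrom, e.low.pos, e.high.pos)
    graph.track = track
    graph.flank = flank
    return graph


# ---------------------------------------------------------------------------
# path enumeration

def _node_sort_key(n: Breakpoint):
    return (n.chrom, n.pos, n.orient, n.sv_id, n.mate_index)


def _neighbors(graph: BreakpointGraph, node: Breakpoint, edge_type: str):
    if edge_type == "sv":
        yield graph.sv_mate(node)
    else:
        for e in sorted(graph.seq_edges_of(node), key=lambda e: (e.length, _node_sort_key(e.low))):
            yield e.high if e.low == node else e.low


def find_anchored_paths(
    graph: BreakpointGraph,
    anchor1: Breakpoint,
    anchor2: Breakpoint,
    max_breakpoints: int = 12,
    min_breakpoints: int = 4,
) -> list[GraphPath]:
    """All simple alternating paths between two anchors with at least
    ``min_breakpoints`` nodes, deduplicated up to reversal and capped at
    ``max_breakpoints`` nodes."""
    for a in (anchor1, anchor2):
        if a not in graph:
            raise ValueError(f"anchor {a} not in graph")
    results: dict[tuple, GraphPath] = {}

    def dfs(node, visited, path_nodes, path_edges):
        if node == anchor2 and len(path_nodes) >= min_breakpoints:
            p = GraphPath(tuple(path_nodes), tuple(path_edges))
            results.setdefault(p.canonical(), p)
            # anchor2 reached; do not extend through it
            return
        if len(path_nodes) >= max_breakpoints:
            return
        last = path_edges[-1] if path_edges else None
        allowed = ("sv", "seq") if last is None else (("seq",) if last == "sv" else ("sv",))
        for et in allowed:
            for nxt in _neighbors(graph, node, et):
                if nxt in visited:
                    continue
                dfs(nxt, visited | {nxt}, path_nodes + [nxt], path_edges + [et])

    dfs(anchor1, {anchor1}, [anchor1], [])
    return sorted(results.values(), key=lambda p: p.canonical())


def enumerate_paths_dfs(
    graph: BreakpointGraph,
    min_breakpoints: int = 4,
    max_breakpoints: int = 30,
) -> list[GraphPath]:
    """Depth-first enumeration of maximal simple alternating paths and of
    alternating cycles with >= ``min_breakpoints`` nodes.

    Deterministic: traversal order follows genomic coordinates.  A path is
    *maximal* when it cannot be extended at either end without revisiting a
    node or breaking alternation.
    """
    paths: dict[tuple, GraphPath] = {}
    cycles: dict[tuple, GraphPath] = {}
    start_nodes = sorted(graph.nodes, key=_node_sort_key)

    def extensions(node, visited, last_et):
        want = "seq" if last_et == "sv" else "sv"
        out = []
        for nxt in _neighbors(graph, node, want):
            if nxt not in visited:
                out.append((nxt, want))
        return out

    def can_extend_start(path_nodes, first_et):
        want = "seq" if first_et == "sv" else "sv"
        visited = set(path_nodes)
        return any(
            nxt not in visited
            for nxt in _neighbors(graph, path_nodes[0], want)
        )

    def dfs(path_nodes, path_edges, visited):
        node = path_nodes[-1]
        last = path_edges[-1]
        # cycle closure: next edge returns to the start
        want = "seq" if last == "sv" else "sv"
        closing = False
        for nxt in _neighbors(graph, node, want):
            if nxt == path_nodes[0] and len(path_nodes) >= max(min_breakpoints, 3):
                if len(path_nodes) % 2 == 0:  # alternation closes cleanly
                    c = GraphPath(
                        tuple(path_nodes), tuple(path_edges) + (want,), is_cycle=True
                    )
                    cycles.setdefault(c.canonical(), c)
                    closing = True
        exts = extensions(node, visited, last)
        if (not exts or len(path_nodes) >= max_breakpoints) and not closing:
            if len(path_nodes) >= min_breakpoints and not can_extend_start(
                path_nodes, path_edges[0]
            ):
                p = GraphPath(tuple(path_nodes), tuple(path_edges))
                paths.setdefault(p.canonical(), p)
            return
        if not exts:
            return
        for nxt, et in exts:
            dfs(path_nodes + [nxt], path_edges + [et], visited | {nxt})

    for start in start_nodes:
        for first_et in ("sv", "seq"):
            for nxt in _neighbors(graph, start, first_et):
                if nxt == start:
                    continue
                dfs([start, nxt], [first_et], {start, nxt})
    out = sorted(cycles.values(), key=lambda p: p.canonical()) + sorted(
        paths.values(), key=lambda p: p.canonical()
    )
    return out
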