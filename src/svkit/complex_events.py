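"""Classification of breakpoint-graph paths into complex-rearrangement
classes, chain clustering, and chromothripsis candidate calling.

A complex rearrangement is modelled as a simple SV whose junction is
bridged by cycles of templated sequence insertions (TSIs): elevated-
coverage sequence edges on an alternating graph path.  The classifier
reads the coverage evidence attached to a path:

* **bridge_deletion** — adjacent same-chromosome anchors whose interval
  lost coverage while every TSI edge gained;
* **tsi_cycle** (circular TD) — adjacent anchors whose interval gained
  coverage, TSI edges elevated;
* **unbalanced_translocation_tsi** — anchors on different chromosomes,
  each showing a copy-number step between its flanks, joined through
  elevated TSI edges;
* **unbalanced_inversion** — same-chromosome anchors with coverage loss
  inside the affected region while the traversed sequence edges stay at
  baseline.

Chains (>= 10 clustered SVs) are found by single-linkage clustering of
breakends; chains with >= 8 breakpoints whose copy numbers oscillate
between two or three states and whose SV types are not skewed are flagged
as chromothripsis candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chisquare

from .bpgraph import BreakpointGraph, GraphPath, enumerate_paths_dfs, find_anchored_paths
from .records import Breakpoint, CNSegment, SVRecord

__all__ = [
    "TSI",
    "ComplexEvent",
    "ChainCluster",
    "classify_path",
    "classify_tsi_origin",
    "detect_chains",
    "detect_chromothripsis",
    "classify_chromothripsis_pattern",
    "detect_complex_events",
]

EVENT_CLASSES = (
    "bridge_deletion",
    "tsi_cycle",
    "unbalanced_inversion",
    "unbalanced_translocation_tsi",
    "tsi_foldback",
    "chain",
    "chromothripsis_candidate",
    "unclassified",
)


@dataclass
class TSI:
    """A templated (copied) segment inserted at a junction."""

    chrom: str
    start: int
    end: int
    origin_class: str = ""  # local | distal | interchromosomal

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TSI segment must have positive size")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class ComplexEvent:
    sample: str
    event_class: str
    path: GraphPath | None = None
    anchors: tuple[Breakpoint, Breakpoint] | None = None
    tsis: list[TSI] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)
    member_sv_ids: tuple[str, ...] = ()


def classify_tsi_origin(tsi: TSI, event_anchor_locus: tuple[str, int]) -> str:
    """local (< 1 Mb), distal (>= 1 Mb) or interchromosomal origin of a
    templated insertion relative to the event anchor locus.  Symmetric in
    the template's strand (only the interval matters)."""
    chrom, pos = event_anchor_locus
    if tsi.chrom != chrom:
        return "interchromosomal"
    if tsi.start <= pos <= tsi.end:
        return "local"
    dist = min(abs(tsi.start - pos), abs(tsi.end - pos))
    return "local" if dist < 1e6 else "distal"


def _tsis_of_path(path: GraphPath, graph: BreakpointGraph) -> list[TSI]:
    a1, a2 = path.anchors
    tsis = []
    for e in path.seq_edges(graph):
        t = TSI(e.chrom, e.low.pos, e.high.pos)
        anchor = a1 if e.chrom == a1.chrom else a2
        t.origin_class = classify_tsi_origin(t, (anchor.chrom, anchor.pos))
        tsis.append(t)
    return tsis


def classify_path(
    path: GraphPath, graph: BreakpointGraph, cn_delta: float = 0.3
) -> ComplexEvent:
    """Classify one alternating path by its coverage evidence.

    ``cn_delta`` is the minimum coverage deviation (on the normalized
    tumor/normal ratio scale, 0.5 per copy on a diploid baseline) treated
    as a real copy-number change.
    """
    if graph.track is None:
        raise ValueError("graph must be coverage-annotated (annotate_coverage)")
    for n in path.nodes:
        if n not in graph:
            raise ValueError(f"path node {n} not in graph")
    track = graph.track
    a1, a2 = path.anchors
    tsis = _tsis_of_path(path, graph)
    seq_edges = path.seq_edges(graph)

    exclude = [(t.chrom, t.start - graph.flank, t.end + graph.flank) for t in tsis]
    same_chrom = a1.chrom == a2.chrom
    if same_chrom:
        lo, hi = sorted((a1.pos, a2.pos))
        exclude.append((a1.chrom, lo - graph.flank, hi + graph.flank))
        baseline = graph.local_baseline(a1.chrom, lo, hi, exclude)
        interval_cov = track.mean(a1.chrom, lo, hi)
    else:
        baseline = graph.local_baseline(a1.chrom, a1.pos, a1.pos, exclude)
        interval_cov = float("nan")

    def edge_baseline(e):
        if same_chrom and e.chrom == a1.chrom:
            return baseline
        return graph.local_baseline(e.chrom, e.low.pos, e.high.pos, exclude)

    edge_base = [edge_baseline(e) for e in seq_edges]
    tsis_elevated = bool(seq_edges) and all(
        e.mean_cov is not None and e.mean_cov > b + cn_delta
        for e, b in zip(seq_edges, edge_base)
    )
    edges_neutral = bool(seq_edges) and all(
        e.mean_cov is not None and abs(e.mean_cov - b) <= cn_delta
        for e, b in zip(seq_edges, edge_base)
    )

    label = "unclassified"
    evidence = {
        "baseline": baseline,
        "interval_cov": interval_cov,
        "edge_cov": [e.mean_cov for e in seq_edges],
        "cn_delta": cn_delta,
    }
    adjacent = same_chrom and graph.adjacent_on_chrom(a1, a2)
    if adjacent and np.isfinite(interval_cov):
        low_a, high_a = sorted((a1, a2), key=lambda n: n.pos)
        # anchor orientations must match the junction the event implies:
        # a deleted interval is flanked (+ ... -), a duplicated one (- ... +)
        if (
            (low_a.orient, high_a.orient) == ("+", "-")
            and interval_cov < baseline - cn_delta
            and tsis_elevated
        ):
            label = "bridge_deletion"
        elif (
            (low_a.orient, high_a.orient) == ("-", "+")
            and interval_cov > baseline + cn_delta
            and tsis_elevated
        ):
            label = "tsi_cycle"
    if label == "unclassified" and not same_chrom:
        steps = []
        for a in (a1, a2):
            left, right = graph.node_flank_cov.get(a, (np.nan, np.nan))
            steps.append(
                np.isfinite(left) and np.isfinite(right) and abs(left - right) >= cn_delta
            )
        evidence["anchor_steps"] = steps
        if all(steps) and tsis_elevated:
            label = "unbalanced_translocation_tsi"
    if label == "unclassified" and same_chrom and np.isfinite(interval_cov):
        if interval_cov < baseline - cn_delta and edges_neutral:
            label = "unbalanced_inversion"

    return ComplexEvent(
        sample=graph.sample,
        event_class=label,
        path=path,
        anchors=(a1, a2),
        tsis=tsis if label != "unbalanced_inversion" else [],
        evidence=evidence,
        member_sv_ids=tuple(sorted({n.sv_id for n in path.nodes})),
    )


def detect_complex_events(
    graph: BreakpointGraph,
    cn_delta: float = 0.3,
    max_breakpoints: int = 12,
) -> list[ComplexEvent]:
    """Run both search strategies over an annotated graph and classify.

    Anchored search (between genomically adjacent node pairs) targets
    bridge deletions and cycles of TSIs; depth-first enumeration of
    maximal paths targets unbalanced inversions and translocations.  One
    event is reported per distinct SV set, preferring a classified label.
    """
    candidates: list[GraphPath] = []
    for chrom in sorted({n.chrom for n in graph.nodes}):
        nodes = graph.nodes_on(chrom)
        for u, v in zip(nodes, nodes[1:]):
            if u.sv_id == v.sv_id:
                continue
            candidates.extend(
                find_anchored_paths(graph, u, v, max_breakpoints=max_breakpoints)
            )
    candidates.extend(
        p for p in enumerate_paths_dfs(graph, min_breakpoints=4) if not p.is_cycle
    )

    rank = {c: i for i, c in enumerate(EVENT_CLASSES)}
    best: dict[tuple, ComplexEvent] = {}
    for path in candidates:
        ev = classify_path(path, graph, cn_delta=cn_delta)
        key = ev.member_sv_ids
        cur = best.get(key)
        if cur is None or rank[ev.event_class] < rank[cur.event_class]:
            best[key] = ev
    # a sub-path of a classified event is shadowed by it
    kept = []
    for key, ev in best.items():
        shadowed = any(
            other is not ev
            and other.event_class != "unclassified"
            and set(key) < set(okey)
            for okey, other in best.items()
        )
        if not shadowed:
            kept.append(ev)
    return sorted(kept, key=lambda e: (rank[e.event_class], e.member_sv_ids))


# ---------------------------------------------------------------------------
# chains & chromothripsis

@dataclass
class ChainCluster:
    """A single-linkage cluster of SVs (translocations join their loci)."""

    svs: list[SVRecord]
    loci: dict[str, tuple[int, int]]  # chrom -> (min, max) breakend positions

    @property
    def n_svs(self) -> int:
        return len(self.svs)

    @property
    def n_breakpoints(self) -> int:
        return 2 * len(self.svs)


def detect_chains(
    svs: list[SVRecord], link_dist: float = 1e6, min_svs: int = 10
) -> list[ChainCluster]:
    """Single-linkage clustering of one genome's breakends within
    ``link_dist``; clusters with >= ``min_svs`` SVs are chains."""
    svs = sorted(svs, key=lambda r: (r.bp1.chrom, r.bp1.pos, r.id))
    parent = list(range(len(svs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    ends: dict[str, list[tuple[int, int]]] = {}
    for i, r in enumerate(svs):
        for bp in r.breakends:
            ends.setdefault(bp.chrom, []).append((bp.pos, i))
    for chrom, items in ends.items():
        items.sort()
        for (p1, i1), (p2, i2) in zip(items, items[1:]):
            if p2 - p1 <= link_dist:
                union(i1, i2)

    groups: dict[int, list[int]] = {}
    for i in range(len(svs)):
        groups.setdefault(find(i), []).append(i)
    chains = []
    for members in groups.values():
        if len(members) < min_svs:
            continue
        cluster = [svs[i] for i in members]
        loci: dict[str, tuple[int, int]] = {}
        for r in cluster:
            for bp in r.breakends:
                lo, hi = loci.get(bp.chrom, (bp.pos, bp.pos))
                loci[bp.chrom] = (min(lo, bp.pos), max(hi, bp.pos))
        chains.append(ChainCluster(svs=cluster, loci=loci))
    chains.sort(key=lambda c: sorted(c.loci.items()))
    return chains


INTRA_TYPES = ("deletion_type", "td_type", "head_to_head", "tail_to_tail")


def detect_chromothripsis(
    chain: ChainCluster,
    cn_segments: list[CNSegment],
    min_breakpoints: int = 8,
    oscillation_frac: float = 0.8,
    type_p_cut: float = 0.05,
) -> ComplexEvent | None:
    """Flag a chain as a chromothripsis candidate.

    Requires >= ``min_breakpoints`` breakpoints, a fraction of adjacent
    copy-number transitions alternating among the 2-3 most frequent CN
    states >= ``oscillation_frac``, and an SV-type spectrum compatible with
    a uniform multinomial over the four intra-chromosomal types
    (chi-square p > ``type_p_cut``).
    """
    if chain.n_breakpoints < min_breakpoints:
        return None

    states: list[float] = []
    for chrom, (lo, hi) in sorted(chain.loci.items()):
        segs = sorted(
            (s for s in cn_segments if s.chrom == chrom and s.end > lo and s.start < hi),
            key=lambda s: s.start,
        )
        states.extend(round(s.cn_total) for s in segs)
    if len(states) < 3:
        return None
    uniq, counts = np.unique(states, return_counts=True)
    best_frac = 0.0
    for n_states in (2, 3):
        top = set(uniq[np.argsort(counts)[::-1][:n_states]])
        trans = list(zip(states, states[1:]))
        ok = sum(1 for a, b in trans if a in top and b in top and a != b)
        frac = ok / len(trans)
        best_frac = max(best_frac, frac)
    if best_frac < oscillation_frac:
        return None

    type_counts = np.array(
        [sum(1 for r in chain.svs if r.svtype == t) for t in INTRA_TYPES]
    )
    if type_counts.sum() > 0:
        _, p = chisquare(type_counts)
        if p <= type_p_cut:
            return None

    sample = chain.svs[0].sample if chain.svs else ""
    return ComplexEvent(
        sample=sample,
        event_class="chromothripsis_candidate",
        evidence={
            "n_breakpoints": chain.n_breakpoints,
            "oscillation_frac": best_frac,
            "loci": chain.loci,
        },
        member_sv_ids=tuple(sorted(r.id for r in chain.svs)),
    )


def classify_chromothripsis_pattern(
    event: ComplexEvent,
    cn_segments: list[CNSegment],
    arms: dict[str, list[tuple[int, int]]] | None = None,
    min_breakpoints: int = 8,
) -> str:
    """Summarize a chromothripsis candidate's segment-size/spread pattern.

    * ``arm_wide_large`` — median oscillating segment >= 1 Mb spanning
      >= 50% of the arm;
    * ``localized_small`` — median segment <= 250 kb with the breakpoints
      packed into <= 10 Mb;
    * ``intermediate`` — anything else.
    """
    loci = event.evidence.get("loci", {})
    sizes: list[int] = []
    span = 0
    arm_len = 0
    for chrom, (lo, hi) in sorted(loci.items()):
        segs = [
            s for s in cn_segments if s.chrom == chrom and s.end > lo and s.start < hi
        ]
        sizes.extend(s.length for s in segs)
        span = max(span, hi - lo)
        if arms and chrom in arms:
            mid = (lo + hi) / 2
            for (a, b) in arms[chrom]:
                if a <= mid <= b:
                    arm_len = max(arm_len, b - a)
        else:
            ends = [s.end for s in cn_segments if s.chrom == chrom]
            arm_len = max(arm_len, max(ends) if ends else 0)
    if not sizes:
        return "intermediate"
    med = float(np.median(sizes))
    if med >= 1e6 and arm_len > 0 and span >= 0.5 * arm_len:
        return "arm_wide_large"
    if med <= 2.5e5 and event.evidence.get("n_breakpoints", 0) >= min_breakpoints and span <= 1e7:
        return "localized_small"
    return "intermediate"
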