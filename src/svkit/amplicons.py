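"""High-level amplicons and their driving mechanism.

Amplified segments (copy number >= arm baseline + 5 by default) are merged
into *amplicons* when a junction connects them.  Each amplicon is then
assigned a mechanism with fixed precedence:

1. **BFB** — at least two fold-back inversions inside the amplicon
   (fold-backs win over a circular structure);
2. **ecDNA** — the amplicon's junctions support a simple alternating cycle
   through pairwise-disjoint amplified sequence segments (a circular
   molecule);
3. **TD_dominated** — at least half the member junctions are tandem
   duplications (high copy arises from stacked duplications plus
   genome-doubling/arm gains);
4. **no_sv** — no breakend falls in the amplified segments;
5. **unclassified** otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bpgraph import BreakpointGraph, build_graph
from .foldback_bfb import FoldbackCall
from .records import CNSegment, SVRecord

__all__ = [
    "Amplicon",
    "find_amplified_segments",
    "group_amplicons",
    "detect_circular_structure",
    "classify_mechanism",
]


@dataclass
class Amplicon:
    sample: str
    segments: list[CNSegment]
    topology: str = "single"  # single | multi_intra | multi_inter
    mechanism: str = "unclassified"
    n_foldbacks: int = 0
    has_cycle: bool = False
    member_svs: list[SVRecord] = field(default_factory=list)

    @property
    def chroms(self) -> set[str]:
        return {s.chrom for s in self.segments}


def _arm_of(arm_table: dict[str, list[tuple[int, int]]], chrom: str, pos: float):
    if chrom not in arm_table:
        raise ValueError(f"arm table missing chromosome {chrom}")
    for (a, b) in arm_table[chrom]:
        if a <= pos < b:
            return (a, b)
    return arm_table[chrom][-1]


def find_amplified_segments(
    cn_segments: list[CNSegment],
    arm_table: dict[str, list[tuple[int, int]]],
    delta: float = 5.0,
    absolute_cn: float | None = None,
) -> list[CNSegment]:
    """Segments amplified by >= ``delta`` copies over their arm baseline.

    The baseline is the length-weighted median copy number of the
    containing chromosome arm; ``absolute_cn`` switches to a flat
    CN >= threshold rule instead.  Adjacent passing segments are merged
    (keeping the length-weighted mean CN).
    """
    by_sample_chrom: dict[tuple[str, str], list[CNSegment]] = {}
    for s in cn_segments:
        by_sample_chrom.setdefault((s.sample, s.chrom), []).append(s)

    passing: list[CNSegment] = []
    for (sample, chrom), segs in sorted(by_sample_chrom.items()):
        segs.sort(key=lambda s: s.start)
        if chrom not in arm_table:
            raise ValueError(f"arm table missing chromosome {chrom}")
        for arm in arm_table[chrom]:
            a, b = arm
            arm_segs = [s for s in segs if s.end > a and s.start < b]
            if not arm_segs:
                continue
            if absolute_cn is not None:
                cut = absolute_cn
            else:
                vals = np.repeat(
                    [s.cn_total for s in arm_segs],
                    [max(int(min(s.end, b) - max(s.start, a)) // 10_000, 1) for s in arm_segs],
                )
                baseline = float(np.median(vals))
                cut = baseline + delta
            passing.extend(s for s in arm_segs if s.cn_total >= cut)

    # merge touching passing segments per sample/chrom
    passing.sort(key=lambda s: (s.sample, s.chrom, s.start))
    merged: list[CNSegment] = []
    for s in passing:
        if (
            merged
            and merged[-1].sample == s.sample
            and merged[-1].chrom == s.chrom
            and s.start <= merged[-1].end
        ):
            prev = merged[-1]
            w1, w2 = prev.length, s.length
            merged[-1] = CNSegment(
                chrom=prev.chrom,
                start=prev.start,
                end=max(prev.end, s.end),
                cn_total=(prev.cn_total * w1 + s.cn_total * w2) / (w1 + w2),
                sample=prev.sample,
            )
        else:
            merged.append(s)
    return merged


def _in_segment(seg: CNSegment, chrom: str, pos: int, tol: int) -> bool:
    return seg.chrom == chrom and seg.start - tol <= pos <= seg.end + tol


def group_amplicons(
    amplified: list[CNSegment],
    svs: list[SVRecord],
    tol: int = 1000,
) -> list[Amplicon]:
    """Merge amplified segments connected by a junction into amplicons.

    Two segments join when one SV has a breakend in each (within ``tol``
    of the segment boundary).  Segments with no breakend at all are
    emitted as ``no_sv`` amplicons.  Output is invariant under segment
    input order.
    """
    amplified = sorted(amplified, key=lambda s: (s.sample, s.chrom, s.start))
    parent = list(range(len(amplified)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    members: dict[int, list[SVRecord]] = {i: [] for i in range(len(amplified))}
    for r in sorted(svs, key=lambda r: r.id):
        hit1 = [
            i
            for i, s in enumerate(amplified)
            if s.sample == r.sample and _in_segment(s, r.bp1.chrom, r.bp1.pos, tol)
        ]
        hit2 = [
            i
            for i, s in enumerate(amplified)
            if s.sample == r.sample and _in_segment(s, r.bp2.chrom, r.bp2.pos, tol)
        ]
        for i in set(hit1 + hit2):
            members[i].append(r)
        for i in hit1:
            for j in hit2:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(amplified)):
        groups.setdefault(find(i), []).append(i)

    amps: list[Amplicon] = []
    for idxs in groups.values():
        segs = [amplified[i] for i in sorted(idxs)]
        seen: dict[str, SVRecord] = {}
        for i in idxs:
            for r in members[i]:
                seen[r.id] = r
        member_svs = sorted(seen.values(), key=lambda r: r.id)
        chroms = {s.chrom for s in segs}
        if len(segs) == 1 and not member_svs:
            mech = "no_sv"
        else:
            mech = "unclassified"
        topology = (
            "single"
            if len(segs) == 1
            else ("multi_intra" if len(chroms) == 1 else "multi_inter")
        )
        amps.append(
            Amplicon(
                sample=segs[0].sample,
                segments=segs,
                topology=topology,
                mechanism=mech,
                member_svs=member_svs,
            )
        )
    amps.sort(key=lambda a: (a.sample, sorted((s.chrom, s.start) for s in a.segments)))
    return amps


def detect_circular_structure(
    amplicon: Amplicon, graph: BreakpointGraph | None = None, tol: int = 1000
) -> bool:
    """True iff the amplicon's junctions form a simple alternating cycle
    whose sequence segments are pairwise disjoint and lie inside the
    amplified segments.

    With ``graph=None`` a local graph is built from the member junctions
    without releasing simple SVs (a circular TD amplicon is legitimately
    cyclic).  The disjointness requirement distinguishes genuine circular
    molecules from nested tandem-duplication stacks, whose apparent cycles
    reuse overlapping reference sequence.
    """
    if not amplicon.member_svs:
        return False
    if graph is None:
        graph = build_graph(
            amplicon.member_svs, release_simple=False, sample=amplicon.sample
        )

    def inside(chrom, pos):
        return any(_in_segment(s, chrom, pos, tol) for s in amplicon.segments)

    allowed = [n for n in graph.nodes if inside(n.chrom, n.pos)]
    allowed_set = set(allowed)

    from .bpgraph import _neighbors, _node_sort_key

    found = False

    def dfs(start, node, visited, edges_types, seq_spans):
        nonlocal found
        if found:
            return
        last = edges_types[-1]
        want = "seq" if last == "sv" else "sv"
        for nxt in _neighbors(graph, node, want):
            if found:
                return
            if nxt == start and len(visited) >= 4 and len(visited) % 2 == 0:
                if want == "seq":
                    e = graph.seq_edge_between(node, nxt)
                    span = (e.chrom, e.low.pos, e.high.pos)
                    if not _spans_disjoint(seq_spans + [span]):
                        continue
                found = True
                return
            if nxt in visited or nxt not in allowed_set:
                continue
            new_spans = seq_spans
            if want == "seq":
                e = graph.seq_edge_between(node, nxt)
                span = (e.chrom, e.low.pos, e.high.pos)
                if not _spans_disjoint(seq_spans + [span]):
                    continue
                new_spans = seq_spans + [span]
            dfs(start, nxt, visited | {nxt}, edges_types + [want], new_spans)

    for start in sorted(allowed, key=_node_sort_key):
        mate = graph.sv_mate(start)
        if mate not in allowed_set:
            continue
        dfs(start, mate, {start, mate}, ["sv"], [])
        if found:
            break
    amplicon.has_cycle = found
    return found


def _spans_disjoint(spans) -> bool:
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            (c1, a1, b1), (c2, a2, b2) = spans[i], spans[j]
            if c1 == c2 and a1 < b2 and a2 < b1:
                return False
    return True


def classify_mechanism(
    amplicon: Amplicon,
    foldbacks: list[FoldbackCall],
    td_frac: float = 0.5,
    tol: int = 1000,
) -> str:
    """Assign the amplification mechanism with fixed precedence
    (BFB > ecDNA > TD_dominated > no_sv > unclassified)."""
    if amplicon.mechanism == "no_sv":
        return "no_sv"
    n_fb = 0
    for f in foldbacks:
        if f.sample and amplicon.sample and f.sample != amplicon.sample:
            continue
        if any(
            _in_segment(s, f.chrom, f.pos1, tol) or _in_segment(s, f.chrom, f.pos2, tol)
            for s in amplicon.segments
        ):
            n_fb += 1
    amplicon.n_foldbacks = n_fb
    if n_fb >= 2:
        amplicon.mechanism = "BFB"
    elif amplicon.has_cycle or detect_circular_structure(amplicon, tol=tol):
        amplicon.mechanism = "ecDNA"
    elif amplicon.member_svs and (
        sum(1 for r in amplicon.member_svs if r.svtype == "td_type")
        / len(amplicon.member_svs)
        >= td_frac
    ):
        amplicon.mechanism = "TD_dominated"
    elif not amplicon.member_svs:
        amplicon.mechanism = "no_sv"
    else:
        amplicon.mechanism = "unclassified"
    return amplicon.mechanism
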