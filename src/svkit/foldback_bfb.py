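"""Fold-back inversion detection, TSI fold-backs, and BFB inference.

A fold-back inversion is a single inversion-type junction (both breakends
the same orientation) whose ends lie close together (< 100 kb), lacking a
reciprocal partner, and sitting on a copy-number step — the hallmark of a
breakage-fusion-bridge (BFB) cycle.  BFB additionally requires telomere
loss on the fold-back's distal side.  A *TSI fold-back* is a fold-back
whose two breakends are connected through cycles of templated insertions
rather than directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .bpgraph import BreakpointGraph, GraphPath
from .complex_events import TSI, classify_tsi_origin
from .records import CNSegment, CoverageTrack, SVRecord

__all__ = [
    "FoldbackCall",
    "TSIFoldback",
    "detect_foldback_inversions",
    "infer_bfb",
    "detect_tsi_foldback",
    "link_coamplified_foldbacks",
]

FOLDBACK_TYPES = {"head_to_head": "++", "tail_to_tail": "--"}


@dataclass
class FoldbackCall:
    sample: str
    sv_id: str
    chrom: str
    pos1: int
    pos2: int
    orient_pair: str  # "++" or "--"
    end_distance: int
    cn_step: float
    q_value: float
    reciprocal: bool
    telomere_loss: bool | None = None
    is_bfb: bool | None = None


def _rank_sum_p(left: np.ndarray, right: np.ndarray) -> float:
    """Two-sided rank-sum p for a coverage step; degenerate windows (all
    values identical) are handled explicitly."""
    if left.size < 3 or right.size < 3:
        return 1.0
    if np.allclose(left, left[0]) and np.allclose(right, right[0]):
        return 0.0 if not np.isclose(left[0], right[0]) else 1.0
    try:
        return float(mannwhitneyu(left, right, alternative="two-sided").pvalue)
    except ValueError:
        return 1.0


def detect_foldback_inversions(
    svs: list[SVRecord],
    track: CoverageTrack,
    max_dist: float = 1e5,
    q_cut: float = 1e-3,
    recip_window: float = 5e3,
    n_flank_bins: int = 20,
) -> list[FoldbackCall]:
    """Detect simple fold-back inversions in one genome.

    A candidate is a head-to-head or tail-to-tail junction with end
    distance < ``max_dist`` and no reciprocal (opposite-orientation)
    inversion whose breakends both lie within ``recip_window``.  The
    copy-number step is tested by a two-sided rank-sum on ``n_flank_bins``
    coverage bins per side, Benjamini-Hochberg corrected across
    candidates; calls require q < ``q_cut``.  Output is invariant to SV
    input order.
    """
    if track is None:
        raise ValueError("coverage track required for fold-back detection")
    svs = sorted(svs, key=lambda r: (r.bp1.chrom, r.bp1.pos, r.bp2.pos, r.id))
    inversions = [r for r in svs if r.svtype in FOLDBACK_TYPES]
    candidates = []
    for r in inversions:
        if r.bp2.pos - r.bp1.pos >= max_dist:
            continue
        reciprocal = any(
            o is not r
            and o.svtype in FOLDBACK_TYPES
            and o.svtype != r.svtype
            and abs(o.bp1.pos - r.bp1.pos) <= recip_window
            and abs(o.bp2.pos - r.bp2.pos) <= recip_window
            and o.bp1.chrom == r.bp1.chrom
            for o in inversions
        )
        candidates.append((r, reciprocal))

    calls = []
    pvals = []
    flank = n_flank_bins * track.bin_size
    for r, reciprocal in candidates:
        chrom = r.bp1.chrom
        left = track.values(chrom, r.bp1.pos - flank, r.bp1.pos)
        right = track.values(chrom, r.bp2.pos, r.bp2.pos + flank)
        step = float(np.median(left) - np.median(right)) if left.size and right.size else 0.0
        p = 1.0 if reciprocal else _rank_sum_p(left, right)
        pvals.append(p)
        calls.append(
            FoldbackCall(
                sample=r.sample,
                sv_id=r.id,
                chrom=chrom,
                pos1=r.bp1.pos,
                pos2=r.bp2.pos,
                orient_pair=FOLDBACK_TYPES[r.svtype],
                end_distance=r.bp2.pos - r.bp1.pos,
                cn_step=step,
                q_value=1.0,
                reciprocal=reciprocal,
            )
        )
    if calls:
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for c, q in zip(calls, qvals):
            c.q_value = float(q)
    return [c for c in calls if not c.reciprocal and c.q_value < q_cut]


def infer_bfb(
    foldbacks: list[FoldbackCall],
    cn_segments: list[CNSegment],
    telo_window: float = 1e6,
    loss_copies: float = 1.0,
) -> list[FoldbackCall]:
    """Set ``telomere_loss`` and ``is_bfb`` on fold-back calls.

    The distal side of a '++' fold-back is the higher-coordinate
    chromosome end, of a '--' fold-back the lower end.  Telomere loss
    means the mean copy number of the terminal ``telo_window`` on that
    side sits at least ``loss_copies`` below the arm baseline (the
    length-weighted median CN of the fold-back's chromosome).
    """
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in cn_segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for v in by_chrom.values():
        v.sort(key=lambda s: s.start)

    def weighted_median_cn(segs):
        if not segs:
            return float("nan")
        vals = np.repeat(
            [s.cn_total for s in segs],
            [max(int(s.length // 1e4), 1) for s in segs],
        )
        return float(np.median(vals))

    def mean_cn(segs, lo, hi):
        tot, wsum = 0.0, 0.0
        for s in segs:
            ov = min(s.end, hi) - max(s.start, lo)
            if ov > 0:
                tot += s.cn_total * ov
                wsum += ov
        return tot / wsum if wsum else float("nan")

    for c in foldbacks:
        segs = by_chrom.get(c.chrom, [])
        if not segs:
            c.telomere_loss = False
            c.is_bfb = False
            continue
        chrom_start = segs[0].start
        chrom_end = segs[-1].end
        baseline = weighted_median_cn(segs)
        if c.orient_pair == "++":
            term = mean_cn(segs, chrom_end - telo_window, chrom_end)
        else:
            term = mean_cn(segs, chrom_start, chrom_start + telo_window)
        c.telomere_loss = bool(np.isfinite(term) and term <= baseline - loss_copies)
        c.is_bfb = c.telomere_loss
    return foldbacks


@dataclass
class TSIFoldback:
    sample: str
    chrom: str
    terminal1: int
    terminal2: int
    orient: str
    tsis: list[TSI]
    stepped_cn: bool
    category: str  # local | distal | interchromosomal
    path: GraphPath | None = None


def detect_tsi_foldback(
    graph: BreakpointGraph,
    paths: list[GraphPath],
    max_dist: float = 1e5,
    cn_delta: float = 0.3,
) -> list[TSIFoldback]:
    """Find fold-backs bridged by templated insertions among graph paths.

    A hit is a path whose two terminal breakends share orientation on one
    chromosome, < ``max_dist`` apart, carrying >= 1 sequence edge elevated
    above the local baseline.  Category: interchromosomal if any template
    comes from another chromosome, otherwise the majority local/distal
    origin.  ``stepped_cn`` is set when the coverage on the fold-back's
    retained side shows >= 2 distinct increasing levels.
    """
    if graph.track is None:
        raise ValueError("graph must be coverage-annotated")
    track = graph.track
    hits = []
    for path in paths:
        a1, a2 = path.anchors
        if a1.chrom != a2.chrom or a1.orient != a2.orient:
            continue
        if abs(a2.pos - a1.pos) >= max_dist:
            continue
        seq_edges = path.seq_edges(graph)
        if not seq_edges:
            continue
        tsis = []
        exclude = [
            (e.chrom, e.low.pos - graph.flank, e.high.pos + graph.flank)
            for e in seq_edges
        ]
        lo, hi = sorted((a1.pos, a2.pos))
        exclude.append((a1.chrom, lo - graph.flank, hi + graph.flank))
        elevated = 0
        for e in seq_edges:
            base = graph.local_baseline(e.chrom, e.low.pos, e.high.pos, exclude)
            t = TSI(e.chrom, e.low.pos, e.high.pos)
            t.origin_class = classify_tsi_origin(t, (a1.chrom, a1.pos))
            tsis.append(t)
            if e.mean_cov is not None and e.mean_cov > base + cn_delta:
                elevated += 1
        if elevated == 0:
            continue
        if any(t.origin_class == "interchromosomal" for t in tsis):
            category = "interchromosomal"
        else:
            n_local = sum(1 for t in tsis if t.origin_class == "local")
            category = "local" if n_local >= len(tsis) / 2 else "distal"
        # stepped CN: distinct increasing coverage levels on the retained side
        span = 5e5
        if a1.orient == "+":
            win_lo, win_hi = lo - span, lo
        else:
            win_lo, win_hi = hi, hi + span
        vals = track.values(a1.chrom, win_lo, win_hi)
        base = graph.local_baseline(a1.chrom, lo, hi, exclude)
        levels = sorted({round(float(v) / cn_delta) for v in vals if v > base + cn_delta / 2})
        stepped = len(levels) >= 2
        hits.append(
            TSIFoldback(
                sample=graph.sample,
                chrom=a1.chrom,
                terminal1=a1.pos,
                terminal2=a2.pos,
                orient=a1.orient * 2,
                tsis=tsis,
                stepped_cn=stepped,
                category=category,
                path=path,
            )
        )
    hits.sort(key=lambda h: (h.chrom, h.terminal1, h.terminal2))
    return hits


def link_coamplified_foldbacks(
    foldbacks: list[FoldbackCall],
    graph: BreakpointGraph,
    amplicons,
) -> list[dict]:
    """Pairs of fold-back-bearing amplified loci on one chromosome joined
    by a single alternating graph chain.

    Returns one record per linked pair with the connecting path.
    """
    from .bpgraph import find_anchored_paths

    def segment_nodes(amp):
        nodes = []
        for seg in amp.segments:
            for n in graph.nodes:
                if n.chrom == seg.chrom and seg.start - 1e4 <= n.pos <= seg.end + 1e4:
                    nodes.append(n)
        return nodes

    def has_foldback(amp):
        for seg in amp.segments:
            for f in foldbacks:
                if f.chrom == seg.chrom and (
                    seg.start - 1e4 <= f.pos1 <= seg.end + 1e4
                    or seg.start - 1e4 <= f.pos2 <= seg.end + 1e4
                ):
                    return True
        return False

    linked = []
    amps = [a for a in amplicons if has_foldback(a)]
    for i in range(len(amps)):
        for j in range(i + 1, len(amps)):
            a, b = amps[i], amps[j]
            chroms_a = {s.chrom for s in a.segments}
            chroms_b = {s.chrom for s in b.segments}
            if not (chroms_a & chroms_b):
                continue
            found = None
            for u in segment_nodes(a):
                for v in segment_nodes(b):
                    ps = find_anchored_paths(graph, u, v, max_breakpoints=12)
                    if ps:
                        found = ps[0]
                        break
                if found:
                    break
            if found is not None:
                linked.append({"amplicon_a": a, "amplicon_b": b, "path": found})
    return linked
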