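"""Rearrangement-hotspot detection via piecewise-constant fitting (PCF).

Breakpoints of one signature, pooled across a cohort, are scanned per
chromosome.  PCF is run on the log10 inter-breakpoint distances (short
distances mean locally dense rearrangement); segments are converted to a
breakpoints-per-Mb density and kept as hotspots when that density exceeds
``min_ratio`` times the genome-wide background of the signature and the
breakpoints come from at least ``min_samples`` distinct genomes.

``pcf_segment`` is an exact penalized-least-squares segmentation solved by
dynamic programming: it minimizes sum of squared residuals + gamma per
additional segment, with every segment at least ``kmin`` points long.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DensitySegment", "Hotspot", "pcf_segment", "call_hotspots"]


@dataclass
class DensitySegment:
    chrom: str
    start: int
    end: int
    mean_density: float  # breakpoints per Mb
    n_breakpoints: int
    n_samples: int


@dataclass
class Hotspot:
    segment: DensitySegment
    signature: str
    density_ratio: float


def pcf_segment(
    values, gamma: float = 25.0, kmin: int = 10
) -> tuple[list[tuple[int, int]], list[float]]:
    """Exact penalized least-squares piecewise-constant fit.

    Minimizes ``sum_j SSE(segment_j) + gamma * (n_segments - 1)`` over all
    segmentations whose segments each contain >= ``kmin`` points, by
    O(n^2) dynamic programming.  Deterministic.  Returns half-open index
    segments and their means; fewer than ``kmin`` points yield a single
    segment.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return [], []
    if n < 2 * kmin:
        return [(0, n)], [float(x.mean())]
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    INF = float("inf")
    best = np.full(n + 1, INF)
    back = np.zeros(n + 1, dtype=int)
    best[0] = -gamma  # first segment carries no penalty
    for j in range(kmin, n + 1):
        for i in range(0, j - kmin + 1):
            if best[i] == INF:
                continue
            cand = best[i] + gamma + sse(i, j)
            if cand < best[j] - 1e-12:
                best[j] = cand
                back[j] = i
    bounds = []
    j = n
    while j > 0:
        i = int(back[j])
        bounds.append((i, j))
        j = i
    bounds.reverse()
    means = [float(x[i:j].mean()) for i, j in bounds]
    return bounds, means


def call_hotspots(
    breakpoints: pd.DataFrame,
    chrom_lengths: dict[str, int],
    signature: str = "",
    gamma: float = 25.0,
    kmin: int = 10,
    min_samples: int = 15,
    min_ratio: float = 2.0,
) -> list[Hotspot]:
    """Call hotspots from pooled breakpoints of one signature.

    ``breakpoints`` needs columns ``chrom``, ``pos``, ``sample``.  The
    background is this signature's genome-wide breakpoint density; PCF is
    run per chromosome on log10 inter-breakpoint distance, segments are
    converted to density, and passing adjacent segments are merged.
    """
    if breakpoints.empty:
        return []
    for col in ("chrom", "pos", "sample"):
        if col not in breakpoints.columns:
            raise ValueError(f"breakpoints table missing column {col!r}")
    total = len(breakpoints)
    genome_len = float(sum(chrom_lengths.values()))
    background = total / (genome_len / 1e6)  # per Mb

    hotspots: list[Hotspot] = []
    for chrom, group in breakpoints.groupby("chrom", sort=True):
        group = group.sort_values("pos")
        pos = group["pos"].to_numpy()
        samples = group["sample"].to_numpy()
        if pos.size < 2:
            continue
        dist = np.diff(pos).astype(float)
        logd = np.log10(dist + 1.0)
        bounds, _means = pcf_segment(logd, gamma=gamma, kmin=kmin)

        passing: list[tuple[int, int]] = []  # breakpoint index ranges [i, j]
        for (i, j) in bounds:
            # distance indices [i, j) involve breakpoints i .. j
            span = pos[j] - pos[i]
            n_bp = j - i + 1
            if span <= 0:
                continue
            density = n_bp / (span / 1e6)
            if density >= min_ratio * background:
                passing.append((i, j))
        # merge adjacent passing ranges
        merged: list[list[int]] = []
        for (i, j) in passing:
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            n_bp = j - i + 1
            span = int(pos[j] - pos[i])
            density = n_bp / (span / 1e6)
            n_samp = len(set(samples[i : j + 1]))
            if n_samp < min_samples:
                continue
            ratio = density / background
            if ratio < min_ratio:
                continue
            hotspots.append(
                Hotspot(
                    segment=DensitySegment(
                        chrom=chrom,
                        start=int(pos[i]),
                        end=int(pos[j]),
                        mean_density=density,
                        n_breakpoints=n_bp,
                        n_samples=n_samp,
                    ),
                    signature=signature,
                    density_ratio=ratio,
                )
            )
    return hotspots


def breakpoint_table(svs) -> pd.DataFrame:
    """Both breakends of each intra-chromosomal SV and each translocation
    end contribute one row to the density table."""
    rows = []
    for r in svs:
        for bp in r.breakends:
            rows.append({"chrom": bp.chrom, "pos": bp.pos, "sample": r.sample})
    return pd.DataFrame(rows, columns=["chrom", "pos", "sample"])
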