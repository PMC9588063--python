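"""Core domain types for somatic structural-variation analysis.

A structural variant (SV) is a junction joining two oriented breakends.
Orientation semantics: ``'+'`` means the reference bases at coordinates
<= pos are joined into the junction (the left flank survives); ``'-'``
means bases >= pos are joined (the right flank survives).  The
(orientation1, orientation2) pair of a coordinate-sorted intra-chromosomal
junction determines its type:

====================  ===========
orientations          svtype
====================  ===========
(+, -)                deletion_type
(-, +)                td_type (tandem duplication)
(+, +)                head_to_head inversion
(-, -)                tail_to_tail inversion
different chromosome  translocation
====================  ===========

All positions are 0-based internally; readers/writers convert at the I/O
boundary (BEDPE starts are 0-based already, VCF POS is 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ORIENTS = ("+", "-")
SV_TYPES = (
    "deletion_type",
    "td_type",
    "head_to_head",
    "tail_to_tail",
    "translocation",
)
SIMPLE_STATUSES = ("simple", "non_simple", "unset")


@dataclass(frozen=True, order=True)
class Breakpoint:
    """One oriented breakend of a junction (0-based position); ordered by
    (chrom, pos, orient, sv_id, mate_index)."""

    chrom: str
    pos: int
    orient: str
    sv_id: str = ""
    mate_index: int = 1

    def __post_init__(self) -> None:
        if self.orient not in ORIENTS:
            raise ValueError(f"invalid orientation {self.orient!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def classify_sv_type(bp1: Breakpoint, bp2: Breakpoint) -> str:
    """Classify a junction from its two breakends (canonical order assumed).

    Total and deterministic over the 2x2 orientation grid; any
    inter-chromosomal junction is a translocation.
    """
    if bp1.chrom != bp2.chrom:
        return "translocation"
    key = (bp1.orient, bp2.orient)
    return {
        ("+", "-"): "deletion_type",
        ("-", "+"): "td_type",
        ("+", "+"): "head_to_head",
        ("-", "-"): "tail_to_tail",
    }[key]


@dataclass
class SVRecord:
    """One somatic junction: two oriented breakends plus junction evidence.

    ``mh_len`` (microhomology) and ``ins_len`` (untemplated insertion) are
    mutually exclusive pieces of junction-resolution evidence; at most one
    may be positive.
    """

    id: str
    bp1: Breakpoint
    bp2: Breakpoint
    svtype: str = ""
    mh_len: int = 0
    ins_len: int = 0
    ins_seq: str | None = None
    qual: float = 0.0
    sample: str = ""
    simple_status: str = "unset"

    def __post_init__(self) -> None:
        self.canonicalize()
        if self.mh_len < 0 or self.ins_len < 0:
            raise ValueError(f"{self.id}: negative mh_len/ins_len")
        if self.mh_len > 0 and self.ins_len > 0:
            raise ValueError(
                f"{self.id}: mh_len and ins_len cannot both be positive"
            )

    def canonicalize(self) -> None:
        """Order breakends: by position intra-chromosomally, lexicographically
        for translocations; (re)derive svtype and mate indices."""
        a, b = self.bp1, self.bp2
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            a, b = b, a
        self.bp1 = replace(a, sv_id=self.id, mate_index=1)
        self.bp2 = replace(b, sv_id=self.id, mate_index=2)
        self.svtype = classify_sv_type(self.bp1, self.bp2)

    @property
    def is_intra(self) -> bool:
        return self.bp1.chrom == self.bp2.chrom

    @property
    def size(self) -> int | None:
        """Span in bp for intra-chromosomal junctions; None for translocations."""
        if not self.is_intra:
            return None
        return self.bp2.pos - self.bp1.pos

    @property
    def breakends(self) -> tuple[Breakpoint, Breakpoint]:
        return (self.bp1, self.bp2)


@dataclass(frozen=True)
class CNSegment:
    """A total-copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    cn_total: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CN segment {self.chrom}:{self.start}-{self.end} is empty"
            )
        if self.cn_total < 0:
            raise ValueError("negative copy number")

    @property
    def length(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Binned normalized coverage (tumor/normal ratio; 1.0 ~ 2 copies).

    Bins have one fixed width per track and are contiguous per chromosome.
    """

    def __init__(self, bin_size: int, sample: str = ""):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.sample = sample
        self._chroms: dict[str, tuple[int, np.ndarray]] = {}

    def add_chrom(self, chrom: str, start0: int, values) -> None:
        vals = np.asarray(values, dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"negative coverage value on {chrom}")
        self._chroms[chrom] = (int(start0), vals)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def values(self, chrom: str, start: float, end: float) -> np.ndarray:
        """Values of bins overlapping [start, end)."""
        if chrom not in self._chroms:
            raise KeyError(f"no coverage for chromosome {chrom}")
        start0, vals = self._chroms[chrom]
        lo = int(np.floor((start - start0) / self.bin_size))
        hi = int(np.ceil((end - start0) / self.bin_size))
        lo = max(lo, 0)
        hi = min(max(hi, lo), len(vals))
        return vals[lo:hi]

    def mean(self, chrom: str, start: float, end: float) -> float:
        v = self.values(chrom, start, end)
        return float(np.mean(v)) if v.size else float("nan")

    def median(self, chrom: str, start: float, end: float) -> float:
        v = self.values(chrom, start, end)
        return float(np.median(v)) if v.size else float("nan")

    def median_excluding(
        self,
        chrom: str,
        start: float,
        end: float,
        exclude: list[tuple[str, float, float]],
    ) -> float:
        """Median over [start, end) bins, dropping bins that overlap any
        excluded span (used for 'locally non-affected' baselines)."""
        if chrom not in self._chroms:
            raise KeyError(f"no coverage for chromosome {chrom}")
        start0, vals = self._chroms[chrom]
        lo = max(int(np.floor((start - start0) / self.bin_size)), 0)
        hi = min(int(np.ceil((end - start0) / self.bin_size)), len(vals))
        if hi <= lo:
            return float("nan")
        idx = np.arange(lo, hi)
        bin_lo = start0 + idx * self.bin_size
        bin_hi = bin_lo + self.bin_size
        keep = np.ones(idx.shape, dtype=bool)
        for (c, s, e) in exclude:
            if c != chrom:
                continue
            keep &= ~((bin_lo < e) & (bin_hi > s))
        sel = vals[idx[keep]]
        if sel.size == 0:
            sel = vals[idx]
        return float(np.median(sel))

    def iter_bins(self, chrom: str):
        start0, vals = self._chroms[chrom]
        for i, v in enumerate(vals):
            s = start0 + i * self.bin_size
            yield s, s + self.bin_size, float(v)
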