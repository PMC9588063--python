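"""Ground-truth simulator: synthetic cohorts of simple SVs drawn from
size-mixture presets, planted complex events with internally consistent
copy-number profiles, and rendered coverage tracks.

Every planted event is built from the derivative-allele segment walk it
implies: the junctions, the copy-number deltas and the templated-insertion
list all derive from one construction, so rendered coverage always matches
the emitted SV calls exactly at zero noise.  Each event carries a
:class:`TruthRecord` so inference modules can be scored against known
truth.

Size presets (log-normal mixture modes) ship for the three intra-
chromosomal SV classes as observed in esophageal squamous-cell carcinoma
genomes: tandem duplications at 12 kb / 213 kb / 1170 kb, deletions at
1.7 kb / 105 kb / 9.7 Mb, inversions at 3 kb / 4.1 Mb.  Component sigmas
(0.25 log10 units) and equal weights are package defaults chosen for
clear mode separation, not published values.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .records import Breakpoint, CNSegment, CoverageTrack, SVRecord
from . import sv_io

__all__ = [
    "GenomeModel",
    "SizePreset",
    "SIZE_PRESETS",
    "TruthRecord",
    "PlantedEvent",
    "SimCohort",
    "make_toy_genome",
    "draw_sizes",
    "simulate_simple_cohort",
    "plant_complex_event",
    "render_coverage",
    "emit_cohort",
]

COMPLEX_CLASSES = (
    "bridge_deletion",
    "tsi_cycle",
    "unbalanced_inversion",
    "unbalanced_translocation_tsi",
    "tsi_foldback",
    "simple_foldback",
    "reciprocal_inversion",
    "bfb_ladder",
    "ecdna",
    "chromothripsis",
    "td_stack",
)


@dataclass
class GenomeModel:
    """A toy reference: chromosome lengths, centromeres, base ploidy."""

    lengths: dict[str, int]
    centromeres: dict[str, int]
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        for c, L in self.lengths.items():
            if L <= 0:
                raise ValueError(f"{c}: non-positive length")
            if not 0 < self.centromeres[c] < L:
                raise ValueError(f"{c}: centromere outside chromosome")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def arms(self) -> dict[str, list[tuple[int, int]]]:
        return {
            c: [(0, self.centromeres[c]), (self.centromeres[c], L)]
            for c, L in self.lengths.items()
        }


def make_toy_genome(n_chrom: int = 3, length: int = 50_000_000, seed: int = 0) -> GenomeModel:
    """Deterministic toy genome; centromeres at 40% of each chromosome."""
    lengths = {f"chr{i + 1}": int(length) for i in range(n_chrom)}
    cents = {c: int(0.4 * L) for c, L in lengths.items()}
    return GenomeModel(lengths=lengths, centromeres=cents)


@dataclass
class SizePreset:
    name: str
    sv_class: str
    medians_bp: tuple[float, ...]
    sigmas_log10: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("preset weights must sum to 1")


def _preset(name, sv_class, medians):
    k = len(medians)
    return SizePreset(
        name=name,
        sv_class=sv_class,
        medians_bp=tuple(medians),
        sigmas_log10=(0.25,) * k,
        weights=(1.0 / k,) * k,
    )


SIZE_PRESETS: dict[str, SizePreset] = {
    "escc-td": _preset("escc-td", "TD", (12e3, 213e3, 1170e3)),
    "escc-del": _preset("escc-del", "DEL", (1.7e3, 105e3, 9.7e6)),
    "escc-inv": _preset("escc-inv", "INV", (3e3, 4.1e6)),
}


def draw_sizes(preset: SizePreset, n: int, seed: int = 0) -> np.ndarray:
    """Draw n sizes (bp) from a log-normal mixture preset."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(preset.weights), size=n, p=preset.weights)
    mu = np.log10(np.asarray(preset.medians_bp))[comp]
    sd = np.asarray(preset.sigmas_log10)[comp]
    return 10.0 ** rng.normal(mu, sd)


@dataclass
class TruthRecord:
    event_id: str
    sample: str
    event_class: str
    sv_ids: tuple[str, ...]
    breakends: tuple[tuple[str, int, str], ...] = ()
    cn_deltas: tuple[tuple[str, int, int, float], ...] = ()
    tsis: tuple[tuple[str, int, int, str], ...] = ()  # chrom,start,end,origin
    info: dict = field(default_factory=dict)


@dataclass
class PlantedEvent:
    svs: list[SVRecord]
    cn_deltas: list[tuple[str, int, int, float]]
    truth: TruthRecord


class CNProfile:
    """Piecewise-constant total copy number built from planted deltas."""

    def __init__(self, genome: GenomeModel, sample: str = ""):
        self.genome = genome
        self.sample = sample
        self._deltas: dict[str, list[tuple[int, int, float]]] = {
            c: [] for c in genome.chroms
        }

    def add(self, chrom: str, start: int, end: int, delta: float) -> None:
        if chrom not in self._deltas:
            raise KeyError(f"unknown chromosome {chrom}")
        start = max(int(start), 0)
        end = min(int(end), self.genome.lengths[chrom])
        if end > start:
            self._deltas[chrom].append((start, end, float(delta)))

    def cn_at_bins(self, chrom: str, bin_size: int) -> np.ndarray:
        L = self.genome.lengths[chrom]
        n = int(np.ceil(L / bin_size))
        cn = np.full(n, self.genome.ploidy, dtype=float)
        for (s, e, d) in self._deltas[chrom]:
            lo = int(s // bin_size)
            hi = int(np.ceil(e / bin_size))
            cn[lo:hi] += d
        np.maximum(cn, 0.0, out=cn)
        return cn

    def segments(self) -> list[CNSegment]:
        segs = []
        for chrom in self.genome.chroms:
            L = self.genome.lengths[chrom]
            points = {0, L}
            for (s, e, _) in self._deltas[chrom]:
                points.update((s, e))
            pts = sorted(points)
            prev_cn = None
            run_start = 0
            for a, b in zip(pts, pts[1:]):
                mid = (a + b) / 2
                cn = self.genome.ploidy + sum(
                    d for (s, e, d) in self._deltas[chrom] if s <= mid < e
                )
                cn = max(cn, 0.0)
                if prev_cn is None:
                    prev_cn, run_start = cn, a
                elif not np.isclose(cn, prev_cn):
                    segs.append(CNSegment(chrom, run_start, a, prev_cn, self.sample))
                    prev_cn, run_start = cn, a
            segs.append(CNSegment(chrom, run_start, L, prev_cn, self.sample))
        return segs


def render_coverage(
    genome: GenomeModel,
    profile: CNProfile,
    bin_size: int = 10_000,
    noise_sd: float = 0.0,
    purity: float = 1.0,
    seed: int = 0,
) -> CoverageTrack:
    """Render a normalized tumor/normal coverage track from a CN profile.

    Bin value = purity * CN/ploidy + (1 - purity) * 1 + Gaussian noise,
    clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    track = CoverageTrack(bin_size=bin_size, sample=profile.sample)
    for chrom in genome.chroms:
        cn = profile.cn_at_bins(chrom, bin_size)
        vals = purity * cn / genome.ploidy + (1.0 - purity)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        track.add_chrom(chrom, 0, np.maximum(vals, 0.0))
    return track


# ---------------------------------------------------------------------------
# simple SV cohorts

_MECH_BANDS = {
    "NHEJ": lambda rng: (int(rng.integers(0, 2)), 0),
    "alt_EJ": lambda rng: (int(rng.integers(2, 101)), 0),
    "NAHR": lambda rng: (int(rng.integers(101, 251)), 0),
    "FoSTeS_MMBIR": lambda rng: (0, int(rng.integers(11, 51))),
}

_TYPE_ORIENTS = {
    "deletion_type": ("+", "-"),
    "td_type": ("-", "+"),
    "head_to_head": ("+", "+"),
    "tail_to_tail": ("-", "-"),
}

_CLASS_PRESET = {
    "deletion_type": "escc-del",
    "td_type": "escc-td",
    "head_to_head": "escc-inv",
    "tail_to_tail": "escc-inv",
}


def _place_interval(rng, genome: GenomeModel, size: int, margin: int = 2_000_000):
    """Uniform placement avoiding centromere +- 1 Mb; resamples on overflow."""
    for _ in range(200):
        chrom = genome.chroms[int(rng.integers(len(genome.chroms)))]
        L = genome.lengths[chrom]
        if size >= L - 2 * margin:
            continue
        start = int(rng.integers(margin, L - margin - size))
        cent = genome.centromeres[chrom]
        if start < cent + 1_000_000 and start + size > cent - 1_000_000:
            continue
        return chrom, start
    raise RuntimeError("could not place interval; genome too small for size")


def simulate_simple_cohort(
    genome: GenomeModel,
    n_samples: int = 5,
    counts: dict[str, int] | None = None,
    presets: dict[str, str] | None = None,
    mechanism_mix: dict[str, float] | None = None,
    seed: int = 0,
    cn_effects: bool = False,
) -> "SimCohort":
    """Simulate genomes carrying independent simple SVs.

    ``counts`` gives per-sample SV counts by type (default 30 TDs, 30
    deletions, 10+10 inversions, 5 translocations); sizes are drawn from
    the named presets; junction microhomology/insertion lengths are drawn
    inside each planted mechanism's rule band.  Fully seeded; with
    ``cn_effects`` TDs/deletions also shift the copy-number profile.
    """
    counts = counts or {
        "deletion_type": 30,
        "td_type": 30,
        "head_to_head": 10,
        "tail_to_tail": 10,
        "translocation": 5,
    }
    presets = presets or dict(_CLASS_PRESET)
    mechanism_mix = mechanism_mix or {"NHEJ": 0.45, "alt_EJ": 0.4, "NAHR": 0.05, "FoSTeS_MMBIR": 0.1}
    mechs = sorted(mechanism_mix)
    probs = np.array([mechanism_mix[m] for m in mechs], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    cohort = SimCohort(genome=genome)
    for si in range(n_samples):
        sample = f"S{si + 1:03d}"
        cohort.add_sample(sample)
        idx = 0
        for svtype in sorted(counts):
            n = counts[svtype]
            for _ in range(n):
                idx += 1
                sv_id = f"{sample}_sv{idx:05d}"
                mech = mechs[int(rng.choice(len(mechs), p=probs))]
                mh, ins = _MECH_BANDS[mech](rng)
                if svtype == "translocation":
                    c1, p1 = _place_interval(rng, genome, 1)
                    c2, p2 = _place_interval(rng, genome, 1)
                    while c2 == c1:
                        c2, p2 = _place_interval(rng, genome, 1)
                    o1 = "+" if rng.random() < 0.5 else "-"
                    o2 = "+" if rng.random() < 0.5 else "-"
                    rec = SVRecord(
                        id=sv_id,
                        bp1=Breakpoint(c1, p1, o1),
                        bp2=Breakpoint(c2, p2, o2),
                        mh_len=mh,
                        ins_len=ins,
                        sample=sample,
                    )
                else:
                    # largest interval placeable on either side of a centromere
                    limit = max(
                        max(cent - 3_000_000, L - cent - 3_000_000)
                        for cent, L in (
                            (genome.centromeres[c], genome.lengths[c])
                            for c in genome.chroms
                        )
                    ) - 1
                    size = limit
                    while size >= limit:  # oversize draws are resampled
                        size = int(
                            draw_sizes(
                                SIZE_PRESETS[presets[svtype]], 1,
                                seed=int(rng.integers(2**31)),
                            )[0]
                        )
                    size = max(size, 50)
                    chrom, start = _place_interval(rng, genome, size)
                    o1, o2 = _TYPE_ORIENTS[svtype]
                    rec = SVRecord(
                        id=sv_id,
                        bp1=Breakpoint(chrom, start, o1),
                        bp2=Breakpoint(chrom, start + size, o2),
                        mh_len=mh,
                        ins_len=ins,
                        sample=sample,
                    )
                    if cn_effects and svtype in ("td_type", "deletion_type"):
                        delta = 1.0 if svtype == "td_type" else -1.0
                        cohort.profiles[sample].add(chrom, start, start + size, delta)
                cohort.svs.append(rec)
                cohort.truth.append(
                    TruthRecord(
                        event_id=sv_id,
                        sample=sample,
                        event_class=f"simple_{svtype}",
                        sv_ids=(sv_id,),
                        breakends=tuple(
                            (bp.chrom, bp.pos, bp.orient) for bp in rec.breakends
                        ),
                        info={"mechanism": mech},
                    )
                )
    return cohort


# ---------------------------------------------------------------------------
# planted complex events

def _template_locus(rng, genome, chrom, anchor, origin, size, side=-1, used=(),
                    exclude_chroms=()):
    """Pick a template segment for a TSI of the requested origin class.

    ``side`` fixes which flank of the anchor same-chromosome templates land
    on (-1 left / +1 right); overlap with ``used`` intervals is resampled.
    """
    for _ in range(100):
        if origin == "interchromosomal":
            others = [
                c for c in genome.chroms if c != chrom and c not in exclude_chroms
            ]
            tc = others[int(rng.integers(len(others)))]
            L = genome.lengths[tc]
            s = int(rng.integers(2_000_000, L - 2_000_000 - size))
        else:
            if origin == "local":
                off = int(rng.integers(300_000, 900_000))
            else:  # distal
                off = int(rng.integers(2_000_000, 6_000_000))
            tc = chrom
            s = anchor + side * off
            L = genome.lengths[chrom]
            s = int(np.clip(s, 1_500_000, L - 1_500_000 - size))
        if all(
            uc != tc or s >= ue + 50_000 or s + size <= us - 50_000
            for (uc, us, ue) in used
        ):
            return tc, s
    raise RuntimeError("could not place a non-overlapping template")


def plant_complex_event(
    genome: GenomeModel,
    event_class: str,
    params: dict | None = None,
    seed: int = 0,
    sample: str = "S001",
    event_id: str | None = None,
) -> PlantedEvent:
    """Plant one complex event; returns its junctions, CN deltas and truth.

    Supported classes: bridge_deletion, tsi_cycle, unbalanced_inversion,
    unbalanced_translocation_tsi, tsi_foldback, simple_foldback,
    reciprocal_inversion, bfb_ladder, ecdna, chromothripsis, td_stack.
    """
    if event_class not in COMPLEX_CLASSES:
        raise ValueError(f"unknown event class {event_class!r}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    event_id = event_id or f"{sample}_{event_class}_{seed}"
    chrom = params.get("chrom", genome.chroms[0])
    L = genome.lengths[chrom]
    cent = genome.centromeres[chrom]
    # default anchor well inside the q arm, away from centromere/telomere
    default_center = int(cent + 0.4 * (L - cent))
    center = int(params.get("center", default_center))

    svs: list[SVRecord] = []
    deltas: list[tuple[str, int, int, float]] = []
    tsis: list[tuple[str, int, int, str]] = []
    info: dict = {}
    n = [0]

    def new_sv(bp1, bp2, mh=2, ins=0):
        n[0] += 1
        svs.append(
            SVRecord(
                id=f"{event_id}_j{n[0]}",
                bp1=bp1,
                bp2=bp2,
                mh_len=mh,
                ins_len=ins,
                sample=sample,
            )
        )

    def make_templates(n_tsis, origin, tsi_size, anchor, side=-1, exclude_chroms=()):
        out = []
        used = []
        for _ in range(n_tsis):
            tc, ts = _template_locus(
                rng, genome, chrom, anchor, origin, tsi_size, side=side, used=used,
                exclude_chroms=exclude_chroms,
            )
            out.append((tc, ts, ts + tsi_size))
            used.append((tc, ts, ts + tsi_size))
            tsis.append((tc, ts, ts + tsi_size, origin))
        return out

    def chain_junctions(p0: Breakpoint, q: Breakpoint, templates, delta):
        """Walk p0 -> templates -> q.  Each template is entered in the
        orientation of the previous breakend, so template-to-template
        junctions are inversion-type and survive simple-SV release."""
        prev = p0
        for (tc, ts, te) in templates:
            if prev.orient == "+":
                entry, exit_ = Breakpoint(tc, te, "+"), Breakpoint(tc, ts, "-")
            else:
                entry, exit_ = Breakpoint(tc, ts, "-"), Breakpoint(tc, te, "+")
            new_sv(prev, entry)
            deltas.append((tc, ts, te, delta))
            prev = exit_
        new_sv(prev, q)

    if event_class == "bridge_deletion":
        del_size = int(params.get("del_size", 100_000))
        n_tsis = int(params.get("n_tsis", 2))
        if n_tsis < 1:
            raise ValueError("bridge_deletion requires >= 1 TSI")
        tsi_size = int(params.get("tsi_size", 5_000))
        origin = params.get("tsi_origin", "local")
        A, B = center, center + del_size
        templates = make_templates(n_tsis, origin, tsi_size, A, side=-1)
        chain_junctions(
            Breakpoint(chrom, A, "+"), Breakpoint(chrom, B, "-"), templates, +1.0
        )
        deltas.append((chrom, A, B, -1.0))
        info["anchors"] = (A, B)

    elif event_class == "tsi_cycle":
        dup_size = int(params.get("dup_size", 100_000))
        n_tsis = int(params.get("n_tsis", 1))
        if n_tsis < 1:
            raise ValueError("tsi_cycle requires >= 1 TSI")
        tsi_size = int(params.get("tsi_size", 5_000))
        origin = params.get("tsi_origin", "interchromosomal")
        A, B = center, center + dup_size
        templates = make_templates(n_tsis, origin, tsi_size, B, side=+1)
        chain_junctions(
            Breakpoint(chrom, B, "+"), Breakpoint(chrom, A, "-"), templates, +1.0
        )
        deltas.append((chrom, A, B, +1.0))
        info["anchors"] = (A, B)

    elif event_class == "unbalanced_inversion":
        inv_size = int(params.get("inv_size", 200_000))
        loss_size = int(params.get("loss_size", 400_000))
        p = center
        q = p + loss_size
        r = q + inv_size
        s = r + loss_size
        new_sv(Breakpoint(chrom, p, "+"), Breakpoint(chrom, r, "+"))
        new_sv(Breakpoint(chrom, q, "-"), Breakpoint(chrom, s, "-"))
        deltas.append((chrom, p, q, -1.0))
        deltas.append((chrom, r, s, -1.0))
        info["anchors"] = (p, s)

    elif event_class == "unbalanced_translocation_tsi":
        n_tsis = int(params.get("n_tsis", 1))
        if n_tsis < 1:
            raise ValueError("unbalanced_translocation_tsi requires >= 1 TSI")
        tsi_size = int(params.get("tsi_size", 5_000))
        origin = params.get("tsi_origin", "distal")
        others = [c for c in genome.chroms if c != chrom]
        chromB = params.get("chrom2", others[0])
        LB = genome.lengths[chromB]
        b = int(params.get("center2", genome.centromeres[chromB] + 0.5 * (LB - genome.centromeres[chromB])))
        a = center
        templates = make_templates(
            n_tsis, origin, tsi_size, a, side=-1, exclude_chroms={chromB}
        )
        chain_junctions(
            Breakpoint(chrom, a, "+"), Breakpoint(chromB, b, "-"), templates, +1.0
        )
        deltas.append((chrom, a, L, -1.0))
        deltas.append((chromB, b, LB, +1.0))
        info["anchors"] = ((chrom, a), (chromB, b))

    elif event_class == "tsi_foldback":
        gap = int(params.get("gap", 50_000))
        n_tsis = int(params.get("n_tsis", 1))
        if n_tsis < 1:
            raise ValueError("tsi_foldback requires >= 1 TSI")
        tsi_size = int(params.get("tsi_size", 5_000))
        origin = params.get("tsi_origin", "local")
        f1, f2 = center, center + gap
        templates = make_templates(n_tsis, origin, tsi_size, f1, side=-1)
        chain_junctions(
            Breakpoint(chrom, f1, "+"), Breakpoint(chrom, f2, "+"), templates, +2.0
        )
        # stepped amplification on the retained (left) side, telomere loss distal
        deltas.append((chrom, f1 - 400_000, f1 - 200_000, +1.0))
        deltas.append((chrom, f1 - 200_000, f1, +2.0))
        deltas.append((chrom, f2, L, -1.0))
        info["anchors"] = (f1, f2)

    elif event_class == "simple_foldback":
        gap = int(params.get("gap", 20_000))
        orient = params.get("orient", "++")
        cn_step = float(params.get("cn_step", 2.0))
        telomere_loss = bool(params.get("telomere_loss", True))
        step_span = int(params.get("step_span", 2_000_000))
        p, q = center, center + gap
        o = orient[0]
        new_sv(Breakpoint(chrom, p, o), Breakpoint(chrom, q, o))
        if orient == "++":
            deltas.append((chrom, p - step_span, p, +cn_step))
            if telomere_loss:
                deltas.append((chrom, q, L, -1.0))
        else:
            deltas.append((chrom, q, q + step_span, +cn_step))
            if telomere_loss:
                deltas.append((chrom, 0, p, -1.0))
        info["anchors"] = (p, q)

    elif event_class == "reciprocal_inversion":
        size = int(params.get("size", 50_000))
        p, q = center, center + size
        new_sv(Breakpoint(chrom, p, "+"), Breakpoint(chrom, q, "+"))
        new_sv(Breakpoint(chrom, p + 100, "-"), Breakpoint(chrom, q + 100, "-"))
        info["anchors"] = (p, q)

    elif event_class == "bfb_ladder":
        rounds = int(params.get("rounds", 3))
        spacing = int(params.get("spacing", 1_000_000))
        gap = int(params.get("gap", 20_000))
        # fold-backs from distal (f_1) to proximal (f_rounds); each round
        # adds copies proximally and the terminal segment is lost
        f = [center + (rounds - i) * spacing for i in range(1, rounds + 1)]
        # f[0] most distal ... f[-1] most proximal
        deltas.append((chrom, f[0] + gap, L, -1.0))
        for i in range(rounds):
            new_sv(Breakpoint(chrom, f[i], "+"), Breakpoint(chrom, f[i] + gap, "+"))
        for i in range(1, rounds):
            deltas.append((chrom, f[i], f[i - 1], 5.0 + 2.0 * (i - 1)))
        deltas.append((chrom, f[-1] - 2_000_000, f[-1], 5.0 + 2.0 * (rounds - 1)))
        info["foldback_positions"] = f

    elif event_class == "ecdna":
        seg_size = int(params.get("seg_size", 500_000))
        gap = int(params.get("gap", 1_000_000))
        target_cn = float(params.get("target_cn", 20.0))
        a, b = center, center + seg_size
        c, d = b + gap, b + gap + seg_size
        new_sv(Breakpoint(chrom, b, "+"), Breakpoint(chrom, c, "-"))
        new_sv(Breakpoint(chrom, d, "+"), Breakpoint(chrom, a, "-"))
        amp = target_cn - genome.ploidy
        deltas.append((chrom, a, b, amp))
        deltas.append((chrom, c, d, amp))
        info["segments"] = ((a, b), (c, d))

    elif event_class == "chromothripsis":
        n_svs = int(params.get("n_svs", 10))
        seg_size = int(params.get("seg_size", 300_000))
        start = int(params.get("start", center - n_svs * seg_size))
        pts = [start + i * seg_size + int(rng.integers(0, seg_size // 4)) for i in range(2 * n_svs)]
        pts.sort()
        # alternate retained / lost segments -> oscillating 2-state CN
        for i in range(1, len(pts) - 1, 2):
            deltas.append((chrom, pts[i], pts[i + 1], -1.0))
        ends = list(pts)
        rng.shuffle(ends)
        type_cycle = ["deletion_type", "td_type", "head_to_head", "tail_to_tail"]
        for i in range(0, len(ends) - 1, 2):
            x, y = sorted((ends[i], ends[i + 1]))
            o1, o2 = _TYPE_ORIENTS[type_cycle[(i // 2) % 4]]
            new_sv(Breakpoint(chrom, x, o1), Breakpoint(chrom, y, o2), mh=0, ins=20)
        info["region"] = (pts[0], pts[-1])

    elif event_class == "td_stack":
        core = int(params.get("core_size", 200_000))
        n_tds = int(params.get("n_tds", 5))
        step = int(params.get("step", 20_000))
        for i in range(n_tds):
            a = center - i * step
            b = center + core + i * step
            new_sv(Breakpoint(chrom, a, "-"), Breakpoint(chrom, b, "+"))
            deltas.append((chrom, a, b, +1.0))
        info["core"] = (center, center + core)

    truth = TruthRecord(
        event_id=event_id,
        sample=sample,
        event_class=event_class,
        sv_ids=tuple(r.id for r in svs),
        breakends=tuple((bp.chrom, bp.pos, bp.orient) for r in svs for bp in r.breakends),
        cn_deltas=tuple((c, int(s), int(e), float(d)) for (c, s, e, d) in deltas),
        tsis=tuple(tsis),
        info=info,
    )
    return PlantedEvent(svs=svs, cn_deltas=deltas, truth=truth)


# ---------------------------------------------------------------------------
# cohort container & emission

@dataclass
class SimCohort:
    genome: GenomeModel
    svs: list[SVRecord] = field(default_factory=list)
    profiles: dict[str, CNProfile] = field(default_factory=dict)
    truth: list[TruthRecord] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.profiles)

    def add_sample(self, sample: str) -> None:
        if sample not in self.profiles:
            self.profiles[sample] = CNProfile(self.genome, sample=sample)

    def add_event(self, event: PlantedEvent) -> None:
        sample = event.truth.sample
        self.add_sample(sample)
        self.svs.extend(event.svs)
        for (c, s, e, d) in event.cn_deltas:
            self.profiles[sample].add(c, s, e, d)
        self.truth.append(event.truth)

    def plant(self, event_class: str, sample: str, params=None, seed: int = 0,
              event_id: str | None = None) -> PlantedEvent:
        ev = plant_complex_event(
            self.genome, event_class, params=params, seed=seed, sample=sample,
            event_id=event_id,
        )
        self.add_event(ev)
        return ev

    def sample_svs(self, sample: str) -> list[SVRecord]:
        return [r for r in self.svs if r.sample == sample]

    def cn_segments(self, sample: str) -> list[CNSegment]:
        return self.profiles[sample].segments()

    def coverage(self, sample: str, bin_size: int = 10_000, noise_sd: float = 0.0,
                 purity: float = 1.0, seed: int = 0) -> CoverageTrack:
        return render_coverage(
            self.genome, self.profiles[sample], bin_size=bin_size,
            noise_sd=noise_sd, purity=purity, seed=seed,
        )


def emit_cohort(
    cohort: SimCohort,
    out_dir: str,
    bin_size: int = 10_000,
    noise_sd: float = 0.0,
    purity: float = 1.0,
    seed: int = 0,
    force: bool = False,
) -> dict[str, str]:
    """Write a cohort to disk: BEDPE, CN BED, per-sample bedGraph coverage,
    truth manifest TSV and chrom.sizes; re-readable by :mod:`svkit.sv_io`
    with zero loss.  Refuses to write into a non-empty directory unless
    ``force``."""
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["bedpe"] = os.path.join(out_dir, "svs.bedpe")
    sv_io.write_bedpe(cohort.svs, paths["bedpe"])
    segs = []
    for sample in cohort.samples:
        segs.extend(cohort.cn_segments(sample))
    paths["cn_bed"] = os.path.join(out_dir, "cn_segments.bed")
    sv_io.write_cn_segments(segs, paths["cn_bed"])
    for i, sample in enumerate(cohort.samples):
        track = cohort.coverage(
            sample, bin_size=bin_size, noise_sd=noise_sd, purity=purity,
            seed=seed + i,
        )
        p = os.path.join(out_dir, f"{sample}.coverage.bedgraph")
        sv_io.write_coverage(track, p)
        paths[f"coverage:{sample}"] = p
    paths["chrom_sizes"] = os.path.join(out_dir, "chrom.sizes")
    with open(paths["chrom_sizes"], "w") as fh:
        for c, Ln in cohort.genome.lengths.items():
            fh.write(f"{c}\t{Ln}\n")
    paths["truth"] = os.path.join(out_dir, "truth.tsv")
    with open(paths["truth"], "w") as fh:
        fh.write("event_id\tsample\tevent_class\tsv_ids\tcn_deltas\ttsis\n")
        for t in cohort.truth:
            fh.write(
                "\t".join(
                    [
                        t.event_id,
                        t.sample,
                        t.event_class,
                        ",".join(t.sv_ids),
                        json.dumps(list(t.cn_deltas)),
                        json.dumps(list(t.tsis)),
                    ]
                )
                + "\n"
            )
    return paths
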