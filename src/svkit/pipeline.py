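"""End-to-end orchestration: classify -> signatures -> graph -> complex ->
fold-back -> hotspots -> amplicons, with per-sample and cohort summaries.

The run configuration is a plain dict (typically loaded from JSON); every
analysis threshold surfaces as a named key with the package default.  A
machine-readable manifest with the effective parameters and package
version is written next to the outputs so a run can be replayed exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__, sv_io
from .amplicons import classify_mechanism, find_amplified_segments, group_amplicons
from .bpgraph import annotate_coverage, build_graph, enumerate_paths_dfs
from .complex_events import (
    detect_chains,
    detect_chromothripsis,
    detect_complex_events,
)
from .foldback_bfb import detect_foldback_inversions, detect_tsi_foldback, infer_bfb
from .hotspots import breakpoint_table, call_hotspots
from .signatures import (
    SV_CLASS_OF_TYPE,
    call_mechanisms,
    call_tdp_status,
    classify_instability,
    compute_tdp,
    fit_size_gmm,
    assign_signature,
)

DEFAULTS = {
    "seed": 0,
    "max_span": 5e6,
    "max_seq_edges": 2,
    "flank": 1e4,
    "cn_delta": 0.3,
    "foldback_max_dist": 1e5,
    "foldback_q_cut": 1e-3,
    "recip_window": 5e3,
    "telo_window": 1e6,
    "amplify_delta": 5.0,
    "min_foldbacks_bfb": 2,
    "chain_link_dist": 1e6,
    "chain_min_svs": 10,
    "ct_min_breakpoints": 8,
    "oscillation_frac": 0.8,
    "hotspot_min_samples": 15,
    "hotspot_min_ratio": 2.0,
    "pcf_gamma": 25.0,
    "pcf_kmin": 10,
    "gmm_k": None,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: dict) -> dict:
    """Run the full pipeline from a configuration dict.

    Required keys: ``bedpe`` (SV calls), ``out_dir``.  Optional: ``cn_bed``,
    ``coverage`` (mapping sample -> bedGraph path, or one path for a
    single-sample run), ``chrom_sizes``, ``arms`` and any parameter from
    :data:`DEFAULTS`.  Unknown keys are rejected.
    """
    known = set(DEFAULTS) | {
        "bedpe", "cn_bed", "coverage", "chrom_sizes", "arms", "out_dir",
        "log_level",
    }
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULTS, **config}
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {"version": __version__, "parameters": {
        k: cfg[k] for k in DEFAULTS}, "stages": []}

    def stage(name):
        report["stages"].append(name)

    try:
        stage("read")
        svs = sv_io.read_bedpe(cfg["bedpe"])
        chrom_sizes = (
            sv_io.read_chrom_sizes(cfg["chrom_sizes"]) if cfg.get("chrom_sizes") else None
        )
        cn_segments = sv_io.read_cn_segments(cfg["cn_bed"]) if cfg.get("cn_bed") else []
        coverage_cfg = cfg.get("coverage") or {}
        samples = sorted({r.sample for r in svs})
    except StageError:
        raise
    except Exception as exc:
        raise StageError("read", exc) from exc

    try:
        stage("classify")
        by_sample = {
            s: sv_io.classify_simple_status([r for r in svs if r.sample == s])
            for s in samples
        }
        sv_io.write_records(
            [r for s in samples for r in by_sample[s]],
            os.path.join(out_dir, "svs.classified.tsv"),
        )
    except Exception as exc:
        raise StageError("classify", exc) from exc

    summary_rows = []
    try:
        stage("signatures")
        mech = {m.sv_id: m.mechanism for m in call_mechanisms(svs)}
        models = {}
        for fam in ("TD", "DEL", "INV"):
            sizes = [
                r.size for r in svs
                if r.is_intra and SV_CLASS_OF_TYPE.get(r.svtype) == fam and r.size > 0
            ]
            if len(sizes) >= 50:
                models[fam] = fit_size_gmm(sizes, fam, k=cfg["gmm_k"], seed=cfg["seed"])
        sig = {}
        for r in svs:
            fam = SV_CLASS_OF_TYPE.get(r.svtype)
            if fam in models and r.size and r.size > 0:
                sig[r.id] = assign_signature(r, models[fam])
        rows = [
            {
                "id": r.id, "sample": r.sample, "svtype": r.svtype,
                "simple_status": r.simple_status,
                "signature": sig.get(r.id, "."), "mechanism": mech.get(r.id, "."),
            }
            for s in samples for r in by_sample[s]
        ]
        pd.DataFrame(rows).to_csv(
            os.path.join(out_dir, "sv_signatures.tsv"), sep="\t", index=False
        )
    except Exception as exc:
        raise StageError("signatures", exc) from exc

    try:
        stage("tdp_instability")
        tdp_rows = []
        if chrom_sizes:
            results = []
            for s in samples:
                tds = [r for r in by_sample[s] if r.svtype == "td_type"]
                if tds:
                    results.append(compute_tdp(tds, chrom_sizes, sample=s))
            if len(results) >= 10:
                call_tdp_status(results, seed=cfg["seed"])
            tdp_rows = [
                {"sample": r.sample, "td_total": r.td_total,
                 "tdp_score": r.tdp_score, "is_tdp": r.is_tdp}
                for r in results
            ]
        burdens = {
            s: sv_io.simple_sv_burden(by_sample[s]) for s in samples
        }
        calls = classify_instability(burdens) if len(burdens) >= 2 else []
        groups = {c.sample: c.group for c in calls}
        for s in samples:
            summary_rows.append(
                {"sample": s, "n_svs": len(by_sample[s]),
                 "simple_sv_burden": burdens[s],
                 "instability": groups.get(s, ".")}
            )
        if tdp_rows:
            pd.DataFrame(tdp_rows).to_csv(
                os.path.join(out_dir, "tdp.tsv"), sep="\t", index=False
            )
    except Exception as exc:
        raise StageError("tdp_instability", exc) from exc

    events_rows, foldback_rows, tsi_fb_rows = [], [], []
    graphs = {}
    try:
        stage("graph_complex_foldback")
        if isinstance(coverage_cfg, str):
            coverage_cfg = {samples[0]: coverage_cfg} if len(samples) == 1 else {}
        for s in samples:
            if s not in coverage_cfg:
                continue
            track = sv_io.read_coverage(coverage_cfg[s], sample=s)
            g = build_graph(
                by_sample[s], max_span=cfg["max_span"],
                max_seq_edges=int(cfg["max_seq_edges"]),
            )
            annotate_coverage(g, track, flank=cfg["flank"])
            graphs[s] = g
            for ev in detect_complex_events(g, cn_delta=cfg["cn_delta"]):
                events_rows.append(
                    {"sample": s, "event_class": ev.event_class,
                     "n_breakpoints": ev.path.n_breakpoints if ev.path else 0,
                     "sv_ids": ",".join(ev.member_sv_ids),
                     "n_tsis": len(ev.tsis)}
                )
            fbs = detect_foldback_inversions(
                by_sample[s], track, max_dist=cfg["foldback_max_dist"],
                q_cut=cfg["foldback_q_cut"], recip_window=cfg["recip_window"],
            )
            sample_cn = [c for c in cn_segments if c.sample == s]
            if sample_cn:
                infer_bfb(fbs, sample_cn, telo_window=cfg["telo_window"])
            foldback_rows.extend(
                {"sample": s, "sv_id": f.sv_id, "chrom": f.chrom,
                 "pos1": f.pos1, "pos2": f.pos2, "orient": f.orient_pair,
                 "cn_step": f.cn_step, "q_value": f.q_value,
                 "telomere_loss": f.telomere_loss, "is_bfb": f.is_bfb}
                for f in fbs
            )
            paths = enumerate_paths_dfs(g)
            for h in detect_tsi_foldback(g, paths, max_dist=cfg["foldback_max_dist"],
                                         cn_delta=cfg["cn_delta"]):
                tsi_fb_rows.append(
                    {"sample": s, "chrom": h.chrom, "terminal1": h.terminal1,
                     "terminal2": h.terminal2, "category": h.category,
                     "stepped_cn": h.stepped_cn, "n_tsis": len(h.tsis)}
                )
            chains = detect_chains(
                by_sample[s], link_dist=cfg["chain_link_dist"],
                min_svs=int(cfg["chain_min_svs"]),
            )
            for ch in chains:
                ev = detect_chromothripsis(
                    ch, sample_cn, min_breakpoints=int(cfg["ct_min_breakpoints"]),
                    oscillation_frac=cfg["oscillation_frac"],
                ) if sample_cn else None
                events_rows.append(
                    {"sample": s,
                     "event_class": ev.event_class if ev else "chain",
                     "n_breakpoints": ch.n_breakpoints,
                     "sv_ids": ",".join(r.id for r in ch.svs), "n_tsis": 0}
                )
        if events_rows:
            pd.DataFrame(events_rows).to_csv(
                os.path.join(out_dir, "complex_events.tsv"), sep="\t", index=False
            )
        if foldback_rows:
            pd.DataFrame(foldback_rows).to_csv(
                os.path.join(out_dir, "foldbacks.tsv"), sep="\t", index=False
            )
        if tsi_fb_rows:
            pd.DataFrame(tsi_fb_rows).to_csv(
                os.path.join(out_dir, "tsi_foldbacks.tsv"), sep="\t", index=False
            )
    except Exception as exc:
        raise StageError("graph_complex_foldback", exc) from exc

    try:
        stage("hotspots")
        if chrom_sizes:
            bp = breakpoint_table([r for r in svs if r.svtype == "td_type"])
            hs = call_hotspots(
                bp, chrom_sizes, signature="TD",
                gamma=cfg["pcf_gamma"], kmin=int(cfg["pcf_kmin"]),
                min_samples=int(cfg["hotspot_min_samples"]),
                min_ratio=cfg["hotspot_min_ratio"],
            )
            with open(os.path.join(out_dir, "hotspots.bed"), "w") as fh:
                for h in hs:
                    fh.write(
                        f"{h.segment.chrom}\t{h.segment.start}\t{h.segment.end}\t"
                        f"{h.signature}\t{h.density_ratio:.2f}\t{h.segment.n_samples}\n"
                    )
    except Exception as exc:
        raise StageError("hotspots", exc) from exc

    amp_rows = []
    try:
        stage("amplicons")
        if cn_segments:
            arms = cfg.get("arms")
            if arms is None and chrom_sizes:
                arms = {c: [(0, L)] for c, L in chrom_sizes.items()}
            if arms is not None:
                for s in samples:
                    sample_cn = [c for c in cn_segments if c.sample == s]
                    if not sample_cn:
                        continue
                    segs = find_amplified_segments(
                        sample_cn, arms, delta=cfg["amplify_delta"]
                    )
                    amps = group_amplicons(segs, by_sample[s])
                    fbs = [
                        f for f in foldback_rows if f["sample"] == s
                    ]
                    from .foldback_bfb import FoldbackCall

                    fb_calls = [
                        FoldbackCall(
                            sample=f["sample"], sv_id=f["sv_id"], chrom=f["chrom"],
                            pos1=f["pos1"], pos2=f["pos2"], orient_pair=f["orient"],
                            end_distance=f["pos2"] - f["pos1"], cn_step=f["cn_step"],
                            q_value=f["q_value"], reciprocal=False,
                        )
                        for f in fbs
                    ]
                    for a in amps:
                        classify_mechanism(a, fb_calls)
                        amp_rows.append(
                            {"sample": s, "topology": a.topology,
                             "mechanism": a.mechanism,
                             "n_segments": len(a.segments),
                             "n_foldbacks": a.n_foldbacks,
                             "has_cycle": a.has_cycle,
                             "segments": ";".join(
                                 f"{x.chrom}:{x.start}-{x.end}" for x in a.segments)}
                        )
            if amp_rows:
                pd.DataFrame(amp_rows).to_csv(
                    os.path.join(out_dir, "amplicons.tsv"), sep="\t", index=False
                )
    except Exception as exc:
        raise StageError("amplicons", exc) from exc

    stage("summary")
    pd.DataFrame(summary_rows).to_csv(
        os.path.join(out_dir, "sample_summary.tsv"), sep="\t", index=False
    )
    report["n_samples"] = len(samples)
    report["n_svs"] = len(svs)
    report["n_complex_events"] = len(events_rows)
    report["n_foldbacks"] = len(foldback_rows)
    report["n_amplicons"] = len(amp_rows)
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def version_info(as_json: bool = False) -> str:
    info = {"tool": "svkit", "version": __version__, "parameter_schema": "1"}
    if as_json:
        return json.dumps(info)
    return f"svkit {__version__} (parameter schema 1)"
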