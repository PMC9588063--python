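"""Simulator: determinism, conservation between SVs/CN/coverage, presets."""

import numpy as np
import pytest

from svkit import sv_io
from svkit.signatures import fit_size_gmm, infer_repair_mechanism
from svkit.simulate import (
    SIZE_PRESETS,
    SimCohort,
    draw_sizes,
    emit_cohort,
    make_toy_genome,
    plant_complex_event,
    render_coverage,
    simulate_simple_cohort,
)


class TestGenome:
    def test_defaults(self):
        g = make_toy_genome()
        assert len(g.lengths) == 3
        assert all(L == 50_000_000 for L in g.lengths.values())
        assert all(c == 20_000_000 for c in g.centromeres.values())

    def test_single_chromosome(self):
        g = make_toy_genome(n_chrom=1)
        assert g.chroms == ["chr1"]

    def test_seed_determinism(self):
        assert make_toy_genome(seed=5) == make_toy_genome(seed=5)

    def test_invalid_centromere_rejected(self):
        from svkit.simulate import GenomeModel

        with pytest.raises(ValueError, match="centromere"):
            GenomeModel(lengths={"chr1": 100}, centromeres={"chr1": 200})


class TestSimpleCohort:
    def test_gmm_recovers_preset_medians(self, genome):
        cohort = simulate_simple_cohort(
            genome, n_samples=1, counts={"td_type": 1000}, seed=21
        )
        sizes = [r.size for r in cohort.svs]
        m = fit_size_gmm(sizes, "TD", k=3, seed=0)
        for got, want in zip(m.component_medians_bp, SIZE_PRESETS["escc-td"].medians_bp):
            assert abs(got - want) / want < 0.25  # small n per component

    def test_pure_nhej_mix_respects_rule_band(self, genome):
        cohort = simulate_simple_cohort(
            genome, n_samples=2, mechanism_mix={"NHEJ": 1.0}, seed=2
        )
        assert all(r.mh_len <= 1 and r.ins_len == 0 for r in cohort.svs)
        assert all(
            infer_repair_mechanism(r.mh_len, r.ins_len) == "NHEJ" for r in cohort.svs
        )

    def test_planted_mechanisms_roundtrip_through_rule(self, genome):
        cohort = simulate_simple_cohort(genome, n_samples=2, seed=3)
        truth = {t.event_id: t.info["mechanism"] for t in cohort.truth}
        for r in cohort.svs:
            assert infer_repair_mechanism(r.mh_len, r.ins_len) == truth[r.id]

    def test_positions_avoid_centromere(self, genome):
        cohort = simulate_simple_cohort(genome, n_samples=2, seed=4)
        for r in cohort.svs:
            if r.is_intra:
                cent = genome.centromeres[r.bp1.chrom]
                assert not (
                    r.bp1.pos < cent + 1_000_000 and r.bp2.pos > cent - 1_000_000
                )

    def test_byte_identical_given_seed(self, genome, tmp_path):
        a = simulate_simple_cohort(genome, n_samples=2, seed=9)
        b = simulate_simple_cohort(genome, n_samples=2, seed=9)
        pa, pb = tmp_path / "a.bedpe", tmp_path / "b.bedpe"
        sv_io.write_bedpe(a.svs, pa)
        sv_io.write_bedpe(b.svs, pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestPlantComplex:
    def test_bridge_deletion_bookkeeping(self, genome):
        ev = plant_complex_event(
            genome, "bridge_deletion", params={"n_tsis": 2}, seed=1
        )
        assert len(ev.svs) == 3
        deltas = {d[3] for d in ev.cn_deltas}
        assert deltas == {1.0, -1.0}
        assert sum(1 for d in ev.cn_deltas if d[3] == 1.0) == 2  # one per TSI
        assert len(ev.truth.tsis) == 2

    def test_ecdna_reaches_target_cn(self, genome):
        ev = plant_complex_event(
            genome, "ecdna", params={"target_cn": 20}, seed=2, sample="S1"
        )
        co = SimCohort(genome=genome)
        co.add_event(ev)
        segs = co.cn_segments("S1")
        assert max(s.cn_total for s in segs) == 20

    def test_bfb_ladder_stepped_and_terminal_loss(self, genome):
        ev = plant_complex_event(genome, "bfb_ladder", params={"rounds": 3}, seed=3, sample="S1")
        assert len(ev.svs) == 3
        assert all(r.svtype == "head_to_head" for r in ev.svs)
        co = SimCohort(genome=genome)
        co.add_event(ev)
        segs = [s for s in co.cn_segments("S1") if s.chrom == ev.svs[0].bp1.chrom]
        assert segs[-1].cn_total == 1.0  # telomere loss
        amped = sorted({s.cn_total for s in segs if s.cn_total > 2})
        assert len(amped) >= 3  # stepped ladder

    def test_inconsistent_params_rejected(self, genome):
        with pytest.raises(ValueError, match="TSI"):
            plant_complex_event(genome, "tsi_cycle", params={"n_tsis": 0})
        with pytest.raises(ValueError, match="unknown event class"):
            plant_complex_event(genome, "nonsense")

    def test_every_sv_maps_to_one_truth_record(self, genome):
        co = SimCohort(genome=genome)
        for i, k in enumerate(("bridge_deletion", "ecdna", "td_stack")):
            co.plant(k, f"S{i}", seed=i)
        owner = {}
        for t in co.truth:
            for sid in t.sv_ids:
                assert sid not in owner
                owner[sid] = t.event_id
        assert set(owner) == {r.id for r in co.svs}


class TestRenderCoverage:
    def test_pure_ratio_arithmetic(self, genome):
        from svkit.simulate import CNProfile

        prof = CNProfile(genome, sample="S1")
        prof.add("chr1", 1_000_000, 2_000_000, 2.0)  # CN 4
        t = render_coverage(genome, prof, noise_sd=0.0, purity=1.0)
        assert t.mean("chr1", 1_000_000, 2_000_000) == 2.0
        assert t.mean("chr1", 5_000_000, 6_000_000) == 1.0

    def test_purity_mixing(self, genome):
        from svkit.simulate import CNProfile

        prof = CNProfile(genome, sample="S1")
        prof.add("chr1", 1_000_000, 2_000_000, 2.0)
        t = render_coverage(genome, prof, purity=0.5)
        assert t.mean("chr1", 1_000_000, 2_000_000) == pytest.approx(1.5)

    def test_noise_sd_calibrated(self, genome):
        from svkit.simulate import CNProfile

        prof = CNProfile(genome, sample="S1")
        t = render_coverage(genome, prof, noise_sd=0.05, seed=3)
        vals = t.values("chr1", 0, 50_000_000)
        assert abs(np.std(vals) - 0.05) / 0.05 < 0.2

    def test_conservation_cn_equals_truth_plus_baseline(self, genome):
        co = SimCohort(genome=genome)
        ev = co.plant("bridge_deletion", "S1", seed=6)
        track = co.coverage("S1", noise_sd=0.0)
        for (chrom, s, e, d) in ev.truth.cn_deltas:
            assert track.mean(chrom, s, e) == pytest.approx((2 + d) / 2)


class TestEmit:
    def test_emit_read_cycle_lossless(self, genome, tmp_path):
        co = simulate_simple_cohort(genome, n_samples=2, seed=5)
        paths = emit_cohort(co, tmp_path / "out")
        back = sv_io.read_bedpe(paths["bedpe"])
        assert len(back) == len(co.svs)
        segs = sv_io.read_cn_segments(paths["cn_bed"])
        assert segs
        track = sv_io.read_coverage(paths[f"coverage:{co.samples[0]}"])
        assert track.bin_size == 10_000

    def test_manifest_row_count_matches_truth(self, genome, tmp_path):
        co = simulate_simple_cohort(genome, n_samples=1, seed=6)
        paths = emit_cohort(co, tmp_path / "out")
        rows = open(paths["truth"]).read().splitlines()
        assert len(rows) - 1 == len(co.truth)

    def test_refuses_nonempty_dir_without_force(self, genome, tmp_path):
        co = simulate_simple_cohort(genome, n_samples=1, seed=7)
        out = tmp_path / "out"
        emit_cohort(co, out)
        with pytest.raises(FileExistsError):
            emit_cohort(co, out)
        emit_cohort(co, out, force=True)

    def test_same_seed_identical_files(self, genome, tmp_path):
        for d in ("a", "b"):
            co = simulate_simple_cohort(genome, n_samples=1, seed=8)
            emit_cohort(co, tmp_path / d, seed=8)
        fa = (tmp_path / "a" / "svs.bedpe").read_bytes()
        fb = (tmp_path / "b" / "svs.bedpe").read_bytes()
        assert fa == fb
        ca = (tmp_path / "a" / "S001.coverage.bedgraph").read_bytes()
        cb = (tmp_path / "b" / "S001.coverage.bedgraph").read_bytes()
        assert ca == cb
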