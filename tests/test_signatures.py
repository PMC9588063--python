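"""Size-mixture fitting, repair mechanisms, TDP scoring, instability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from svkit.signatures import (
    SizeMixtureModel,
    assign_signature,
    call_tdp_status,
    classify_instability,
    compute_tdp,
    fit_size_gmm,
    infer_repair_mechanism,
    TDPResult,
)
from svkit.simulate import SIZE_PRESETS, draw_sizes

from conftest import make_sv


class TestFitSizeGmm:
    def test_single_lognormal_recovers_median(self):
        rng = np.random.default_rng(0)
        sizes = 10 ** rng.normal(4.0, 0.2, 10_000)  # median 10 kb
        m = fit_size_gmm(sizes, "TD", seed=0)
        assert m.k == 1
        assert abs(m.component_medians_bp[0] - 1e4) / 1e4 < 0.05

    def test_escc_td_preset_three_modes(self):
        sizes = draw_sizes(SIZE_PRESETS["escc-td"], 30_000, seed=1)
        m = fit_size_gmm(sizes, "TD", k=3, seed=1)
        for got, want in zip(m.component_medians_bp, (12e3, 213e3, 1170e3)):
            assert abs(got - want) / want < 0.15

    def test_equal_weight_components_recovered(self):
        rng = np.random.default_rng(3)
        sizes = np.concatenate(
            [10 ** rng.normal(3.5, 0.2, 5000), 10 ** rng.normal(5.5, 0.2, 5000)]
        )
        m = fit_size_gmm(sizes, "DEL", k=2, seed=3)
        assert np.allclose(m.weights, 0.5, atol=0.03)

    def test_parameter_recovery_separated_mixture(self):
        # component medians >= 0.8 log10 units apart: 15% relative recovery
        rng = np.random.default_rng(7)
        true = np.array([3.0, 3.9, 5.0])
        comp = rng.integers(0, 3, 30_000)
        sizes = 10 ** rng.normal(true[comp], 0.2)
        m = fit_size_gmm(sizes, "TD", k=3, seed=7)
        assert np.all(
            np.abs(m.component_medians_bp - 10 ** true) / 10 ** true < 0.15
        )

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">=50"):
            fit_size_gmm([100.0] * 10, "TD")
        with pytest.raises(ValueError, match="positive"):
            fit_size_gmm([100.0] * 60 + [-1.0], "TD")

    def test_deterministic_given_seed(self):
        sizes = draw_sizes(SIZE_PRESETS["escc-inv"], 2000, seed=5)
        a = fit_size_gmm(sizes, "INV", k=2, seed=9)
        b = fit_size_gmm(sizes, "INV", k=2, seed=9)
        assert np.array_equal(a.means, b.means)


class TestAssignSignature:
    @pytest.fixture
    def td_model(self):
        p = SIZE_PRESETS["escc-td"]
        return SizeMixtureModel(
            sv_class="TD",
            weights=np.array(p.weights),
            means=np.log10(p.medians_bp),
            sds=np.array(p.sigmas_log10),
        )

    def test_10kb_td_is_first_component(self, td_model):
        sv = make_sv("t", "chr1", 0, "-", "chr1", 10_000, "+")
        assert assign_signature(sv, td_model) == "TD-c1"

    def test_tie_breaks_to_smaller_index(self):
        # symmetric components around log10(size)=4: exact posterior tie
        model = SizeMixtureModel(
            sv_class="TD",
            weights=np.array([0.5, 0.5]),
            means=np.array([3.0, 5.0]),
            sds=np.array([0.3, 0.3]),
        )
        sv = make_sv("t", "chr1", 0, "-", "chr1", 10_000, "+")
        assert assign_signature(sv, model) == "TD-c1"

    def test_class_mismatch_and_translocation_rejected(self, td_model):
        dele = make_sv("d", "chr1", 0, "+", "chr1", 10_000, "-")
        with pytest.raises(ValueError, match="does not match"):
            assign_signature(dele, td_model)
        tra = make_sv("x", "chr1", 0, "+", "chr2", 10, "-")
        with pytest.raises(ValueError, match="translocation"):
            assign_signature(tra, td_model)

    def test_argmax_agrees_with_bruteforce_density(self, td_model):
        rng = np.random.default_rng(11)
        sizes = 10 ** rng.uniform(3, 6.5, 1000)
        for s in sizes:
            sv = make_sv("t", "chr1", 0, "-", "chr1", int(s) + 1, "+")
            lab = assign_signature(sv, td_model)
            dens = [
                w * norm.pdf(np.log10(sv.size), mu, sd)
                for w, mu, sd in zip(
                    td_model.weights, td_model.means, td_model.sds
                )
            ]
            assert lab == td_model.labels[int(np.argmax(dens))]


class TestRepairMechanism:
    @pytest.mark.parametrize(
        "mh,ins,want",
        [
            (150, 0, "NAHR"),
            (0, 25, "FoSTeS_MMBIR"),
            (0, 0, "NHEJ"),
            (1, 0, "NHEJ"),
            (0, 5, "NHEJ"),
            (2, 0, "alt_EJ"),
            (100, 0, "alt_EJ"),
            (101, 0, "NAHR"),
            (0, 10, "NHEJ"),
            (0, 11, "FoSTeS_MMBIR"),
        ],
    )
    def test_rule_boundaries(self, mh, ins, want):
        assert infer_repair_mechanism(mh, ins) == want

    def test_exhaustive_grid_partitions(self):
        labels = {"NAHR": 0, "alt_EJ": 0, "NHEJ": 0, "FoSTeS_MMBIR": 0}
        for mh in range(121):
            for ins in range(21):
                labels[infer_repair_mechanism(mh, ins)] += 1
        assert sum(labels.values()) == 121 * 21
        assert all(v > 0 for v in labels.values())


class TestTdp:
    def test_perfectly_proportional_scores_zero(self):
        lengths = {"chr1": 100, "chr2": 100}
        r = compute_tdp({"chr1": 5, "chr2": 5}, lengths)
        assert r.tdp_score == pytest.approx(0.0)

    def test_fully_skewed_two_equal_chromosomes(self):
        lengths = {"chr1": 100, "chr2": 100}
        r = compute_tdp({"chr1": 10}, lengths)
        assert r.tdp_score == pytest.approx(-1.0)
        assert r.exp["chr1"] == pytest.approx(5.0)

    def test_zero_tds_is_an_error(self):
        with pytest.raises(ValueError, match="zero TDs"):
            compute_tdp({}, {"chr1": 100})

    def test_accepts_sv_records(self):
        svs = [make_sv(f"t{i}", "chr1", 0, "-", "chr1", 100 + i, "+") for i in range(4)]
        r = compute_tdp(svs, {"chr1": 1000, "chr2": 1000})
        assert r.td_total == 4 and r.obs == {"chr1": 4}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_score_bounded_in_minus2_zero(self, obs_counts):
        lengths = {f"chr{i}": 10 + 7 * i for i in range(len(obs_counts))}
        obs = {f"chr{i}": n for i, n in enumerate(obs_counts)}
        r = compute_tdp(obs, lengths)
        assert -2.0 <= r.tdp_score <= 0.0
        assert sum(r.exp.values()) == pytest.approx(r.td_total)


class TestTdpStatus:
    def _results(self, scores):
        return [
            TDPResult(sample=f"S{i}", td_total=10, obs={}, exp={}, tdp_score=s)
            for i, s in enumerate(scores)
        ]

    def test_explicit_cutoff(self):
        (r,) = call_tdp_status(self._results([-0.4]), cutoff=-0.5)
        assert r.is_tdp is True

    def test_bimodal_scores_high_cluster_flagged(self):
        scores = [-1.2 + 0.01 * i for i in range(8)] + [-0.3 - 0.01 * i for i in range(4)]
        out = call_tdp_status(self._results(scores), seed=0)
        assert [r.is_tdp for r in out] == [False] * 8 + [True] * 4

    def test_degenerate_scores_without_cutoff_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            call_tdp_status(self._results([-0.5] * 12))

    def test_too_few_samples_for_clustering(self):
        with pytest.raises(ValueError, match=">=10"):
            call_tdp_status(self._results([-0.5, -0.1]))


class TestInstability:
    def test_median_split(self):
        calls = {c.sample: c.group for c in classify_instability({"a": 10, "b": 20, "c": 30})}
        assert calls == {"a": "stable", "b": "stable", "c": "unstable"}

    def test_all_equal_all_stable(self):
        calls = classify_instability({"a": 5, "b": 5, "c": 5})
        assert all(c.group == "stable" for c in calls)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_instability({"a": 5})
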