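"""Fit the log-size mixture behind the TD signatures and score TDP.

Tandem-duplication sizes in tumor cohorts are multi-modal on a log scale;
a 3-component Gaussian mixture on log10(size) recovers the planted modes.
The TDP score measures how unevenly one genome's TDs spread over
chromosomes: 0 = perfectly length-proportional, -2 = maximally skewed.
"""

from svkit.signatures import compute_tdp, fit_size_gmm, infer_repair_mechanism
from svkit.simulate import SIZE_PRESETS, draw_sizes

sizes = draw_sizes(SIZE_PRESETS["escc-td"], 30_000, seed=1)
model = fit_size_gmm(sizes, "TD", k=3, seed=1)
for label, med, w in zip(model.labels, model.component_medians_bp, model.weights):
    print(f"{label}: median {med / 1e3:.1f} kb, weight {w:.2f}")
# expected: modes near 12, 213 and 1170 kb with roughly equal weights

for mh, ins in ((0, 0), (5, 0), (150, 0), (0, 30)):
    print(f"mh={mh:>3} ins={ins:>2} -> {infer_repair_mechanism(mh, ins)}")

r = compute_tdp({"chr1": 10}, {"chr1": 100, "chr2": 100})
print(f"all TDs on one of two equal chromosomes: TDP score {r.tdp_score:.2f}")
# -1.0: half of the duplications sit where none were expected
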