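"""Simulate a small cohort and classify SV types and simple/non-simple status.

Each junction's type follows from its breakend orientations alone
(+/- deletion-like, -/+ tandem duplication, +/+ and -/- inversions,
different chromosomes = translocation); a junction is "simple" when no
other breakend falls between its two positions.
"""

from collections import Counter

from svkit.simulate import make_toy_genome, simulate_simple_cohort
from svkit.sv_io import classify_simple_status, simple_sv_burden

genome = make_toy_genome()
cohort = simulate_simple_cohort(genome, n_samples=3, seed=1)

for sample in cohort.samples:
    svs = classify_simple_status(cohort.sample_svs(sample))
    types = Counter(r.svtype for r in svs)
    burden = simple_sv_burden(svs)
    print(f"{sample}: {len(svs)} SVs, {dict(types)}, simple burden {burden}")

# Simple burden is the per-genome count of isolated intra-chromosomal
# junctions; it is the instability measure used to split cohorts into
# stable/unstable halves.
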