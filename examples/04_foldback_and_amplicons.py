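"""Detect fold-back inversions, infer BFB, and classify amplicon mechanism.

A fold-back inversion (same-orientation junction, ends < 100 kb apart,
on a copy-number step, no reciprocal partner) is the hallmark of
breakage-fusion-bridge cycles; combined with telomere loss it is called
BFB.  High-level amplicons (>= +5 copies over the arm baseline) are
classified BFB (>= 2 fold-backs) > ecDNA (circular junction structure) >
TD-dominated (stacked duplications).
"""

from svkit.amplicons import classify_mechanism, find_amplified_segments, group_amplicons
from svkit.foldback_bfb import detect_foldback_inversions, infer_bfb
from svkit.simulate import SimCohort, make_toy_genome
from svkit.sv_io import classify_simple_status

genome = make_toy_genome()
cohort = SimCohort(genome=genome)
cohort.plant("bfb_ladder", "S1", seed=1, params={"chrom": "chr1"})
cohort.plant("ecdna", "S1", seed=2, params={"chrom": "chr2", "target_cn": 20})
cohort.plant("td_stack", "S1", seed=3, params={"chrom": "chr3"})

svs = classify_simple_status(cohort.sample_svs("S1"))
track = cohort.coverage("S1", noise_sd=0.02, seed=4)
cn = cohort.cn_segments("S1")

foldbacks = detect_foldback_inversions(svs, track)
infer_bfb(foldbacks, cn)
for f in foldbacks:
    print(f"fold-back {f.chrom}:{f.pos1}-{f.pos2} ({f.orient_pair}) "
          f"step {f.cn_step:.1f}, q={f.q_value:.2e}, BFB={f.is_bfb}")

segments = find_amplified_segments(cn, genome.arms())
for amp in group_amplicons(segments, svs):
    mech = classify_mechanism(amp, foldbacks)
    locus = ", ".join(f"{s.chrom}:{s.start // 1000}k-{s.end // 1000}k"
                      for s in amp.segments)
    print(f"amplicon [{locus}] -> {mech} "
          f"(foldbacks={amp.n_foldbacks}, cycle={amp.has_cycle})")
# one amplicon per chromosome: BFB on chr1, ecDNA on chr2, TD stack on chr3
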