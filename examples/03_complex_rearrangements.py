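"""Plant complex rearrangements, rebuild them from the breakpoint graph.

A complex rearrangement is modelled as a simple SV bridged by templated
sequence insertions (TSIs).  The classifier reads coverage evidence off
alternating SV/sequence-edge paths: a deleted anchor interval with
elevated templates is a bridge deletion; a duplicated interval is a cycle
of TSIs (circular TD).
"""

from svkit.bpgraph import annotate_coverage, build_graph
from svkit.complex_events import detect_complex_events
from svkit.simulate import SimCohort, make_toy_genome
from svkit.sv_io import classify_simple_status

genome = make_toy_genome()
cohort = SimCohort(genome=genome)
cohort.plant("bridge_deletion", "S1", seed=1, params={"n_tsis": 2, "tsi_origin": "local"})
cohort.plant("tsi_cycle", "S1", seed=2,
             params={"chrom": "chr2", "tsi_origin": "interchromosomal"})

svs = classify_simple_status(cohort.sample_svs("S1"))
graph = build_graph(svs)
annotate_coverage(graph, cohort.coverage("S1"))

for ev in detect_complex_events(graph):
    origins = [t.origin_class for t in ev.tsis]
    print(f"{ev.event_class}: {len(ev.member_sv_ids)} junctions, "
          f"TSI origins {origins}, baseline {ev.evidence['baseline']:.2f}, "
          f"anchor interval {ev.evidence['interval_cov']:.2f}")
# interval below baseline -> deleted (bridge); above -> duplicated (cycle)
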