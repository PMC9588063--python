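# Methods

This note documents the models implemented in svkit, the defaults that
matter, what the simulator does and does not emulate, and the numerical
choices made where the underlying methodology left the design open.

## Coordinates and SV typing

All positions are 0-based internally; BEDPE starts are used directly, VCF
POS is decremented on read and restored on write.  Breakend orientation is
defined by which reference flank is joined into the junction: `+` keeps
bases ≤ pos, `-` keeps bases ≥ pos.  This makes SV type a pure function of
(same-chromosome?, orient₁, orient₂) on coordinate-sorted breakends:
(+,−) deletion-type, (−,+) tandem duplication, (+,+)/(−,−) the two
inversion orientations, and anything inter-chromosomal a translocation.
Near-duplicate junctions (both ends within 10 bp, same orientations and
sample) are merged keeping the higher caller quality, as when combining
two callers' output.

A junction is **simple** iff no breakend of another junction lies strictly
between its two positions.  Translocations span no interval and are always
non-simple.  The per-genome *simple SV burden* (translocations excluded by
default; a flag includes them) is the instability measure used to split
cohorts at the median into stable/unstable groups.

## Size-mixture signatures

Sizes of one SV class are modelled as a k-component Gaussian mixture in
log₁₀(bp), fit by EM (scikit-learn, 1-D full covariance, 20 random
restarts, seeded; k by BIC over 1–5 when not fixed).  Components are
relabelled in ascending mean so `TD-c1` is always the smallest mode.
Per-SV signature assignment is the maximum-posterior component, ties going
to the smaller index.  At 30,000 draws and modes ≥ 0.8 log₁₀ units apart,
recovered medians are reliably within a few percent (the acceptance suite
asserts 15%).

Shipped presets give the mode medians observed for esophageal
squamous-cell carcinoma cohorts: TD 12 kb / 213 kb / 1170 kb, deletions
1.7 kb / 105 kb / 9.7 Mb, inversions 3 kb / 4.1 Mb.  Component sigmas
(0.25 log₁₀ units) and equal weights are package defaults chosen for
clearly separated modes — they are simulator conventions, not published
quantities, and are configurable.

Repair mechanism per junction is a fixed rule ladder on microhomology
(mh) and untemplated insertion (ins) lengths, applied in order: ins >
10 bp → FoSTeS/MMBIR; mh > 100 bp → NAHR; 2 ≤ mh ≤ 100 → alt-EJ; else
NHEJ (0–1 bp mh or 1–10 bp insertion).  The two evidence fields are
treated as mutually exclusive; records carrying neither default to 0/0
(NHEJ-compatible) and are flagged on output only by those zeros.

**TDP.** `TDPscore = −Σ|Obs_i − Exp_i|/TD` with `Exp_i` proportional to
chromosome length (a mappable-length table can be substituted).  The score
is bounded in [−2, 0] because Σ|Obs−Exp| ≤ 2·TD.  No published cutoff
exists for "TD-overrepresented"; the default is a seeded 2-means split of
cohort scores with the higher cluster flagged, and an explicit cutoff
override.

## Breakpoint graph

Nodes are breakends of a genome's junctions after releasing simple TDs and
simple deletions (isolated copy-number events would otherwise riddle the
graph with spurious sequence edges).  Each node has exactly one SV edge.
A sequence edge requires a `-` node at the lower coordinate and a `+` node
at the higher one — the intervening reference segment can then be
traversed into both junctions — within 5 Mb, between distinct junctions.
With more than two candidates per node only the nearest per node survive,
and an edge is kept only if both endpoints keep it, enforcing the
at-most-two rule.  Construction is order-invariant.

Coverage annotation stores per-node left/right flank means (10 kb windows
truncated at the nearest other breakend) and per-sequence-edge means.  The
*local baseline* for an event is the median coverage within ±1 Mb of its
span, excluding bins inside any candidate event segment.

Two search modes: anchored (all simple alternating paths between two
nodes, ≥ 4 breakpoints, deduplicated up to reversal, capped at 12
breakpoints for combinatorial control) and exhaustive DFS (maximal simple
alternating paths and cycles, deterministic by coordinate-sorted
traversal).  Both are validated against a brute-force all-alternating-
paths oracle on small graphs.

## Complex-event classification

Classification reads coverage evidence off a path with anchors a₁, a₂ and
sequence edges (candidate templated insertions, TSIs), with a single
threshold `cn_delta` (default 0.3 on the tumor/normal ratio scale, i.e.
just over half a copy at purity 1 — no numeric threshold is published for
"lower/higher than the locally non-affected region").  Rules in fixed
order; the first hit wins:

1. **bridge_deletion** — anchors adjacent on one chromosome with
   orientations (+…−), anchor-interval coverage < baseline − δ, every TSI
   edge > its local baseline + δ;
2. **tsi_cycle** — adjacent anchors oriented (−…+), interval > baseline +
   δ, TSI edges elevated;
3. **unbalanced_translocation_tsi** — anchors on different chromosomes,
   each with a flank step ≥ δ, TSI edges elevated;
4. **unbalanced_inversion** — same-chromosome anchors, coverage loss in
   the anchor interval, sequence edges within δ of baseline;
5. otherwise unclassified.

The anchor-orientation requirements in rules 1–2 are a design choice the
rule text alone does not force: a deleted interval must be flanked
(+ … −) and a duplicated one (− … +), exactly as the corresponding simple
junction would be.  Without this, sub-paths of larger events can mimic a
cycle against a contaminated baseline.  One event is reported per distinct
junction set, and an event whose junctions are a strict subset of a
classified event's is suppressed as a sub-path.

TSI origin is interchromosomal when the template sits on another
chromosome, local within 1 Mb of the event anchor, distal beyond; the
classification depends only on the template interval, not its insertion
strand.

**Chains and chromothripsis.**  Chains are single-linkage clusters of
breakends within 1 Mb (a translocation fuses its two loci) holding ≥ 10
SVs; the linkage radius is a knob (arm-wide events with multi-Mb fragment
spacing need a larger radius).  A chain is a chromothripsis candidate when
it has ≥ 8 breakpoints, ≥ 80% of adjacent copy-number transitions
alternate among the 2–3 most frequent (rounded) CN states, and a
chi-square test does not reject uniformity of the four intra-chromosomal
SV types (p > 0.05 — the methodology says "uniform" without naming a
test).  Candidate patterns: `arm_wide_large` (median oscillating segment ≥
1 Mb spanning ≥ 50% of the arm), `localized_small` (median ≤ 250 kb packed
into ≤ 10 Mb), else `intermediate`; the 1 Mb / 250 kb / 50% thresholds are
package choices separating the described regimes and are configurable.

## Fold-backs and BFB

Fold-back candidates are head-to-head or tail-to-tail junctions with end
distance < 100 kb and no opposite-orientation inversion with both ends
within 5 kb (the reciprocal-support window is a package choice).  The
copy-number step is tested by a two-sided rank-sum on 20 coverage bins per
side, Benjamini–Hochberg corrected across a genome's candidates; calls
need q < 10⁻³.  Degenerate windows (noise-free constant coverage) are
resolved exactly: different constants → step (p = 0), equal → no step
(p = 1).  Telomere loss — terminal megabase on the fold-back's distal side
at least one copy below the chromosome's length-weighted median CN — turns
a fold-back into a BFB call; the one-copy margin is a package definition.

TSI fold-backs are alternating paths whose terminal breakends share
orientation on one chromosome < 100 kb apart (the same distance constant
as simple fold-backs, one knob) with at least one elevated template edge;
the category is interchromosomal if any template is, else the majority
local/distal origin; `stepped_cn` marks ≥ 2 distinct elevated coverage
levels on the retained side (500 kb window, levels resolved at the
`cn_delta` granularity).

## Hotspots

`pcf_segment` is an exact O(n²) dynamic program minimising
`Σ SSE(segment) + γ·(segments − 1)` with each segment at least `kmin`
points (defaults γ = 25, kmin = 10); it is verified against exhaustive
enumeration of all segmentations on ≤ 20 points.  Hotspot calling pools
one signature's breakpoints across the cohort (both ends of
intra-chromosomal SVs, each translocation end on its own chromosome),
runs PCF per chromosome on log₁₀(inter-breakpoint distance + 1), converts
segments to breakpoints/Mb, merges adjacent passing segments, and keeps
those at ≥ 2× this signature's genome-wide density with ≥ 15 distinct
genomes.  The background is per-signature (a global option exists).

## Amplicons

Amplified segments have total CN ≥ arm baseline + 5, the baseline being
the length-weighted median CN of the containing arm (an absolute-CN mode
exists; on a diploid arm the +5 rule coincides with CN ≥ 7).  Segments
sharing a junction (one breakend in each, 1 kb boundary tolerance) merge
into amplicons; segments with no breakend are `no_sv`.  Mechanism
precedence is fixed: ≥ 2 fold-backs → BFB; else a circular structure →
ecDNA; else ≥ 50% TD-type member junctions → TD_dominated; else
unclassified.

The circular-structure test searches the amplicon-local graph (simple SVs
retained — a circular TD is legitimately cyclic) for a simple alternating
cycle whose sequence-edge segments lie in the amplified segments and are
**pairwise disjoint**.  Disjointness is what separates a genuine circular
molecule, which traverses each segment once, from nested
tandem-duplication stacks whose apparent cycles reuse overlapping
reference sequence; without it every TD stack would be called ecDNA.  The
TD-dominated criterion counts TD-type junctions regardless of their
simple/non-simple status, since stacked duplications mutually contain one
another's breakends and are therefore never "simple" in the interval
sense.

## Simulator

Events are generated from the derivative-allele walk they imply: the
junction list, the copy-number deltas and the templated-insertion list all
come from one construction, so at zero noise the rendered coverage equals
baseline + planted delta exactly (asserted by a conservation test).
Coverage bins (10 kb default) carry
`purity · CN/ploidy + (1 − purity) + N(0, noise_sd)`, clipped at zero —
Gaussian ratio-scale noise, not read resampling, which suffices for
threshold-based classifiers but does not emulate GC waves, mappability
dropout or replication-timing trends.  Simple-SV cohorts draw sizes from
the presets, place events uniformly outside centromere ± 1 Mb (no
kataegis-like positional clustering — users benchmarking hotspot callers
should note placement is uniform), and draw microhomology/insertion
lengths inside the planted mechanism's rule band.

Templated-insertion chains enter each template in the orientation of the
preceding breakend, so template-to-template junctions are inversion-type;
combined with side-constrained template placement this guarantees no
junction of a planted complex event is an isolated simple deletion/TD
that graph construction would release.  This mirrors the observation that
real TSI junctions interleave with their anchors; a TSI junction that
genuinely looks like an isolated simple deletion is indistinguishable
from one at the resolution of this representation.

Planted-event geometry defaults: bridge deletions delete 100 kb bridged by
5 kb templates; cycles duplicate 100 kb; unbalanced inversions lose
2 × 400 kb around a preserved 200 kb inverted segment; BFB ladders place
three fold-backs 1 Mb apart with +5/+7/+9 copy steps and terminal loss;
ecDNA circularises two 500 kb segments to CN 20; TD stacks nest five
duplications over a 200 kb core (+5); chromothripsis alternates retained/
deleted ~300 kb fragments with junction types cycled uniformly over the
four intra-chromosomal classes.  Problem sizes throughout the test suite
(3 × 50 Mb toy genomes, 10 kb bins, tens of events per class) were chosen
so the full suite exercises every code path in well under a minute of
simulation time per module.

## Known limitations

* Coverage evidence is interpreted at face value; no purity/ploidy
  inference is performed (tracks are assumed normalized, 1.0 ≈ diploid).
* Graph reconstruction cannot phase breakpoints; events sharing junctions
  are reported once per junction set, and sub-path suppression may hide a
  genuinely nested smaller event inside a classified larger one.
* Chromothripsis calling follows screening heuristics (oscillation +
  type uniformity); it does not attempt to separate one-off shattering
  from iterative template-switching mimics.
* The ecDNA test proves a circular junction structure exists, not that
  the molecule is extrachromosomal (homogeneously staining regions give
  the same graph signature).
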