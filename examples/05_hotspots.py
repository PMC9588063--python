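"""Call a rearrangement hotspot from pooled cohort breakpoints with PCF.

Breakpoints of one signature are pooled across genomes; exact piecewise-
constant fitting of the log10 inter-breakpoint distances finds dense
segments, kept as hotspots when their density is at least twice the
genome-wide background and at least 15 distinct genomes contribute.
"""

import numpy as np
import pandas as pd

from svkit.hotspots import call_hotspots

rng = np.random.default_rng(0)
background = pd.DataFrame({
    "chrom": "chr1",
    "pos": np.sort(rng.integers(0, 250_000_000, 2000)),
    "sample": [f"S{i % 40}" for i in range(2000)],
})
cluster = pd.DataFrame({
    "chrom": "chr1",
    "pos": np.sort(rng.integers(100_000_000, 101_000_000, 300)),
    "sample": [f"S{i % 20}" for i in range(300)],
})
table = pd.concat([background, cluster], ignore_index=True)

for h in call_hotspots(table, {"chr1": 250_000_000}, signature="TD-c2"):
    s = h.segment
    print(f"hotspot {s.chrom}:{s.start}-{s.end}: {s.n_breakpoints} breakpoints "
          f"from {s.n_samples} genomes, {h.density_ratio:.0f}x background")
# the planted 1 Mb cluster stands ~30x above the genome-wide density
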