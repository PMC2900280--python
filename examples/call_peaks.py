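"""Well-defined nucleosomes from read coverage, and occupancy peak calling.

Builds a synthetic mononucleosome read map (three jittered reads per true
nucleosome), forms the reads-occupancy track and its 147-bp moving average,
and selects "well-defined" nucleosomes: sharp peaks of height >= 1.9 whose
20-bp flank slopes exceed 0.01/bp.  The same smoothed-track peak caller,
with a 127-bp minimum separation, turns any occupancy score into predicted
centers.
"""

import numpy as np

from nucdhmm import (moving_average, occupancy_peak_caller, reads_occupancy,
                     well_defined_nucleosomes)

rng = np.random.default_rng(0)
L = 60000
true_centers = np.arange(400, L - 400, 185)  # beads on a string, 185-bp repeat
reads = []
for c in true_centers:
    for _ in range(3):
        j = int(rng.integers(-8, 9))
        reads.append((c + j - 73, c + j + 73))

occ = reads_occupancy(reads, L)
avg = moving_average(occ.astype(float), 147)
well = np.array(well_defined_nucleosomes(avg))
hits = sum(1 for c in true_centers if np.abs(well - (c - 1)).min() <= 10)
print(f"{len(reads)} reads over {L} bp; {len(true_centers)} true nucleosomes")
print(f"well-defined nucleosomes: {len(well)} "
      f"({hits} within +-10 bp of a true center)")

called = occupancy_peak_caller(occ.astype(float), min_sep=127)
sep = np.diff(called).min() if len(called) > 1 else None
print(f"occupancy peak caller:    {len(called)} centers, "
      f"minimum separation {sep} bp")
# With >= 2 well-overlapping reads per nucleosome, essentially every true
# center is recovered, and no two called centers violate the 127-bp rule.
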