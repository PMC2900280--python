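"""Recover a linker-length distribution by iterative posterior updates.

A genome is simulated with Normal(100, 20) linker lengths; starting from a
flat prior on 1..200 bp, each iteration takes posterior expected length
counts (forward/backward), picks a Gaussian bandwidth by cross-validation,
and kernel-smooths them into the next distribution.  The total-variation
distance to the true (discretized) law shrinks each round.
"""

import numpy as np

from nucdhmm import (LinkerLengthDistribution, NormalLinkerLaw, law_pmf,
                     simulate_genome, surrogate_profile,
                     update_linker_distribution)
from nucdhmm.emission import precompute

nuc, link = surrogate_profile(order=1)
law = NormalLinkerLaw(100, 20)
genome = simulate_genome(nuc, link, law, 500, seed=11, tau_l=200)
truth = law_pmf(law, 200)

em = precompute(genome.seq, nuc, link)  # reused across iterations
F = LinkerLengthDistribution.uniform(200)
print(f"genome: {len(genome.seq)} bp, 500 nucleosomes, 501 linkers")
print(f"iter 0: TV to truth = {0.5 * np.abs(F.pmf - truth.pmf).sum():.3f} "
      "(uniform prior)")
for it in range(1, 4):
    F, diag = update_linker_distribution([genome.seq], nuc, link, F,
                                         n_iter=1, ems=[em])
    tv = 0.5 * np.abs(F.pmf - truth.pmf).sum()
    d = diag[0]
    print(f"iter {it}: TV to truth = {tv:.3f}, bandwidth = {d['bandwidth']:.1f} "
          f"bp, E[#nucleosomes] = {d['expected_nucleosomes']:.0f}")
mean = (np.arange(1, 201) * F.pmf).sum()
print(f"recovered mean linker length: {mean:.1f} bp (truth 100)")
# The residual TV reflects nucleosome-placement uncertainty: the posterior
# sees each linker's length smeared by the boundary error of its flanking
# nucleosomes, so the recovered law is a widened version of the truth.
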