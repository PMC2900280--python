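"""Mini replicate study: does updating F_L improve prediction?

Simulates replicate genomes with Normal(100, 20) linkers, decodes each with
the flat linker prior (update 0) and after one re-estimation round
(update 1), and tabulates predicted totals, sensitivity, and FDR
(center-to-center, +-35 bp).  One update typically buys several points of
sensitivity and drops the FDR by a similar amount.
"""

from nucdhmm import ExperimentConfig, NormalLinkerLaw, run_table_experiment
from nucdhmm import surrogate_profile

nuc, link = surrogate_profile(order=1)
cfg = ExperimentConfig(nuc=nuc, link=link, law=NormalLinkerLaw(100, 20),
                       n_nucleosomes=500, replicates=3, updates=(0, 1),
                       seed=123)
table, _raw = run_table_experiment(cfg)
print(table.round(2).to_string(index=False))
print("\n(500 true nucleosomes per replicate; sensitivity/FDR in percent,"
      "\n mean and standard error over 3 replicate genomes)")
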