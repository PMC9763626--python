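"""Simulate a structured drought-phenotyping cohort and inspect its truth.

Builds a 246-accession panel (6 subpopulations, LD blocks, one causal
wilting SNP, one planted metabolite QTL), then prints the cohort-level
quantities a field trial would report.
"""

import numpy as np

from qkmgwas import SimConfig, simulate_cohort, summary_stats

cfg = SimConfig(n_snps=1000, n_metabolites=60,
                planted_qtls=[(500, 0, 0.15)], seed=11)
G, grades, dsi, ck, ds, truth = simulate_cohort(cfg)

print(f"genotypes: {G.n_samples} accessions x {G.n_snps} SNPs, "
      f"median MAF {np.median(G.maf()):.3f}, "
      f"missing {np.isnan(G.dosages).mean():.1%}")
stats = summary_stats(dsi, below=1.0, above=2.5)
print(f"DSI: mean {stats['mean']:.2f}, CV {stats['cv']:.0%}; "
      f"{stats['n_below']} accessions below 1 (resistant tail), "
      f"{stats['n_above']} above 2.5 (sensitive tail)")
counts = dsi["resistance_class"].value_counts()
print(f"extreme groups: {counts['R']} R, {counts['S']} S, "
      f"{counts['intermediate']} intermediate")
print(f"metabolites: {ck.abundances.shape[1]} features; "
      f"mean simulated h2 {truth.true_h2.mean():.2f}; "
      f"{(truth.true_induction_fc != 1).sum()} drought-induced features")
# the DSI mean/CV mirror a wilting trial where most accessions wilt by
# 120 h; the truth ledger is what downstream recovery tests score against
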