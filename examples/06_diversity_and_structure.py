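"""Genome and metabolome structure: windowed pi, LD pruning, PCA, NJ tree.

The QC side of the pipeline: nucleotide diversity in 1 Mb windows, the
pruned marker set used for population structure, metabolome PCA, and the
sample neighbor-joining tree on the simple matching distance.
"""

import numpy as np

from qkmgwas import (
    SimConfig,
    filter_variants,
    ld_prune,
    log2_transform,
    pca_scores,
    sample_nj_tree,
    simulate_cohort,
    structure_covariates,
    windowed_pi,
)

cfg = SimConfig(n_accessions=80, n_snps=800, n_metabolites=50,
                chrom_length_bp=10_000_000, seed=17)
G, grades, dsi, ck, ds, truth = simulate_cohort(cfg)
Gf = filter_variants(G)

pi = windowed_pi(Gf, window_bp=1_000_000)
print(f"pi over {len(pi)} x 1 Mb windows: "
      f"{pi['pi'].min():.2e} to {pi['pi'].max():.2e} "
      "(per-bp heterozygosity; windows with no SNPs are 0)")

kept = ld_prune(Gf)
print(f"LD pruning (window 50, step 5, r2 0.2): {len(kept)}/{Gf.n_snps} "
      "SNPs kept for structure analysis")

pcs = structure_covariates(Gf.take_snps(kept), 2)
print(f"genotype PC1 spans [{pcs[:, 0].min():.1f}, {pcs[:, 0].max():.1f}] "
      "across subpopulations")

# metabolome: CK and DS samples should separate on PC1 once induction
# fold changes are planted
both = np.vstack([np.log2(ck.abundances.to_numpy()),
                  np.log2(ds.abundances.to_numpy())])
import pandas as pd
M = pd.DataFrame(both, index=(list(ck.abundances.index)
                              + list(ds.abundances.index)))
scores, evr = pca_scores(M, 2)
print(f"metabolome PCA: PC1 {evr[0]:.0%}, PC2 {evr[1]:.0%} of variance")

newick = sample_nj_tree(M.iloc[:20])
print(f"NJ tree of 20 samples: {len(newick)} chars of Newick, "
      f"e.g. {newick[:60]}...")
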