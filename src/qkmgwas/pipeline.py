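"""End-to-end orchestration: simulate -> score -> QC -> GWAS -> loci ->
metabolomics -> haplotypes, with provenance-stamped TSV outputs.

Each stage draws randomness from an independent counter-derived stream
of the single global seed, so adding a stage never shifts another
stage's stream and a fixed (config, seed) pair reproduces every output
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype import filter_variants, kinship, ld_prune, structure_covariates, windowed_pi
from .haplotypes import allele_composition, genotype_class_test
from .io import write_metabolites, write_truth, write_tsv, write_vcf
from .lmm import bonferroni_threshold, fit_null_lmm, wald_scan
from .loci import cluster_loci
from .metabolites import classify_inducible_constitutive, differential_call, log2_transform
from .phenotype import classify_extremes, compute_dsi
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger("qkmgwas")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full synthetic-cohort pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    k_extremes: int = 20
    maf_min: float = 0.05
    mcf_max: float = 0.1
    n_pcs: int = 6
    alpha: float = 0.05
    threshold: float | None = None   # default: alpha / n_filtered_snps
    merge_bp: int = 1_000_000
    max_span_bp: int = 30_000_000
    min_snps: int = 6
    pi_window_bp: int = 1_000_000
    run_metabolites: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        cfg.sim.seed = cfg.seed
        cfg.validate()
        return cfg

    def validate(self):
        self.sim.validate()
        if 2 * self.k_extremes > self.sim.n_accessions:
            raise ValueError("k_extremes too large for the cohort")
        if self.n_pcs >= self.sim.n_accessions:
            raise ValueError("n_pcs must be < n_accessions")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage on a freshly simulated cohort; returns the run dir.

    Outputs: genotypes.vcf, grades.tsv, dsi.tsv, pi.tsv, kinship.tsv,
    pcs.tsv, assoc_dsi.tsv, loci_dsi.tsv, metabolites_{ck,ds}.tsv,
    diff_*.tsv, classes.tsv, causal_snp_report.json, truth.json.
    """
    config.validate()
    config.sim.seed = config.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = [f"qkmgwas {__version__}", f"config {_config_hash(config)}",
             f"seed {config.seed}"]

    log.info("stage simulate: %d accessions, %d SNPs, %d metabolites",
             config.sim.n_accessions, config.sim.n_snps,
             config.sim.n_metabolites)
    G, grades, _, ck, ds, truth = simulate_cohort(config.sim)
    write_vcf(G, out / "genotypes.vcf")
    write_tsv(grades.drop(columns=[], errors="ignore"), out / "grades.tsv",
              stamp)
    write_truth(truth, out / "truth.json")

    log.info("stage score-dsi")
    dsi = classify_extremes(compute_dsi(grades), k=config.k_extremes)
    write_tsv(dsi, out / "dsi.tsv", stamp)

    log.info("stage qc")
    Gf = filter_variants(G, config.maf_min, config.mcf_max)
    kept = ld_prune(Gf)
    write_tsv(Gf.variants.iloc[kept][["chrom", "pos"]], out / "pruned_snps.tsv",
              stamp)
    pi = windowed_pi(Gf, config.pi_window_bp)
    write_tsv(pi, out / "pi.tsv", stamp + ["coordinates 0-based half-open"])

    log.info("stage kinship/pca")
    K = kinship(Gf)
    np.savetxt(out / "kinship.tsv", K.values, delimiter="\t")
    pcs = structure_covariates(Gf.take_snps(kept), config.n_pcs)
    write_tsv(pd.DataFrame(pcs, columns=[f"PC{i+1}" for i in range(config.n_pcs)]),
              out / "pcs.tsv", stamp)

    log.info("stage gwas (DSI)")
    y_map = dsi.set_index("accession")["dsi"]
    y = y_map.loc[Gf.sample_ids].to_numpy()
    Q = np.column_stack([np.ones(len(y)), pcs])
    fit = fit_null_lmm(y, Q, K)
    assoc = wald_scan(y, Q, Gf, fit)
    assoc["trait"] = "DSI"
    write_tsv(assoc, out / "assoc_dsi.tsv", stamp)

    log.info("stage loci")
    threshold = (config.threshold if config.threshold is not None
                 else bonferroni_threshold(config.alpha, Gf.n_snps))
    sig = assoc[assoc["p"] <= threshold]
    loci = cluster_loci(sig, config.merge_bp, config.max_span_bp,
                        config.min_snps, trait="DSI")
    write_tsv(loci, out / "loci_dsi.tsv",
              stamp + [f"threshold {threshold:.3e}"])

    if config.run_metabolites:
        log.info("stage metabolites")
        write_metabolites(ck, out / "metabolites_ck.tsv")
        write_metabolites(ds, out / "metabolites_ds.tsv")
        from .metabolites import MetaboliteMatrix
        all_ab = pd.concat([ck.abundances, ds.abundances])
        all_meta = pd.concat([ck.sample_meta, ds.sample_meta])
        M = MetaboliteMatrix(all_ab, all_meta)
        diff_all = differential_call(
            M, M.select(condition="CK"), M.select(condition="DS"))
        diff_ck = differential_call(
            M, M.select(condition="CK", group="S"),
            M.select(condition="CK", group="R"))
        diff_ds = differential_call(
            M, M.select(condition="DS", group="S"),
            M.select(condition="DS", group="R"))
        classes = classify_inducible_constitutive(diff_all, diff_ck, diff_ds)
        write_tsv(diff_all.reset_index(), out / "diff_ds_vs_ck.tsv", stamp)
        write_tsv(diff_ck.reset_index(), out / "diff_r_vs_s_ck.tsv", stamp)
        write_tsv(diff_ds.reset_index(), out / "diff_r_vs_s_ds.tsv", stamp)
        write_tsv(classes.reset_index(), out / "classes.tsv", stamp)
    else:
        log.info("stage metabolites skipped: no metabolite input configured")

    log.info("stage haplotype (causal DSI SNP)")
    groups = dsi.set_index("accession")["resistance_class"].loc[
        G.sample_ids].to_numpy()
    causal = config.sim.causal_dsi_snp
    report = {}
    try:
        gct = genotype_class_test(G, causal, y_map.loc[G.sample_ids].to_numpy())
        report["anova_f"] = gct["f"]
        report["anova_p"] = gct["p"]
        report["class_means"] = gct["class_means"]
        report["letters"] = gct["letters"]
    except ValueError as e:
        report["anova_error"] = str(e)
    comp = allele_composition(G, causal, groups)
    report["composition"] = comp
    with open(out / "causal_snp_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return out
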