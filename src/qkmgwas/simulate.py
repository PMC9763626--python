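"""Synthetic structured-cohort generator with a ground-truth ledger.

Emulates the data structure of a resequenced highland-barley diversity
panel phenotyped for drought sensitivity under control (CK) and mild
drought (DS) conditions:

* genotypes under the Balding-Nichols model (structured subpopulations at
  a chosen Fst) with first-order Markov LD blocks and uniform missingness;
* metabolite features simulated on the log2 scale as planted SNP effects
  (calibrated to a target per-SNP PVE) plus a kinship-correlated polygenic
  background (target broad-sense heritability) plus Gaussian noise, with
  drought-induction log2 fold changes and optional group-specific
  constitutive offsets;
* wilting-grade tables from a liability model tied to one causal SNP, a
  monotone time course, and replicate noise.

All randomness is driven by ``SimConfig.seed``, so a fixed seed yields
bit-identical matrices and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, kinship
from .metabolites import MetaboliteMatrix
from .phenotype import TIMEPOINTS_H, wilting_rate_to_grade

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes",
           "simulate_metabolites", "simulate_wilting", "simulate_cohort"]

# total leaves per replicate: 15 plants x 3 leaves, the counting unit
# used when wilting rates were scored
LEAVES_PER_REPLICATE = 45


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the real panel: 246 accessions in 6 subpopulations,
    biallelic SNPs with MAF in [0.05, 0.5] and 5% missing calls, LD
    blocks of 20 SNPs with copy probability 0.9, metabolite heritability
    averaging 0.54, planted QTLs at 15% PVE, ~11% of features
    drought-induced with fold changes of 1.5-5x (mostly up), and three
    replicates of wilting scoring.
    """

    n_accessions: int = 246
    n_snps: int = 2000
    n_chromosomes: int = 7
    chrom_length_bp: int = 50_000_000
    n_subpops: int = 6
    fst: float = 0.10
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.05
    ld_block_len: int = 20
    ld_copy_prob: float = 0.9
    n_metabolites: int = 120
    h2_mean: float = 0.54
    planted_qtls: list = field(default_factory=list)  # (snp, metabolite, pve)
    induction_log2fc: np.ndarray | None = None        # per metabolite
    induced_fraction: float = 0.11
    induced_up_fraction: float = 0.89
    constitutive_log2fc: np.ndarray | None = None     # R-minus-S offset
    metabolite_noise_sd: float | None = None          # override residual sd
    causal_dsi_snp: int = 0
    causal_dsi_effect: float = 0.7    # liability units per alt allele
    liability_noise_sd: float = 1.0
    replicate_sd: float = 0.3
    wilting_slope: float = 1.0
    wilting_time_offsets: tuple = (-1.0, 0.0, 1.0)
    grade_na_rate: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def validate(self):
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for snp, met, pve in self.planted_qtls:
            if not (0 < pve < 1):
                raise ValueError("planted pve_target must lie in (0, 1)")
            if not (0 <= snp < self.n_snps):
                raise ValueError(f"planted SNP index {snp} out of range")
            if not (0 <= met < self.n_metabolites):
                raise ValueError(f"planted metabolite index {met} out of range")
        if not (0 <= self.causal_dsi_snp < self.n_snps):
            raise ValueError("causal_dsi_snp out of range")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


@dataclass
class SimTruth:
    """Ground truth planted by the generator, for recovery tests."""

    causal_map: list                      # (snp_index, metabolite_index, beta)
    subpop_labels: np.ndarray
    true_h2: np.ndarray                   # per metabolite, total genetic
    true_induction_fc: np.ndarray         # per metabolite, DS/CK ratio
    true_constitutive_log2fc: np.ndarray  # per metabolite, R minus S
    true_grades_liability: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "causal_map": [[int(s), int(m), float(b)]
                           for s, m, b in self.causal_map],
            "subpop_labels": [int(x) for x in self.subpop_labels],
            "true_h2": [float(x) for x in self.true_h2],
            "true_induction_fc": [float(x) for x in self.true_induction_fc],
            "true_constitutive_log2fc": [
                float(x) for x in self.true_constitutive_log2fc],
        }
        if self.true_grades_liability is not None:
            d["true_grades_liability"] = [
                float(x) for x in self.true_grades_liability]
        return d


def _subpop_sizes(n: int, k: int) -> np.ndarray:
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return sizes


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols genotypes with LD blocks.

    Ancestral frequencies are Uniform over ``maf_range``; each
    subpopulation's frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F) (the
    no-divergence limit p0 at F = 0).  Within an LD block each haplotype
    copies the previous SNP's allele with probability ``ld_copy_prob``
    and redraws from the subpopulation frequency otherwise.  Diploid
    dosages are the sum of two haplotypes; missing entries are masked
    uniformly at ``missing_rate``.

    Returns ``(GenotypeMatrix, subpop_labels)``.
    """
    config.validate()
    rng = config.rng(0)
    n, m = config.n_accessions, config.n_snps
    k = config.n_subpops

    # variant table: SNPs split near-evenly across chromosomes, sorted
    # unique positions per chromosome
    per_chrom = _subpop_sizes(m, config.n_chromosomes)
    chroms, positions = [], []
    for c, mc in enumerate(per_chrom):
        # rejection-sample distinct positions (collisions negligible for
        # mc << chromosome length)
        pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=2 * mc))
        while len(pos) < mc:
            extra = rng.integers(1, config.chrom_length_bp + 1, size=2 * mc)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=mc, replace=False))
        chroms.extend([f"chr{c + 1}H"] * mc)
        positions.extend(pos.tolist())
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=m)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": ref, "alt": alt})

    p0 = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    F = config.fst
    if F == 0:
        freqs = np.tile(p0, (k, 1))
    else:
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        freqs = np.clip(rng.beta(a, b, size=(k, m)), 1e-3, 1 - 1e-3)

    sizes = _subpop_sizes(n, k)
    labels = np.repeat(np.arange(k), sizes)

    # block id per SNP, restarting at chromosome boundaries
    block = np.empty(m, dtype=int)
    offset = bid = 0
    for mc in per_chrom:
        ids = np.arange(mc) // config.ld_block_len
        block[offset:offset + mc] = bid + ids
        bid += ids[-1] + 1 if mc else 0
        offset += mc
    new_block = np.ones(m, dtype=bool)
    new_block[1:] = block[1:] != block[:-1]

    dosage = np.empty((n, m))
    row = 0
    for sp, size in enumerate(sizes):
        nh = 2 * size
        draws = (rng.random((nh, m)) < freqs[sp]).astype(np.int8)
        copy = rng.random((nh, m)) < config.ld_copy_prob
        hap = draws.copy()
        for j in range(1, m):
            if new_block[j]:
                continue
            c = copy[:, j]
            hap[c, j] = hap[c, j - 1]
        dosage[row:row + size] = hap[0::2] + hap[1::2]
        row += size

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan

    sample_ids = [f"ACC{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosage, variants, sample_ids), labels


def _induction_log2fc(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Default induction effects: ~11% of features induced, FC 1.5-5x."""
    if config.induction_log2fc is not None:
        arr = np.asarray(config.induction_log2fc, dtype=float)
        if arr.shape != (config.n_metabolites,):
            raise ValueError("induction_log2fc must have one entry per feature")
        return arr
    lfc = np.zeros(config.n_metabolites)
    induced = rng.random(config.n_metabolites) < config.induced_fraction
    mag = rng.uniform(np.log2(1.5), np.log2(5.0), size=config.n_metabolites)
    sign = np.where(rng.random(config.n_metabolites)
                    < config.induced_up_fraction, 1.0, -1.0)
    lfc[induced] = (mag * sign)[induced]
    return lfc


def simulate_metabolites(config: SimConfig, G: GenotypeMatrix,
                         groups: np.ndarray | None = None
                         ) -> tuple[MetaboliteMatrix, MetaboliteMatrix, SimTruth]:
    """Two-condition metabolite matrices plus the truth ledger.

    On the log2 scale each feature is

        baseline + sum_q beta_q * x_q  +  g  +  e

    with standardized planted dosages x_q (beta chosen so the marginal
    variance fraction equals the target PVE), a polygenic term g drawn
    through the square root of the realized kinship and scaled to the
    background heritability, and Gaussian noise filling the unit
    variance budget.  DS values share the genetic part, add the
    induction log2 fold change and redraw the residual.  Features with a
    constitutive offset add it to R-group accessions under both
    conditions (``groups``: per-accession R/S/intermediate labels;
    derived from the causal DSI SNP when omitted).  Raw abundances are
    ``2**log2`` and strictly positive.
    """
    config.validate()
    rng = config.rng(1)
    n, p = config.n_accessions, config.n_metabolites
    if G.n_samples != n:
        raise ValueError("genotype matrix does not match n_accessions")

    X = G.imputed()
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xc / sd

    # kinship square root for the polygenic background
    K = kinship(G).values
    K = K / np.mean(np.diag(K))
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0, None)
    L = U * np.sqrt(w)

    qtl_by_met: dict[int, list] = {}
    for snp, met, pve in config.planted_qtls:
        qtl_by_met.setdefault(met, []).append((snp, pve))

    # total genetic fraction ~ Beta with mean h2_mean, concentration 10
    a = 10.0 * config.h2_mean
    b = 10.0 - a
    h2_total = rng.beta(a, b, size=p)

    baseline = rng.normal(14.0, 2.0, size=p)
    lfc = _induction_log2fc(config, rng)
    const = (np.zeros(p) if config.constitutive_log2fc is None
             else np.asarray(config.constitutive_log2fc, dtype=float))
    if const.shape != (p,):
        raise ValueError("constitutive_log2fc must have one entry per feature")

    if groups is None:
        dos = X[:, config.causal_dsi_snp]
        # alt allele raises liability (sensitive); hom-ref accessions are R
        groups = np.where(dos < 0.5, "R", np.where(dos > 1.5, "S",
                                                   "intermediate"))
    groups = np.asarray(groups)
    r_mask = groups == "R"

    causal_map = []
    log2_ck = np.empty((n, p))
    log2_ds = np.empty((n, p))
    for j in range(p):
        qtls = qtl_by_met.get(j, [])
        pve_sum = sum(pve for _, pve in qtls)
        h2_bg = max(h2_total[j] - pve_sum, 0.0)
        if pve_sum + h2_bg >= 1.0:
            raise ValueError(
                f"feature {j}: planted PVE {pve_sum:.3f} + background "
                f"h2 {h2_bg:.3f} exceeds the unit variance budget")
        genetic = np.zeros(n)
        for snp, pve in qtls:
            beta = np.sqrt(pve)
            genetic += beta * Xs[:, snp]
            causal_map.append((snp, j, float(beta)))
        if h2_bg > 0:
            g = L @ rng.standard_normal(n)
            if qtls:
                # orthogonalize the background against the planted SNPs so
                # the marginal variance fraction at each QTL stays on target
                Xq = np.column_stack([Xs[:, snp] for snp, _ in qtls])
                coef, *_ = np.linalg.lstsq(Xq, g, rcond=None)
                g = g - Xq @ coef
            gs = g.std()
            if gs > 0:
                genetic += np.sqrt(h2_bg) * g / gs
        resid_sd = (config.metabolite_noise_sd
                    if config.metabolite_noise_sd is not None
                    else np.sqrt(max(1.0 - pve_sum - h2_bg, 1e-12)))
        log2_ck[:, j] = (baseline[j] + genetic + const[j] * r_mask
                         + rng.normal(0, resid_sd, size=n))
        log2_ds[:, j] = (baseline[j] + genetic + const[j] * r_mask
                         + lfc[j] + rng.normal(0, resid_sd, size=n))

    features = [f"met{j + 1:04d}" for j in range(p)]
    feature_meta = pd.DataFrame({"feature": features}).set_index("feature")

    def _matrix(log2_vals, condition):
        ids = [f"{acc}_{condition}" for acc in G.sample_ids]
        ab = pd.DataFrame(2.0 ** log2_vals, index=ids, columns=features)
        meta = pd.DataFrame(
            {"accession": G.sample_ids, "condition": condition,
             "group": groups}, index=ids)
        return MetaboliteMatrix(ab, meta, feature_meta)

    truth = SimTruth(
        causal_map=causal_map,
        subpop_labels=np.zeros(n, dtype=int),
        true_h2=h2_total,
        true_induction_fc=2.0 ** lfc,
        true_constitutive_log2fc=const,
    )
    return _matrix(log2_ck, "CK"), _matrix(log2_ds, "DS"), truth


def simulate_wilting(config: SimConfig, G: GenotypeMatrix) -> pd.DataFrame:
    """Grade table from a causal-SNP liability model.

    Per-accession liability = effect * causal dosage + Gaussian noise;
    the wilting rate at 72/96/120 h is a logistic function of liability
    plus an increasing per-timepoint offset, so rates (and grades) are
    monotone non-decreasing in both liability and time.  Replicates
    share the accession liability but add their own noise; optional NA
    injection at ``grade_na_rate``.
    """
    config.validate()
    rng = config.rng(2)
    n = config.n_accessions
    dos = G.imputed()[:, config.causal_dsi_snp]
    liability = (config.causal_dsi_effect * dos
                 + rng.normal(0, config.liability_noise_sd, size=n))

    rows = []
    for i, acc in enumerate(G.sample_ids):
        for rep in range(1, config.n_replicates + 1):
            rep_shift = rng.normal(0, config.replicate_sd)
            for tp, off in zip(TIMEPOINTS_H, config.wilting_time_offsets):
                z = config.wilting_slope * (liability[i] + rep_shift) + off
                rate = 1.0 / (1.0 + np.exp(-z))
                wilted = int(round(rate * LEAVES_PER_REPLICATE))
                if config.grade_na_rate > 0 and rng.random() < config.grade_na_rate:
                    wilted_v, rate_v, grade_v = np.nan, np.nan, np.nan
                else:
                    wilted_v = wilted
                    rate_v = wilted / LEAVES_PER_REPLICATE
                    grade_v = wilting_rate_to_grade(rate_v)
                rows.append({
                    "accession": acc, "replicate": f"rep{rep}",
                    "timepoint_h": tp, "wilted_leaves": wilted_v,
                    "total_leaves": LEAVES_PER_REPLICATE,
                    "wilting_rate": rate_v, "grade": grade_v,
                })
    table = pd.DataFrame(rows)
    table.attrs["liability"] = liability
    return table


def simulate_cohort(config: SimConfig):
    """Convenience wrapper: genotypes, wilting grades, metabolites, truth.

    Groups for constitutive offsets are derived from the liability-based
    DSI ranking (20 lowest = R, 20 highest = S) to mirror how the real
    cohort's extremes were chosen.
    """
    from .phenotype import classify_extremes, compute_dsi

    G, subpops = simulate_genotypes(config)
    grades = simulate_wilting(config, G)
    dsi = classify_extremes(compute_dsi(grades), k=min(20, config.n_accessions // 3))
    groups = (dsi.set_index("accession")["resistance_class"]
              .loc[G.sample_ids].to_numpy())
    ck, ds, truth = simulate_metabolites(config, G, groups=groups)
    truth.subpop_labels = subpops
    truth.true_grades_liability = grades.attrs["liability"]
    return G, grades, dsi, ck, ds, truth
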