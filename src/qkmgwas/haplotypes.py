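"""Haplotype classes, one-way ANOVA with Fisher LSD, allele composition.

Candidate-gene follow-up of GWAS hits: genotype codes at a handful of
SNPs are concatenated into haplotype classes (unphased; heterozygotes
form their own state), trait or metabolite values are compared across
classes by one-way ANOVA with Fisher's protected LSD and a compact
letter display, and allele/genotype composition is tabulated within
phenotype groups.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix

__all__ = ["build_haplotypes", "anova_lsd", "genotype_class_test",
           "allele_composition"]

# genotype state codes per SNP: hom-ref / het / hom-alt / missing
_CODES = {0.0: "R", 1.0: "H", 2.0: "A"}


def _snp_index(G: GenotypeMatrix, snp_id) -> int:
    if isinstance(snp_id, (int, np.integer)):
        if not (0 <= snp_id < G.n_snps):
            raise KeyError(f"SNP index {snp_id} out of range")
        return int(snp_id)
    ids = G.snp_ids()
    hits = np.where(ids == snp_id)[0]
    if len(hits) == 0:
        raise KeyError(f"SNP {snp_id!r} not found")
    return int(hits[0])


def build_haplotypes(G: GenotypeMatrix, snp_ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate genotype codes at ``snp_ids`` into haplotype classes.

    Returns ``(table, freqs)``: per-accession class strings (accessions
    with any missing constituent are labeled ``excluded``) and a
    frequency table over non-excluded accessions ranked by frequency.
    """
    if len(snp_ids) == 0:
        raise ValueError("snp_ids must be non-empty")
    idx = [_snp_index(G, s) for s in snp_ids]
    sub = G.dosages[:, idx]
    labels = []
    for row in sub:
        if np.any(np.isnan(row)):
            labels.append("excluded")
        else:
            labels.append("".join(_CODES[v] for v in row))
    table = pd.DataFrame({"accession": G.sample_ids, "haplotype": labels})
    counts = (table.loc[table["haplotype"] != "excluded", "haplotype"]
              .value_counts())
    freqs = pd.DataFrame({
        "haplotype": counts.index, "count": counts.to_numpy(),
        "frequency": counts.to_numpy() / counts.sum(),
    }).reset_index(drop=True)
    freqs["class_label"] = [f"Hap{i + 1}" for i in range(len(freqs))]
    label_map = dict(zip(freqs["haplotype"], freqs["class_label"]))
    table["class_label"] = table["haplotype"].map(
        lambda h: label_map.get(h, "excluded"))
    return table, freqs


def _compact_letters(classes, sig_pairs, alpha_order=True) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig_pairs`` is a set of frozensets of class pairs that differ
    significantly; classes sharing no letter differ, classes sharing a
    letter do not.
    """
    letters: list[set] = [set(classes)]
    for a, b in sorted(sig_pairs):
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            sa, sb = s - {b}, s - {a}
            for cand in (sa, sb):
                if not any(cand <= other for other in letters):
                    letters.append(cand)
    # absorb duplicates / subsets
    letters = [s for s in letters
               if not any(s < other for other in letters)]
    letters.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {c: "" for c in classes}
    for i, s in enumerate(letters):
        for c in sorted(s):
            out[c] += alphabet[i % len(alphabet)]
    return out


def anova_lsd(values, classes, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Fisher's protected LSD and compact letters.

    Classes with fewer than two members are dropped with a warning;
    at least two classes must remain.  Pairwise LSD t-tests use the
    pooled within-group mean square and its degrees of freedom, without
    multiplicity correction (the procedure is protected by the omnibus
    F at ``alpha``).  Returns a dict with ``f, p, df, class_means,
    class_counts, lsd_p`` (pairwise P-value dict) and ``letters``.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    ok = ~np.isnan(values)
    values, classes = values[ok], classes[ok]
    keep = []
    for c in pd.unique(classes):
        if np.sum(classes == c) >= 2:
            keep.append(c)
        else:
            warnings.warn(f"class {c!r} has < 2 members and is dropped")
    if len(keep) < 2:
        raise ValueError("need >= 2 classes with >= 2 members")
    mask = np.isin(classes, keep)
    values, classes = values[mask], classes[mask]

    groups = {c: values[classes == c] for c in keep}
    n = len(values)
    k = len(keep)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups.values())
    df_b, df_w = k - 1, n - k
    msb = ss_between / df_b
    msw = ss_within / df_w
    if msw == 0:
        f = 0.0 if msb == 0 else np.inf
        p = 1.0 if msb == 0 else 0.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, df_b, df_w))

    lsd_p = {}
    sig = set()
    for a, b in combinations(keep, 2):
        ga, gb = groups[a], groups[b]
        if msw == 0:
            pv = 1.0 if ga.mean() == gb.mean() else 0.0
        else:
            se = np.sqrt(msw * (1 / len(ga) + 1 / len(gb)))
            t = (ga.mean() - gb.mean()) / se
            pv = float(2 * stats.t.sf(abs(t), df_w))
        lsd_p[(a, b)] = pv
        if pv < alpha:
            sig.add(frozenset((a, b)))
    letters = _compact_letters(list(keep), {tuple(sorted(s)) for s in sig})
    return {
        "f": float(f), "p": p, "df": (df_b, df_w),
        "class_means": {c: float(groups[c].mean()) for c in keep},
        "class_counts": {c: int(len(groups[c])) for c in keep},
        "lsd_p": lsd_p, "letters": letters, "alpha": alpha,
    }


def genotype_class_test(G: GenotypeMatrix, snp_id, values,
                        alpha: float = 0.05) -> dict:
    """Compare trait values across hom-ref / het / hom-alt at one SNP.

    Missing genotypes are excluded.  Monomorphic SNPs are rejected.
    Returns the ``anova_lsd`` report plus the per-class labels used.
    """
    j = _snp_index(G, snp_id)
    dos = G.dosages[:, j]
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(dos) & ~np.isnan(values)
    codes = np.array([_CODES.get(v, "?") for v in dos[ok]])
    if len(np.unique(codes)) < 2:
        raise ValueError("SNP is monomorphic in the scored accessions")
    report = anova_lsd(values[ok], codes, alpha=alpha)
    report["classes"] = codes
    return report


def allele_composition(G: GenotypeMatrix, snp_id, groups) -> dict:
    """Genotype proportions per phenotype group plus an association test.

    ``groups`` is a per-accession label vector (e.g. R/S/intermediate);
    empty groups are rejected.  Proportions of hom-ref/het/hom-alt are
    reported per group together with alternate-allele frequencies.  With
    exactly two groups the association test is Fisher's exact test on
    the 2x2 allele-count table; with more groups a chi-square
    contingency test on the genotype x group table is used.
    """
    j = _snp_index(G, snp_id)
    dos = G.dosages[:, j]
    groups = np.asarray(groups)
    uniq = [g for g in pd.unique(groups)]
    comp = {}
    allele_counts = {}
    for g in uniq:
        sel = (groups == g) & ~np.isnan(dos)
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} has no genotyped accessions")
        d = dos[sel]
        comp[g] = {
            "hom_ref": float(np.mean(d == 0)),
            "het": float(np.mean(d == 1)),
            "hom_alt": float(np.mean(d == 2)),
            "alt_freq": float(d.sum() / (2 * len(d))),
            "n": int(len(d)),
        }
        allele_counts[g] = (int(d.sum()), int(2 * len(d) - d.sum()))
    if len(uniq) == 2:
        table = np.array([allele_counts[g] for g in uniq])
        _, p = stats.fisher_exact(table)
        test = {"test": "fisher_exact_alleles", "p": float(p)}
    else:
        table = np.array([[np.sum((groups == g) & (dos == v))
                           for v in (0.0, 1.0, 2.0)] for g in uniq])
        table = table[:, table.sum(axis=0) > 0]
        chi2, p, _, _ = stats.chi2_contingency(table)
        test = {"test": "chi2_genotypes", "p": float(p)}
    return {"composition": comp, **test}
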