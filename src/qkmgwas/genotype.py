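"""Genotype container and variant-level QC.

Dosage matrices code the alternate-allele count per diploid accession
(0/1/2, ``nan`` for missing).  Operations here mirror the standard
pre-GWAS pipeline for a resequenced crop panel: MAF/missingness filters,
sliding-window LD pruning, a centered cross-product kinship matrix,
principal-component structure covariates, and windowed nucleotide
diversity (pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "filter_variants",
    "ld_prune",
    "kinship",
    "structure_covariates",
    "windowed_pi",
]

#: columns required in a variant table
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs alt-allele dosages with a variant table.

    Parameters
    ----------
    dosages : ndarray of float, shape (n_samples, n_snps)
        Values in {0, 1, 2}; missing calls are ``nan``.
    variants : DataFrame
        One row per SNP with columns ``chrom, pos, ref, alt`` (1-based
        positions, strictly increasing within a chromosome).
    sample_ids : list of str
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage "
                f"matrix has {self.dosages.shape[1]} SNP columns"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variant table lacks column {col!r}")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:04d}" for i in range(self.dosages.shape[0])]
        self.variants = self.variants.reset_index(drop=True)
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_ids(self) -> np.ndarray:
        v = self.variants
        return (v["chrom"].astype(str) + ":" + v["pos"].astype(str)).to_numpy()

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            variants=self.variants.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        X = self.dosages.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(X, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        idx = np.where(np.isnan(X))
        X[idx] = mean[idx[1]]
        return X


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix used as the LMM random effect."""

    values: np.ndarray
    method: str = "centered"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


def filter_variants(G: GenotypeMatrix, maf_min: float = 0.05,
                    mcf_max: float = 0.1) -> GenotypeMatrix:
    """Keep SNPs with MAF >= ``maf_min`` and missing fraction <= ``mcf_max``.

    MAF is computed on non-missing alleles.  SNP order is preserved; an
    empty result triggers a warning, not an error.
    """
    keep = (G.maf() >= maf_min) & (G.missing_rate() <= mcf_max)
    if not keep.any():
        warnings.warn("no SNPs survive the MAF/MCF filter")
    return G.take_snps(np.where(keep)[0])


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation on pairwise-complete observations."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return r * r


def _prune_window(G: GenotypeMatrix, idx: list, removed: set,
                  maf: np.ndarray, pos: np.ndarray, r2_max: float) -> bool:
    """Stabilize one window; returns True if anything was removed."""
    changed = False
    while True:
        live = [i for i in idx if i not in removed]
        hit = None
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                i, j = live[a], live[b]
                if _pairwise_r2(G.dosages[:, i], G.dosages[:, j]) > r2_max:
                    hit = (i, j)
                    break
            if hit:
                break
        if hit is None:
            return changed
        i, j = hit
        # drop the lower-MAF member; tie -> later position
        if maf[i] < maf[j]:
            drop = i
        elif maf[j] < maf[i]:
            drop = j
        else:
            drop = i if pos[i] > pos[j] else j
        removed.add(drop)
        changed = True


def ld_prune(G: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """Sliding-window LD pruning of a filtered genotype matrix.

    Windows of ``window`` SNPs advance by ``step`` within each chromosome
    (never spanning chromosomes).  Within a window, while any pair of
    surviving SNPs has squared pairwise-complete Pearson correlation
    above ``r2_max``, the lower-MAF member of the first such pair is
    removed (tie: the SNP at the later position).  Sweeps over all
    windows repeat until a full pass removes nothing, so pruning an
    already-pruned set is a no-op.

    Returns the sorted array of kept SNP indices into ``G``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    maf = G.maf()
    pos = G.variants["pos"].to_numpy()
    chroms = G.variants["chrom"].to_numpy()
    removed: set = set()
    while True:
        any_change = False
        for chrom in pd.unique(chroms):
            cidx = np.where(chroms == chrom)[0]
            live = [i for i in cidx if i not in removed]
            start = 0
            while start < len(live):
                win = live[start:start + window]
                if len(win) >= 2:
                    any_change |= _prune_window(G, win, removed, maf, pos, r2_max)
                if start + window >= len(live):
                    break
                start += step
        if not any_change:
            break
    return np.array(sorted(set(range(G.n_snps)) - removed), dtype=int)


def kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Centered cross-product kinship K = Xc Xc' / m.

    Missing dosages are mean-imputed per SNP before centering.
    """
    if G.n_snps == 0:
        raise ValueError("cannot compute kinship from zero SNPs")
    X = G.imputed()
    Xc = X - X.mean(axis=0)
    K = Xc @ Xc.T / G.n_snps
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, method="centered")


def loco_kinship(G: GenotypeMatrix, chrom) -> KinshipMatrix:
    """Kinship from all chromosomes except ``chrom`` (leave-one-chromosome-out).

    The standard guard against proximal contamination when testing
    markers on ``chrom``: with a desk-scale marker panel a tested SNP
    would otherwise contribute appreciably to its own random-effect
    covariance and shrink its association signal (at whole-genome marker
    counts the contribution of one locus to K is negligible).
    """
    keep = np.where((G.variants["chrom"] != chrom).to_numpy())[0]
    if len(keep) == 0:
        raise ValueError(f"no SNPs left after excluding {chrom!r}")
    K = kinship(G.take_snps(keep))
    K.method = f"centered_loco_{chrom}"
    return K


def structure_covariates(G: GenotypeMatrix, n_components: int = 6) -> np.ndarray:
    """Top principal-component scores of the standardized dosage matrix.

    The standard proxy for ancestry fractions as LMM fixed effects.
    Missing dosages are mean-imputed; columns are centered and scaled to
    unit variance (monomorphic columns are left at zero).  Score columns
    are centered at zero and mutually orthogonal; signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    if n_components >= G.n_samples:
        raise ValueError("n_components must be < number of accessions")
    X = G.imputed()
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    # deterministic sign convention
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1.0
    return scores


def windowed_pi(G: GenotypeMatrix, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Nucleotide diversity per tiling window.

    Per-site unbiased heterozygosity ``2*p*(1-p) * 2N/(2N-1)`` (N diploid
    non-missing calls) is summed within half-open windows that tile each
    chromosome from position 1, and divided by the window *length* in bp
    (the windowed-pi convention of vcftools).  Output is BED-like:
    ``chrom, start0, end, pi``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    p = G.alt_freq()
    n_called = np.sum(~np.isnan(G.dosages), axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        site_pi = 2.0 * p * (1.0 - p) * (2 * n_called) / (2 * n_called - 1)
    site_pi = np.where(np.isnan(site_pi) | (n_called == 0), 0.0, site_pi)

    rows = []
    chroms = G.variants["chrom"].to_numpy()
    pos = G.variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        cpos = pos[mask]
        cpi = site_pi[mask]
        n_win = int((cpos.max() - 1) // window_bp) + 1
        win = (cpos - 1) // window_bp
        sums = np.bincount(win.astype(int), weights=cpi, minlength=n_win)
        for w in range(n_win):
            rows.append(
                {"chrom": chrom, "start0": w * window_bp,
                 "end": (w + 1) * window_bp, "pi": sums[w] / window_bp}
            )
    return pd.DataFrame(rows, columns=["chrom", "start0", "end", "pi"])
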