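"""Exact single-marker linear mixed-model association scan.

The model is the standard GWAS LMM

    y = x * beta + Q * alpha + g + e,   g ~ N(0, sigma_g^2 K),
                                        e ~ N(0, sigma_e^2 I)

with Q fixed structure covariates (intercept + PCs) and K the kinship
matrix.  Variance components are profiled out over the ratio
delta = sigma_e^2 / sigma_g^2 on the eigenbasis of K (one
eigendecomposition for the whole scan); per-SNP Wald tests run as
generalized least squares in the rotated space, either reusing the null
delta (fast, default) or re-optimizing per SNP (exact mode).

K is rescaled internally to unit mean diagonal so that the reported
pseudo-heritability sigma_g^2/(sigma_g^2+sigma_e^2) lives on the
variance-fraction scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype import GenotypeMatrix, KinshipMatrix

__all__ = ["NullModelFit", "fit_null_lmm", "wald_scan", "snp_pve",
           "bonferroni_threshold", "genomic_inflation"]

_DELTA_LO, _DELTA_HI = 1e-5, 1e5
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class NullModelFit:
    """Variance components of the no-SNP model plus the cached rotation."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    pseudo_h2: float
    loglik: float
    eigenvalues: np.ndarray
    rotation: np.ndarray        # U, columns = eigenvectors of scaled K
    yt: np.ndarray              # U' y
    Qt: np.ndarray              # U' Q
    reml: bool = True
    k_scale: float = 1.0        # mean diagonal of the input K


def _neg_profile_ll(log_delta: float, yt: np.ndarray, Qt: np.ndarray,
                    lam: np.ndarray, reml: bool) -> float:
    """Negative profile (restricted) log-likelihood at a given delta."""
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    n, q = len(yt), Qt.shape[1]
    A = (Qt * w[:, None]).T @ Qt
    b = (Qt * w[:, None]).T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Qt @ beta
    rss = float(np.sum(w * r * r))
    if rss <= 0:
        return np.inf
    if reml:
        df = n - q
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        _, logdet_QQ = np.linalg.slogdet(Qt.T @ Qt)
        ll = 0.5 * (
            df * (np.log(df / (2 * np.pi)) - 1.0 - np.log(rss))
            + np.sum(np.log(w)) + logdet_QQ - logdet_A
        )
    else:
        ll = 0.5 * (
            n * (np.log(n / (2 * np.pi)) - 1.0 - np.log(rss))
            + np.sum(np.log(w))
        )
    return -ll


def _optimize_delta(yt, Qt, lam, reml, n_grid: int = 100) -> tuple[float, float]:
    """Deterministic grid scan over log delta plus Brent refinement."""
    grid = np.linspace(np.log(_DELTA_LO), np.log(_DELTA_HI), n_grid)
    vals = np.array([_neg_profile_ll(g, yt, Qt, lam, reml) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        _neg_profile_ll, bounds=(lo, hi), method="bounded",
        args=(yt, Qt, lam, reml), options={"xatol": 1e-8})
    if res.fun <= vals[i]:
        return float(np.exp(res.x)), float(-res.fun)
    return float(np.exp(grid[i])), float(-vals[i])


def fit_null_lmm(y: np.ndarray, Q: np.ndarray, K: KinshipMatrix | np.ndarray,
                 reml: bool = True) -> NullModelFit:
    """REML (or ML) variance components of the no-SNP mixed model.

    ``Q`` must include an intercept column.  K is eigendecomposed once;
    the ratio delta = sigma_e^2/sigma_g^2 is profiled over a 100-point
    log grid on [1e-5, 1e5] with bounded local refinement, and the scale
    parameter follows in closed form.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[0] != len(y):
        Q = Q.T
    if np.linalg.matrix_rank(Q) < Q.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    if Kv.shape[0] != len(y):
        raise ValueError("kinship does not match phenotype length")
    k_scale = float(np.mean(np.diag(Kv)))
    if k_scale <= 0:
        raise ValueError("kinship has non-positive mean diagonal")
    lam, U = np.linalg.eigh(Kv / k_scale)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Qt = U.T @ Q

    delta, loglik = _optimize_delta(yt, Qt, lam, reml)
    w = 1.0 / (lam + delta)
    A = (Qt * w[:, None]).T @ Qt
    beta = np.linalg.solve(A, (Qt * w[:, None]).T @ yt)
    r = yt - Qt @ beta
    rss = float(np.sum(w * r * r))
    df = len(y) - Q.shape[1] if reml else len(y)
    sigma_g2 = rss / df
    sigma_e2 = sigma_g2 * delta
    return NullModelFit(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
        pseudo_h2=sigma_g2 / (sigma_g2 + sigma_e2), loglik=loglik,
        eigenvalues=lam, rotation=U, yt=yt, Qt=Qt, reml=reml,
        k_scale=k_scale)


def wald_scan(y: np.ndarray, Q: np.ndarray, G: GenotypeMatrix,
              fit: NullModelFit, exact: bool = False) -> pd.DataFrame:
    """Per-SNP Wald tests in the rotated space.

    In the default (approximate) mode the null-model delta is reused for
    every SNP; ``exact=True`` re-optimizes delta per marker.  The
    residual scale is re-estimated per SNP with df = n - q - 1, so with
    K = I and Q = intercept the statistic reduces exactly to the OLS
    t-square and its chi-square(1) P-value.  Missing dosages are
    mean-imputed; monomorphic SNPs are flagged with beta = 0, p = 1.

    Returns a DataFrame: chrom, pos, ref, alt, beta, se, p, pve,
    monomorphic.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = G.imputed()
    U, lam = fit.rotation, fit.eigenvalues
    yt, Qt = fit.yt, fit.Qt
    n, q = len(y), Qt.shape[1]
    var_y = float(np.var(y))

    Xt = U.T @ X
    out = {k: np.zeros(G.n_snps) for k in ("beta", "se", "p", "pve")}
    mono = np.zeros(G.n_snps, dtype=bool)
    df = n - q - 1
    for j in range(G.n_snps):
        xj = X[:, j]
        if np.all(xj == xj[0]):
            mono[j] = True
            out["beta"][j], out["se"][j], out["p"][j] = 0.0, np.nan, 1.0
            continue
        if exact:
            delta, _ = _optimize_delta(
                yt, np.column_stack([Qt, Xt[:, j]]), lam, fit.reml)
        else:
            delta = fit.delta
        w = 1.0 / (lam + delta)
        D = np.column_stack([Qt, Xt[:, j]])
        A = (D * w[:, None]).T @ D
        b = (D * w[:, None]).T @ yt
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            mono[j] = True
            out["beta"][j], out["se"][j], out["p"][j] = 0.0, np.nan, 1.0
            continue
        coef = Ainv @ b
        r = yt - D @ coef
        rss = float(np.sum(w * r * r))
        sigma2 = rss / df
        beta = coef[-1]
        se = np.sqrt(sigma2 * Ainv[-1, -1])
        chi2 = (beta / se) ** 2 if se > 0 else 0.0
        out["beta"][j] = beta
        out["se"][j] = se
        out["p"][j] = float(stats.chi2.sf(chi2, df=1)) if se > 0 else 1.0
        var_x = float(np.var(xj))
        out["pve"][j] = (np.clip(beta ** 2 * var_x / var_y, 0, 1)
                         if var_y > 0 else 0.0)
    res = G.variants[["chrom", "pos", "ref", "alt"]].copy()
    for k, v in out.items():
        res[k] = v
    res["monomorphic"] = mono
    return res


def snp_pve(beta: float, x: np.ndarray, y: np.ndarray) -> float:
    """Marginal phenotypic variance explained: beta^2 Var(x)/Var(y), in [0,1]."""
    y = np.asarray(y, float)
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("phenotype has zero variance")
    x = np.asarray(x, float)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    return float(np.clip(beta ** 2 * np.var(x) / var_y, 0.0, 1.0))


def bonferroni_threshold(alpha: float = 0.05, n_effective: int = 1) -> float:
    """Genome-wide significance threshold alpha / effective SNP count."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    return alpha / n_effective


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic-control lambda: median observed chi2(1) over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need >= 100 P-values for a stable lambda_GC")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)
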