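"""Metabolomics statistics for a two-condition (CK/DS) cohort.

Implements the widely-targeted-metabolomics workflow around differential
accumulation: log2 and min-max transforms, PLS-DA variable importance
(VIP), the three-criterion differential call (VIP > 1, fold change >= 1.5
or <= 0.67, BH-adjusted t-test P < 0.05), the four-group fold-change
framework contrasting drought induction with constitutive R-vs-S
differences, inducible/constitutive classification, feature correlation
structure, sample neighbor-joining trees on the simple matching distance,
and PCA scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

import skbio
from skbio import DistanceMatrix

__all__ = [
    "MetaboliteMatrix",
    "DiffResult",
    "log2_transform",
    "minmax_normalize",
    "plsda_vip",
    "differential_call",
    "four_group_fc",
    "classify_inducible_constitutive",
    "spearman_matrix",
    "simple_matching_distance",
    "nj_from_distance",
    "sample_nj_tree",
    "pca_scores",
]


@dataclass
class MetaboliteMatrix:
    """Samples x features abundance matrix with sample metadata.

    ``abundances``: DataFrame (rows = samples, columns = features) of raw
    positive values.  ``sample_meta``: DataFrame indexed like the rows
    with columns ``accession``, ``condition`` (CK/DS) and ``group``
    (R/S/intermediate).
    """

    abundances: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.abundances.to_numpy() <= 0).any():
            raise ValueError("abundances must be strictly positive")
        if not self.abundances.index.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match abundance rows")
        for col in ("accession", "condition", "group"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks column {col!r}")

    @property
    def features(self) -> pd.Index:
        return self.abundances.columns

    def select(self, condition: str | None = None,
               group: str | None = None) -> pd.Index:
        """Sample index for a (condition, group) cell; None = no constraint."""
        mask = pd.Series(True, index=self.sample_meta.index)
        if condition is not None:
            mask &= self.sample_meta["condition"] == condition
        if group is not None:
            mask &= self.sample_meta["group"] == group
        return self.sample_meta.index[mask]


@dataclass
class DiffResult:
    """Per-feature differential test record (group b vs group a)."""

    feature: str
    fc: float
    vip: float
    p_raw: float
    p_adj: float
    call: str = "ns"


def log2_transform(M: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; rejects non-positive values."""
    if (M.to_numpy() <= 0).any():
        raise ValueError("log2 transform requires strictly positive values")
    return np.log2(M)


def minmax_normalize(M: pd.DataFrame) -> pd.DataFrame:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0."""
    lo = M.min(axis=0)
    span = M.max(axis=0) - lo
    span = span.replace(0, np.nan)
    out = (M - lo) / span
    return out.fillna(0.0)


def plsda_vip(X: np.ndarray, classes, n_components: int = 2) -> np.ndarray:
    """Variable importance in projection from a two-class PLS-DA model.

    ``X`` is samples x features (log2 scale recommended); it is
    autoscaled (zero mean, unit variance) internally.  The response is
    dummy coded +/-1.  With SSY_a the response variance captured by
    component a and w_a the (unit-norm) X-weight vector,

        VIP_j = sqrt( p * sum_a SSY_a * w_aj^2 / sum_a SSY_a )

    which conserves sum_j VIP_j^2 = p (the feature count).
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    uniq = np.unique(classes)
    if len(uniq) != 2:
        raise ValueError("PLS-DA requires exactly two classes")
    y = np.where(classes == uniq[0], -1.0, 1.0)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    n_components = min(n_components, Xs.shape[0] - 1, Xs.shape[1])
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        # degenerate inputs (no class separation) trigger harmless 0/0
        # component warnings inside NIPALS
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        pls.fit(Xs, y)
    W = pls.x_weights_            # (p, A), unit-norm columns
    T = pls.x_scores_             # (n, A)
    Q = pls.y_loadings_.ravel()   # (A,)
    ssy = np.sum(T ** 2, axis=0) * Q ** 2
    if ssy.sum() == 0:
        return np.ones(X.shape[1])
    p = X.shape[1]
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn ** 2 @ ssy) / ssy.sum())
    return vip


def differential_call(M: MetaboliteMatrix, group_a, group_b, *,
                      fc_up: float = 1.5, fc_down: float = 1 / 1.5,
                      vip_min: float = 1.0, alpha: float = 0.05,
                      adjust: str = "fdr_bh", equal_var: bool = True,
                      n_components: int = 2) -> pd.DataFrame:
    """Three-criterion differential-metabolite calling, b vs a.

    Fold change is the ratio of raw group means (b over a); the t-test
    runs on log2 values (pooled-variance Student by default, Welch with
    ``equal_var=False``); P-values are adjusted across features
    (Benjamini-Hochberg by default, ``adjust='bonferroni'`` available);
    VIP comes from a PLS-DA on the two groups.  A feature is called
    ``up`` iff VIP > vip_min, fc >= fc_up and adjusted P < alpha;
    ``down`` with fc <= fc_down; else ``ns``.
    """
    a_idx, b_idx = pd.Index(group_a), pd.Index(group_b)
    if len(a_idx) < 3 or len(b_idx) < 3:
        raise ValueError("both groups need >= 3 samples")
    A = M.abundances.loc[a_idx]
    B = M.abundances.loc[b_idx]
    fc = B.mean(axis=0) / A.mean(axis=0)
    la, lb = np.log2(A.to_numpy()), np.log2(B.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p_raw = stats.ttest_ind(lb, la, axis=0, equal_var=equal_var)
    # degenerate zero-variance, equal-mean features: no evidence
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    _, p_adj, _, _ = multipletests(p_raw, method=adjust)
    X = np.vstack([la, lb])
    labels = np.array([0] * len(a_idx) + [1] * len(b_idx))
    vip = plsda_vip(X, labels, n_components=n_components)
    call = np.where(
        (vip > vip_min) & (fc.to_numpy() >= fc_up) & (p_adj < alpha), "up",
        np.where(
            (vip > vip_min) & (fc.to_numpy() <= fc_down) & (p_adj < alpha),
            "down", "ns"),
    )
    return pd.DataFrame(
        {"feature": M.features, "fc": fc.to_numpy(), "vip": vip,
         "p_raw": p_raw, "p_adj": p_adj, "call": call}
    ).set_index("feature")


_FOUR_CELLS = [("R", "DS", "R", "CK"), ("S", "DS", "S", "CK"),
               ("R", "CK", "S", "CK"), ("R", "DS", "S", "DS")]
FOUR_GROUP_NAMES = ["R_DS/R_CK", "S_DS/S_CK", "R_CK/S_CK", "R_DS/S_DS"]


def four_group_fc(M: MetaboliteMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-feature fold changes for the four R/S x CK/DS contrasts.

    Returns the fold-change table (columns ``R_DS/R_CK, S_DS/S_CK,
    R_CK/S_CK, R_DS/S_DS``) and Wilcoxon rank-sum tests comparing the
    |log2 FC| distributions of each induced contrast (within-group
    CK-to-DS change) against each constitutive contrast (R vs S within a
    condition).  Large constitutive |log2 FC| relative to induced is the
    signature of constitutive differentiation.
    """
    cells = {}
    for g in ("R", "S"):
        for c in ("CK", "DS"):
            idx = M.select(condition=c, group=g)
            if len(idx) == 0:
                raise ValueError(f"empty (group={g}, condition={c}) cell")
            cells[(g, c)] = M.abundances.loc[idx].mean(axis=0)
    fc = pd.DataFrame(index=M.features)
    for name, (g1, c1, g2, c2) in zip(FOUR_GROUP_NAMES, _FOUR_CELLS):
        fc[name] = (cells[(g1, c1)] / cells[(g2, c2)]).to_numpy()
    al = np.abs(np.log2(fc.to_numpy()))
    induced = np.concatenate([al[:, 0], al[:, 1]])
    constitutive = np.concatenate([al[:, 2], al[:, 3]])
    tests = {}
    for name, col in zip(FOUR_GROUP_NAMES[:2], (al[:, 0], al[:, 1])):
        for cname, ccol in zip(FOUR_GROUP_NAMES[2:], (al[:, 2], al[:, 3])):
            if np.ptp(col) == 0 and np.ptp(ccol) == 0 and col[0] == ccol[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(ccol, col,
                                             alternative="two-sided").pvalue)
            tests[f"{cname} vs {name}"] = p
    tests["constitutive vs induced (pooled)"] = (
        1.0 if np.ptp(induced) == 0 and np.ptp(constitutive) == 0
        and induced[0] == constitutive[0]
        else float(stats.mannwhitneyu(constitutive, induced,
                                      alternative="two-sided").pvalue)
    )
    return fc, tests


def classify_inducible_constitutive(diff_all: pd.DataFrame,
                                    diff_rs_ck: pd.DataFrame,
                                    diff_rs_ds: pd.DataFrame) -> pd.Series:
    """Label features inducible / constitutive_differential / both / neither.

    ``diff_all`` holds DS-vs-CK calls on the whole cohort; ``diff_rs_ck``
    and ``diff_rs_ds`` hold R-vs-S calls within each condition.  A
    feature is *inducible* iff called (up or down) in ``diff_all``;
    *constitutive_differential* iff called in the same direction in both
    R-vs-S tables but not in ``diff_all``; *both* iff inducible and
    R-vs-S-called in both conditions; *neither* otherwise.
    """
    feats = diff_all.index
    if not (feats.equals(diff_rs_ck.index) and feats.equals(diff_rs_ds.index)):
        raise ValueError("the three call sets must cover the same features")
    ind = diff_all["call"].isin(["up", "down"])
    rs_same = (
        diff_rs_ck["call"].isin(["up", "down"])
        & (diff_rs_ck["call"] == diff_rs_ds["call"])
    )
    labels = np.where(
        ind & rs_same, "both",
        np.where(ind, "inducible",
                 np.where(rs_same, "constitutive_differential", "neither")),
    )
    return pd.Series(labels, index=feats, name="class")


def spearman_matrix(M: pd.DataFrame, adjust: str = "fdr_bh"):
    """Pairwise Spearman rank correlations with BH-adjusted P-values.

    Needs >= 5 samples.  Constant features yield an NA row/column.
    Returns (rho DataFrame, adjusted-p DataFrame), both symmetric with
    unit / zero diagonals.
    """
    if M.shape[0] < 5:
        raise ValueError("need >= 5 samples for rank correlations")
    X = M.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(X)
    if np.ndim(rho) == 0:  # scipy collapses the two-feature case
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    const = X.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    iu = np.triu_indices_from(p, k=1)
    flat = p[iu]
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method=adjust)[1]
    p_adj = np.full_like(p, np.nan)
    p_adj[iu] = adj
    p_adj.T[iu] = adj
    np.fill_diagonal(p_adj, np.where(const, np.nan, 0.0))
    cols = M.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p_adj, index=cols, columns=cols))


def simple_matching_distance(M: pd.DataFrame) -> pd.DataFrame:
    """Pairwise simple matching distance after median binarization.

    Each feature is binarized at its cohort median (>= median -> 1); the
    distance between two samples is the fraction of features on which
    they disagree.
    """
    B = (M.to_numpy() >= np.median(M.to_numpy(), axis=0)).astype(float)
    n = B.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = np.mean(B != B[i], axis=1)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=M.index, columns=M.index)


def nj_from_distance(D: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining on a distance matrix -> Newick string.

    Negative branch lengths are clamped to zero.  On additive distances
    the true topology and branch lengths are recovered.
    """
    dm = DistanceMatrix(D.to_numpy(), ids=[str(i) for i in D.index])
    tree = skbio.tree.nj(dm)
    return str(tree).strip()


def sample_nj_tree(M: pd.DataFrame) -> str:
    """Neighbor-joining tree of samples on the simple matching distance.

    ``M`` should be log2 abundances (samples x features).  Features are
    binarized at their cohort median; Saitou-Nei neighbor joining is run
    on the resulting distance matrix with negative branch lengths clamped
    to zero.  Returns a Newick string carrying all sample labels.
    """
    if M.shape[0] < 4:
        raise ValueError("neighbor joining needs >= 4 samples")
    return nj_from_distance(simple_matching_distance(M))


def pca_scores(M: pd.DataFrame, n_components: int = 2):
    """PCA of log2, feature-centered data.

    Returns (scores DataFrame with PC columns, explained-variance
    fractions).  Signs are fixed so each component's largest-magnitude
    loading is positive.
    """
    if M.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    X = M.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(S))
    total = np.sum(S ** 2)
    evr = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * S[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=M.index, columns=cols), evr
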