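"""Aggregation of significant SNPs into loci, hotspots, colocalization.

Significant markers are chained into loci by single-linkage on genomic
distance: adjacent significant SNPs closer than 1 Mb join one locus, a
chained locus spanning more than 30 Mb is abandoned, and loci with
fewer than six member SNPs are discarded as likely false positives.
The member with the lowest P-value is the lead SNP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cluster_loci", "hotspot_density", "density_correlation",
           "colocalize"]

LOCUS_COLUMNS = ["trait", "chrom", "start", "end", "n_snps",
                 "lead_pos", "lead_p"]


def cluster_loci(records: pd.DataFrame, merge_bp: int = 1_000_000,
                 max_span_bp: int = 30_000_000, min_snps: int = 6,
                 trait: str = "trait") -> pd.DataFrame:
    """Chain significant SNPs into loci.

    ``records`` must carry columns ``chrom, pos, p`` and already be
    restricted to SNPs passing the significance threshold (duplicated
    rows are dropped; unsorted input is sorted internally).  Consecutive
    SNPs on one chromosome join one locus iff their gap is < ``merge_bp``;
    loci spanning more than ``max_span_bp`` are abandoned together with
    their member SNPs; loci with fewer than ``min_snps`` members are
    discarded.  The lead SNP is the member with the lowest P
    (tie: smallest position).  Locus boundaries are the min/max member
    positions.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=LOCUS_COLUMNS)
    df = (records[["chrom", "pos", "p"]]
          .drop_duplicates(subset=["chrom", "pos"])
          .sort_values(["chrom", "pos"], kind="mergesort")
          .reset_index(drop=True))
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        pvals = sub["p"].to_numpy()
        breaks = np.where(np.diff(pos) >= merge_bp)[0] + 1
        for seg in np.split(np.arange(len(pos)), breaks):
            span = pos[seg[-1]] - pos[seg[0]]
            if span > max_span_bp:
                continue  # abandoned; member SNPs are not re-chained
            if len(seg) < min_snps:
                continue
            pv = pvals[seg]
            best = seg[np.lexsort((pos[seg], pv))[0]]
            rows.append({
                "trait": trait, "chrom": chrom,
                "start": int(pos[seg[0]]), "end": int(pos[seg[-1]]),
                "n_snps": int(len(seg)), "lead_pos": int(pos[best]),
                "lead_p": float(pvals[best]),
            })
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def hotspot_density(loci: pd.DataFrame, window_bp: int = 5_000_000,
                    chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Count lead SNPs per tiling window per chromosome.

    Windows tile each chromosome from position 1 up to the chromosome
    length (defaults to the last lead position seen).  Returns
    ``chrom, start0, end, n_leads``.
    """
    rows = []
    if len(loci) == 0 and not chrom_lengths:
        return pd.DataFrame(columns=["chrom", "start0", "end", "n_leads"])
    chroms = (list(chrom_lengths) if chrom_lengths
              else list(pd.unique(loci["chrom"])))
    for chrom in chroms:
        sub = loci[loci["chrom"] == chrom] if len(loci) else loci
        length = (chrom_lengths[chrom] if chrom_lengths
                  else int(sub["lead_pos"].max()))
        n_win = int((length - 1) // window_bp) + 1
        counts = np.zeros(n_win, dtype=int)
        if len(sub):
            idx = ((sub["lead_pos"].to_numpy() - 1) // window_bp).astype(int)
            np.add.at(counts, idx, 1)
        for w in range(n_win):
            rows.append({"chrom": chrom, "start0": w * window_bp,
                         "end": (w + 1) * window_bp, "n_leads": counts[w]})
    return pd.DataFrame(rows, columns=["chrom", "start0", "end", "n_leads"])


def density_correlation(lead_counts, snp_counts, gene_counts=None):
    """Pearson correlation of window-wise lead-SNP counts with densities.

    Returns ``(r_lead_snp, r_lead_gene)``; a correlation with a constant
    vector is undefined and reported as NaN.  ``gene_counts`` may be
    omitted (second element then NaN).
    """
    def _r(a, b):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) != len(b):
            raise ValueError("window vectors are not aligned")
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r_snp = _r(lead_counts, snp_counts)
    r_gene = _r(lead_counts, gene_counts) if gene_counts is not None else float("nan")
    return r_snp, r_gene


def colocalize(loci_a: pd.DataFrame, loci_b: pd.DataFrame) -> pd.DataFrame:
    """Pairs of loci on the same chromosome with intersecting intervals.

    Intervals are closed [start, end]; a shared endpoint counts as an
    overlap.  Returns one row per overlapping (a, b) pair with both
    traits and coordinates.
    """
    rows = []
    for _, la in loci_a.iterrows():
        sub = loci_b[loci_b["chrom"] == la["chrom"]]
        for _, lb in sub.iterrows():
            if la["start"] <= lb["end"] and lb["start"] <= la["end"]:
                rows.append({
                    "chrom": la["chrom"],
                    "trait_a": la.get("trait", "a"), "start_a": la["start"],
                    "end_a": la["end"],
                    "trait_b": lb.get("trait", "b"), "start_b": lb["start"],
                    "end_b": lb["end"],
                })
    return pd.DataFrame(rows, columns=["chrom", "trait_a", "start_a", "end_a",
                                       "trait_b", "start_b", "end_b"])
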