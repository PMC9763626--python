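"""Wilting-grade phenotyping and the drought-sensitivity index (DSI).

Seedlings scored under progressive drought are graded 0-4 from the
fraction of wilted leaves at 72, 96 and 120 h.  The DSI of an accession
is the mean of the three per-timepoint mean grades (replicates averaged
first); low DSI marks drought-resistant material.  The cohort is split
into extreme resistant (R) / sensitive (S) tails plus an intermediate
remainder for downstream group contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS_H",
    "wilting_rate_to_grade",
    "compute_dsi",
    "classify_extremes",
    "summary_stats",
]

TIMEPOINTS_H = (72, 96, 120)

# grade bins: 0 iff rate == 0, then half-open quartile bins
_GRADE_EDGES = (0.0, 0.25, 0.50, 0.75)


def wilting_rate_to_grade(rate):
    """Map wilting rate(s) in [0, 1] to ordinal grades 0-4.

    Grade 0 iff rate == 0; 1 for (0, 0.25]; 2 for (0.25, 0.50];
    3 for (0.50, 0.75]; 4 for (0.75, 1].  NA passes through as NA.
    Scalar input returns a scalar (or nan); array input an array.
    """
    arr = np.asarray(rate, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 0) | (arr[valid] > 1)):
        raise ValueError("wilting rate must lie in [0, 1]")
    grade = np.full(arr.shape, np.nan)
    g = np.zeros(valid.sum())
    r = arr[valid]
    for edge in _GRADE_EDGES:
        g += (r > edge).astype(float)
    grade[valid] = g
    return float(grade[0]) if scalar else grade


def compute_dsi(grades: pd.DataFrame) -> pd.DataFrame:
    """Per-accession DSI from a grade table.

    ``grades`` needs columns ``accession, replicate, timepoint_h`` and
    either ``grade`` or ``wilting_rate`` (graded on the fly).  Within
    each timepoint, grades are averaged over non-NA replicates; the DSI
    is the mean of the three timepoint means and NA when any timepoint
    has no non-NA replicate.
    """
    df = grades.copy()
    bad = set(df["timepoint_h"].unique()) - set(TIMEPOINTS_H)
    if bad:
        raise ValueError(f"unknown timepoint labels: {sorted(bad)}")
    if "grade" not in df.columns:
        df["grade"] = wilting_rate_to_grade(df["wilting_rate"].to_numpy())
    tp_mean = (
        df.groupby(["accession", "timepoint_h"])["grade"]
        .mean()  # skips NA; empty -> NaN
        .unstack("timepoint_h")
        .reindex(columns=list(TIMEPOINTS_H))
    )
    dsi = tp_mean.mean(axis=1, skipna=False)  # any NA timepoint -> NA
    out = pd.DataFrame({"accession": tp_mean.index, "dsi": dsi.to_numpy()})
    for tp in TIMEPOINTS_H:
        out[f"grade_{tp}h"] = tp_mean[tp].to_numpy()
    return out.reset_index(drop=True)


def classify_extremes(dsi: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Label the k lowest-DSI accessions R, the k highest S, rest intermediate.

    Ties are broken by accession ID (lexicographic) so the partition is
    deterministic.  Accessions with NA DSI stay intermediate.
    """
    out = dsi.copy()
    valid = out.dropna(subset=["dsi"])
    if k < 0:
        raise ValueError("k must be non-negative")
    if 2 * k > len(valid):
        raise ValueError(f"2k = {2 * k} exceeds {len(valid)} scored accessions")
    order = valid.sort_values(
        ["dsi", "accession"], kind="mergesort"
    )["accession"].to_numpy()
    labels = pd.Series("intermediate", index=out["accession"].to_numpy())
    if k > 0:
        labels.loc[order[:k]] = "R"
        labels.loc[order[-k:]] = "S"
    out["resistance_class"] = labels.loc[out["accession"]].to_numpy()
    return out


def summary_stats(dsi: pd.DataFrame, below: float | None = None,
                  above: float | None = None) -> dict:
    """Cohort DSI summaries: mean, CV, and optional threshold counts.

    CV is the sample (n-1) standard deviation divided by the mean.
    ``below``/``above`` ask for strict counts of accessions with
    DSI < below and DSI > above.
    """
    vals = dsi["dsi"].dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError("need at least two non-NA DSI values")
    mean = float(vals.mean())
    cv = float(vals.std(ddof=1) / mean) if mean != 0 else float("nan")
    out = {"n": int(len(vals)), "mean": mean, "cv": cv}
    if below is not None:
        out["n_below"] = int((vals < below).sum())
    if above is not None:
        out["n_above"] = int((vals > above).sum())
    return out
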