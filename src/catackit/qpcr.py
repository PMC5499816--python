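"""Comparative-Ct qRT-PCR time-course analysis.

Relative expression of a target transcript versus a reference gene is
computed per matched replicate as ``2**-(Ct_target - Ct_reference)``; timed
profiles are then normalised to the time-course average so that the mean of
per-timepoint means equals one.  Rhythmic regulation across timepoints is
tested with Kruskal-Wallis on replicate-level normalised values, and the peak
phase is the timepoint with the highest mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionProfile:
    gene: str
    timepoints: np.ndarray
    mean_rel_expr: np.ndarray
    sem_rel_expr: np.ndarray
    kw_h: float | None = None
    kw_p: float | None = None
    peak: float | None = None


def _as_ct_frame(df: pd.DataFrame) -> pd.DataFrame:
    required = {"timepoint", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def relative_expression(target: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate relative levels ``2**-(Ct_target - Ct_reference)``.

    Target and reference measurements are paired on (timepoint, replicate);
    an unmatched replicate structure is an error.
    """
    t = _as_ct_frame(target)
    r = _as_ct_frame(reference)
    merged = t.merge(
        r, on=["timepoint", "replicate"], suffixes=("_target", "_reference"), how="outer",
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        raise ValueError("target and reference replicate structures do not match")
    out = merged[["timepoint", "replicate"]].copy()
    out["rel_expr"] = 2.0 ** -(merged["ct_target"] - merged["ct_reference"])
    return out.sort_values(["timepoint", "replicate"]).reset_index(drop=True)


def normalize_to_time_course_mean(levels: pd.DataFrame) -> pd.DataFrame:
    """Divide replicate levels by the grand mean of per-timepoint means."""
    if levels["timepoint"].nunique() < 2:
        raise ValueError("need >= 2 timepoints")
    grand = levels.groupby("timepoint")["rel_expr"].mean().mean()
    out = levels.copy()
    out["rel_expr"] = out["rel_expr"] / grand
    return out


def normalize_profile(levels: pd.DataFrame, gene: str = "") -> ExpressionProfile:
    """Time-course-average-normalised profile with per-timepoint mean and SEM."""
    norm = normalize_to_time_course_mean(levels)
    g = norm.groupby("timepoint")["rel_expr"]
    means = g.mean()
    sems = g.sem()
    return ExpressionProfile(
        gene=gene,
        timepoints=means.index.to_numpy(dtype=float),
        mean_rel_expr=means.to_numpy(),
        sem_rel_expr=sems.to_numpy(),
    )


def rhythm_test(levels: pd.DataFrame, gene: str = "") -> ExpressionProfile:
    """Kruskal-Wallis across timepoints plus peak-phase call.

    Works on replicate-level normalised relative levels (the rank test is
    invariant to the global normalisation).  All-tied inputs yield H = 0 and
    p = 1; the peak is the leftmost timepoint achieving the maximal mean.
    """
    profile = normalize_profile(levels, gene=gene)
    norm = normalize_to_time_course_mean(levels)
    samples = [g["rel_expr"].to_numpy() for _, g in norm.groupby("timepoint")]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 replicates per timepoint")
    flat = np.concatenate(samples)
    if np.allclose(flat, flat[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    profile.kw_h = float(h)
    profile.kw_p = float(p)
    profile.peak = float(profile.timepoints[int(np.argmax(profile.mean_rel_expr))])
    return profile


def analyze_ct_table(
    ct: pd.DataFrame, reference_gene: str = "reference"
) -> dict[str, ExpressionProfile]:
    """Full comparative-Ct pipeline for every non-reference gene in a table."""
    genes = [g for g in ct["gene"].unique() if g != reference_gene]
    reference = ct[ct["gene"] == reference_gene]
    if reference.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    out = {}
    for gene in genes:
        levels = relative_expression(ct[ct["gene"] == gene], reference)
        out[gene] = rhythm_test(levels, gene=gene)
    return out


def profile_frame(profiles: dict[str, ExpressionProfile]) -> pd.DataFrame:
    """Flatten profiles into a tidy frame (gene, timepoint, mean, sem, p, peak)."""
    rows = []
    for gene, prof in profiles.items():
        for t, m, s in zip(prof.timepoints, prof.mean_rel_expr, prof.sem_rel_expr):
            rows.append(
                {
                    "gene": gene,
                    "timepoint": t,
                    "mean_rel_expr": m,
                    "sem_rel_expr": s,
                    "kw_p": prof.kw_p,
                    "peak": prof.peak,
                }
            )
    return pd.DataFrame(rows)
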