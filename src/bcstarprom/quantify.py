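"""Count normalization, fold changes, drug-response ranking and clustering.

The screen readout is a barcode x sample count table. Sequencing depth is
equalized by median normalization: each count is divided by its sample
(column) median and rescaled by the median over all entries of the table so
the values stay on a read-count-like scale. Induction is expressed as the
fold change of each barcode relative to the average of the control samples
(non-treated time 0 and vehicle/DMSO time points), and barcodes are ranked
by the ratio of mean drug fold change to mean control fold change over the
post-treatment time series (1, 2, 4, 8 h). The strongest responders from
replicate screens are merged and clustered (complete linkage, Euclidean
distance on log2 fold-change profiles) into kinetic response groups.

Numerical note: fold changes are computed from the per-column median-scaled
component of the normalized table (carried in ``attrs``). The global
rescaling constant cancels in the control ratio anyway; cancelling it
structurally makes fold changes, scores and rankings exactly invariant to
rescaling any sample's counts, which is the property that makes the ranking
comparable across sequencing depths.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigError, QCError
from .read_processing import SampleSheet

__all__ = [
    "median_normalize",
    "control_samples",
    "fold_changes",
    "drug_response_score",
    "promoter_profiles",
    "merge_replicates_and_cluster",
    "cv_filter",
]

DEFAULT_DRUG_TIMES = (1, 2, 4, 8)
DEFAULT_CONTROL_TREATMENTS = ("DMSO",)


def median_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize a count table.

    value'[b, s] = value[b, s] / median(column s) * median(all entries).
    The returned frame carries the pre-rescaling component in
    ``attrs['depth_normalized']`` and the scaling constants in ``attrs``.
    """
    col_medians = counts.median(axis=0)
    zero = col_medians[col_medians <= 0]
    if len(zero):
        raise QCError(
            f"zero-median sample column(s): {', '.join(map(str, zero.index))}"
        )
    m = counts.div(col_medians, axis=1)
    g = float(np.median(counts.to_numpy()))
    norm = m * g
    norm.attrs["depth_normalized"] = m
    norm.attrs["column_medians"] = col_medians
    norm.attrs["global_median"] = g
    return norm


def control_samples(
    sheet: SampleSheet,
    control_treatments: Sequence[str] = DEFAULT_CONTROL_TREATMENTS,
    include_time0: bool = True,
) -> list[str]:
    """Control columns: vehicle-treated samples plus (optionally) all time-0."""
    f = sheet.frame
    mask = f["treatment"].isin(control_treatments)
    if include_time0:
        mask |= f["time"] == 0
    return list(f.loc[mask, "sample_id"])


def fold_changes(
    normalized: pd.DataFrame,
    sheet: SampleSheet,
    control_treatments: Sequence[str] = DEFAULT_CONTROL_TREATMENTS,
    include_time0: bool = True,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-barcode fold change of every sample vs. the control average.

    FC[b, s] = (n[b, s] + pc) / mean over controls of (n[b, c] + pc), with n
    the depth-normalized values. The default pseudocount is 0: the upstream
    filter keeps only barcodes present in every sample, so zeros cannot
    occur, and a nonzero pseudocount would break exact depth invariance.
    """
    controls = control_samples(sheet, control_treatments, include_time0)
    controls = [c for c in controls if c in normalized.columns]
    if not controls:
        raise ConfigError("no control samples found in the normalized table")
    m = normalized.attrs.get("depth_normalized")
    if m is None:
        m = normalized.div(normalized.median(axis=0), axis=1)
    m = m + pseudocount
    ctrl_mean = m[controls].mean(axis=1)
    if (ctrl_mean <= 0).any():
        raise QCError("non-positive control mean; increase pseudocount")
    fc = m.div(ctrl_mean, axis=0)
    fc.attrs["controls"] = controls
    return fc


def drug_response_score(
    fc: pd.DataFrame,
    sheet: SampleSheet,
    drug: str,
    drug_times: Sequence[float] = DEFAULT_DRUG_TIMES,
    control_treatments: Sequence[str] = DEFAULT_CONTROL_TREATMENTS,
) -> pd.DataFrame:
    """Rank barcodes by mean drug fold change over mean control fold change.

    score(b) = mean(FC[b, drug, t in drug_times]) / mean(FC[b, ctrl, t in
    drug_times]); control columns are whichever vehicle time points exist
    within ``drug_times``. Ties are broken lexicographically by barcode.
    Returns a frame (barcode index, score, rank) in descending score order.
    """
    f = sheet.frame
    drug_cols, missing = [], []
    for t in drug_times:
        cols = f.loc[(f["treatment"] == drug) & (f["time"] == t), "sample_id"]
        cols = [c for c in cols if c in fc.columns]
        if cols:
            drug_cols.extend(cols)
        else:
            missing.append(t)
    if missing:
        raise ConfigError(f"missing {drug} sample(s) at time(s) {missing}")
    ctrl_cols = [
        c
        for c in f.loc[
            f["treatment"].isin(control_treatments) & f["time"].isin(drug_times),
            "sample_id",
        ]
        if c in fc.columns
    ]
    if not ctrl_cols:
        raise ConfigError("no control samples at the requested times")
    score = fc[drug_cols].mean(axis=1) / fc[ctrl_cols].mean(axis=1)
    out = pd.DataFrame({"score": score})
    out.index.name = "barcode"
    # stable sort after an index sort -> ties broken lexicographically
    out = out.sort_index().sort_values("score", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def promoter_profiles(
    fc: pd.DataFrame,
    barcode_to_promoter: dict[str, str],
    log2: bool = True,
) -> pd.DataFrame:
    """Collapse barcode-level fold changes to promoter-level (log2) profiles.

    Promoters carried by several barcodes are averaged -- those internal
    replicates show near-identical patterns, which is the design's built-in
    QC.
    """
    sub = fc.loc[fc.index.isin(barcode_to_promoter)]
    prom = sub.groupby(sub.index.map(barcode_to_promoter)).mean()
    prom.index.name = "promoter_id"
    return np.log2(prom) if log2 else prom


def merge_replicates_and_cluster(
    rankings: Sequence[pd.DataFrame],
    profiles: pd.DataFrame,
    top_k: int = 20,
    k_groups: int = 4,
) -> pd.Series:
    """Cluster the union of each replicate's strongest responders.

    ``rankings`` are promoter-level score frames (descending); the top
    ``top_k`` promoters of each are merged, and their (log2 fold-change)
    profile vectors are clustered by complete-linkage agglomeration on
    Euclidean distance, cutting the tree into ``k_groups`` groups. Input
    order is fixed by sorting the merged set, making the assignment
    deterministic.
    """
    if not rankings:
        raise ConfigError("need at least one replicate ranking")
    merged: set[str] = set()
    for r in rankings:
        merged.update(r.index[:top_k])
    merged &= set(profiles.index)
    if len(merged) < k_groups:
        raise ConfigError(
            f"merged set of {len(merged)} promoters is smaller than "
            f"k_groups={k_groups}"
        )
    members = sorted(merged)
    x = profiles.loc[members].to_numpy()
    z = linkage(x, method="complete", metric="euclidean")
    labels = fcluster(z, t=k_groups, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(members, name="promoter_id"), name="group")


def cv_filter(values: Iterable[float], max_cv: float = 0.12) -> tuple[bool, float]:
    """Coefficient-of-variation gate (sample SD / mean), kept iff cv < max_cv.

    Mirrors the transfection-uniformity QC in which only dishes with similar
    reporter expression (CV below 12%) enter the screen.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("cv_filter needs at least two values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("cv_filter expects positive values")
    cv = float(vals.std(ddof=1) / mean)
    return cv < max_cv, cv
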