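"""Cross-dataset harmonization of telomere-content estimates.

Raw per-sample contents are log-transformed and z-scored within each
source. Exome sources can carry a technical batch effect visible in the
frequencies of reads containing exactly 4, 5, and 6 telomeric motifs;
k-means on those three frequencies recovers the two batches, and the
minority batch is re-centered onto the majority batch's mean. Sources are
then merged per cell line, averaging z-scores where a line was profiled in
both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import logger


@dataclass
class GroupComparison:
    """Kruskal-Wallis across groups plus a focal-group Mann-Whitney U."""

    h_statistic: float
    h_pvalue: float
    focal_group: str | None = None
    u_statistic: float | None = None
    u_pvalue: float | None = None


def log_z(
    values: pd.Series | np.ndarray,
    log_base: float = 2.0,
    ddof: int = 0,
) -> pd.Series:
    """Z-score of log-transformed values (population SD by default).

    Zeros and non-finite entries are excluded (returned as NaN) with a
    warning; fewer than two usable values is an error because the SD is
    undefined or zero.
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(
        values, pd.Series
    ) else values.astype(float)
    usable = s.notna() & np.isfinite(s) & (s > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("log_z: excluding %d nonpositive/missing values", n_dropped)
    if usable.sum() < 2:
        raise ValueError("log_z requires >= 2 finite positive values")
    logs = np.log(s[usable].to_numpy()) / math.log(log_base)
    sd = logs.std(ddof=ddof)
    if sd == 0:
        raise ValueError("log_z: zero variance after log transform")
    out = pd.Series(np.nan, index=s.index, dtype=float)
    out[usable] = (logs - logs.mean()) / sd
    return out


def detect_batches(
    features: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> pd.Series:
    """Cluster samples into batches from motif-frequency features.

    Parameters
    ----------
    features:
        samples x {freq4, freq5, freq6} frequencies in [0, 1], used raw
        (no rescaling).
    Returns
    -------
    Integer labels indexed like ``features``; clusters are renumbered so
    that cluster 0 is the largest (the reference batch).
    """
    from sklearn.cluster import KMeans

    x = features.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return pd.Series(0, index=features.index)
    if len(features) < 2 * k:
        raise ValueError(f"need >= {2 * k} samples for k={k}")
    if np.allclose(x, x[0]):
        raise ValueError("all feature vectors identical; batches undetectable")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    # renumber by decreasing cluster size, ties by original label
    order = sorted(range(k), key=lambda c: (-(raw == c).sum(), c))
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=features.index)


def recenter(z_values: pd.Series, batch_labels: pd.Series) -> pd.Series:
    """Shift the non-reference batch so its mean matches the reference.

    Within-batch ordering is preserved exactly (pure location shift).
    """
    labels = batch_labels.reindex(z_values.index)
    present = sorted(labels.dropna().unique())
    if len(present) != 2:
        raise ValueError(f"recenter expects exactly two batch labels, got {present}")
    ref, other = present
    ref_mask = labels == ref
    other_mask = labels == other
    for name, mask in (("reference", ref_mask), ("non-reference", other_mask)):
        if mask.sum() < 2:
            logger.warning("recenter: %s batch has < 2 members", name)
    shift = z_values[ref_mask].mean() - z_values[other_mask].mean()
    out = z_values.copy()
    out[other_mask] = out[other_mask] + shift
    return out


def merge(z_a: pd.Series, z_b: pd.Series) -> pd.DataFrame:
    """Merge two per-source z-score vectors into one content vector.

    Samples present in both sources get the arithmetic mean of the two
    z-values; samples in one source keep that value. Duplicate sample
    identifiers within a source are an error (collapse replicates first).
    """
    for name, s in (("a", z_a), ("b", z_b)):
        dups = s.index[s.index.duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicate samples in source {name}: {dups}")
    df = pd.DataFrame({"z_a": z_a, "z_b": z_b})
    df["content"] = df[["z_a", "z_b"]].mean(axis=1)
    df["n_sources"] = df[["z_a", "z_b"]].notna().sum(axis=1)
    return df


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    focal_group: str | None = None,
) -> GroupComparison:
    """Kruskal-Wallis H across groups; optional focal group vs rest MWU.

    Groups with all-missing values are excluded with a warning; ties are
    handled by midranks in both tests.
    """
    groups = groups.reindex(values.index)
    valid = values.notna() & groups.notna()
    values, groups = values[valid], groups[valid]
    arrays = []
    for g, sub in values.groupby(groups):
        if sub.empty:
            logger.warning("group_compare: group %s has no values; excluded", g)
            continue
        arrays.append(sub.to_numpy())
    if len(arrays) < 2:
        raise ValueError("group_compare requires >= 2 non-empty groups")
    h, hp = stats.kruskal(*arrays)
    result = GroupComparison(h_statistic=float(h), h_pvalue=float(hp))
    if focal_group is not None:
        in_focal = values[groups == focal_group].to_numpy()
        rest = values[groups != focal_group].to_numpy()
        if len(in_focal) == 0 or len(rest) == 0:
            raise ValueError(f"focal group {focal_group!r} or its complement empty")
        u, up = stats.mannwhitneyu(in_focal, rest, alternative="two-sided")
        result.focal_group = focal_group
        result.u_statistic = float(u)
        result.u_pvalue = float(up)
    return result


def harmonize_sources(
    raw_a: pd.Series,
    raw_b: pd.Series,
    batch_features_b: pd.DataFrame | None = None,
    log_base: float = 2.0,
    kmeans_seed: int = 0,
    kmeans_restarts: int = 10,
) -> pd.DataFrame:
    """End-to-end: log-z each source, batch-correct source b, merge.

    Returns the merged frame with z_a, z_b (post-correction), content and
    n_sources columns, plus batch labels for source b when correction ran.
    """
    z_a = log_z(raw_a, log_base=log_base)
    z_b = log_z(raw_b, log_base=log_base)
    labels = None
    if batch_features_b is not None:
        labels = detect_batches(
            batch_features_b, k=2, seed=kmeans_seed, n_init=kmeans_restarts
        )
        z_b = recenter(z_b, labels)
        # re-standardize after the shift so the source contract (mean 0,
        # SD 1) holds for merging
        z_b = (z_b - z_b.mean()) / z_b.std(ddof=0)
    merged = merge(z_a, z_b)
    if labels is not None:
        merged["batch_b"] = labels.reindex(merged.index)
    return merged
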