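"""Gene-dependency association analyses.

Dependency matrices are genes x cell lines, with more negative scores
indicating greater dependence on a gene. Three analyses are provided:

* per-gene Pearson correlation of dependency with a sample-level target
  (e.g. telomere content), p-values from the two-tailed t distribution;
* recursive codependency expansion: starting from a seed set, a gene
  joins when its squared correlation with a current member ranks in the
  member's top-k over all other genes and vice versa; applied for a fixed
  number of rounds against the full gene universe;
* mutation-dependency association: rank-biserial effect (mutant vs
  wild-type dependency ranks) with a two-sided Mann-Whitney U p-value,
  excluding genes with fewer than ``min_mutants`` mutant lines.

Families of p-values are Benjamini-Hochberg adjusted and ranked by the
signed q-value, sign(effect) * -log10(q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import logger

DEFAULT_TOP_K = 5
DEFAULT_ITERATIONS = 4
DEFAULT_MIN_MUTANTS = 5
DEFAULT_MIN_N = 10

_Q_FLOOR = 1e-300


@dataclass
class AssociationResult:
    feature: str
    effect: float  # Pearson r or rank-biserial, in [-1, 1]
    p: float
    n: int
    q: float | None = None
    signed_q: float | None = None


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[mask], y[mask]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def correlate(
    matrix: pd.DataFrame,
    target: pd.Series,
    min_n: int = 3,
) -> list[AssociationResult]:
    """Pearson r (with two-tailed t p) of each gene row against a target.

    Pairwise-complete masking per gene; genes with fewer than ``min_n``
    complete pairs, or zero variance, are flagged undefined (NaN effect)
    with a log entry.
    """
    target = target.reindex(matrix.columns).to_numpy(dtype=float)
    results, skipped = [], 0
    for gene, row in matrix.iterrows():
        r, p, n = _pearson_with_p(row.to_numpy(dtype=float), target)
        if n < min_n or not np.isfinite(r):
            skipped += 1
            results.append(AssociationResult(feature=gene, effect=np.nan, p=np.nan, n=n))
        else:
            results.append(AssociationResult(feature=gene, effect=r, p=p, n=n))
    if skipped:
        logger.info("correlate: %d genes undefined (low n or zero variance)", skipped)
    return results


def _top_k_sets(r2: pd.DataFrame, top_k: int) -> dict[str, set[str]]:
    """Per gene: the set of genes whose r2 ranks in its top k (self
    excluded); ties at the k-th value are all admitted."""
    tops: dict[str, set[str]] = {}
    genes = r2.index
    values = r2.to_numpy(copy=True)
    np.fill_diagonal(values, -np.inf)
    for i, g in enumerate(genes):
        row = values[i]
        order = np.argsort(row)[::-1]
        if top_k >= len(order):
            cutoff = -np.inf
        else:
            cutoff = row[order[top_k - 1]]
        members = {genes[j] for j in np.flatnonzero(row >= cutoff)}
        members.discard(g)
        tops[g] = members
    return tops


def pairwise_r2(matrix: pd.DataFrame, min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """Squared pairwise-complete Pearson correlations between gene rows."""
    r = matrix.T.corr(min_periods=min_n)
    return r**2


def codependency_expand(
    seed: list[str] | set[str],
    matrix: pd.DataFrame,
    top_k: int = DEFAULT_TOP_K,
    iterations: int = DEFAULT_ITERATIONS,
    min_n: int = DEFAULT_MIN_N,
) -> set[str]:
    """Grow a seed gene set by mutual top-k codependency, ``iterations``
    times; rankings are against the full gene universe each round."""
    seed = set(seed)
    missing = seed - set(matrix.index)
    if missing:
        raise KeyError(f"seed genes absent from matrix: {sorted(missing)}")
    if iterations == 0 or not seed:
        return set(seed)
    # round so that ties at the k-th rank are detected stably regardless of
    # the floating-point path that produced the correlations
    r2 = pairwise_r2(matrix, min_n=min_n).round(12).fillna(-np.inf)
    tops = _top_k_sets(r2, top_k)
    current = set(seed)
    for _ in range(iterations):
        additions = set()
        for x in current:
            for y in tops[x]:
                if y not in current and x in tops[y]:
                    additions.add(y)
        if not additions:
            break
        current |= additions
    return current


def rank_biserial(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Rank-biserial correlation, 2*P(a > b) - 1 with midrank ties.

    -1 when every value in ``group_a`` is below every value in
    ``group_b``; +1 for the reverse; ~0 for exchangeable groups.
    """
    u_a, _ = stats.mannwhitneyu(group_a, group_b, alternative="two-sided")
    return float(2.0 * u_a / (len(group_a) * len(group_b)) - 1.0)


def mutation_association(
    dep_row: pd.Series,
    mut_row: pd.Series,
    min_mutants: int = DEFAULT_MIN_MUTANTS,
    feature: str = "",
) -> AssociationResult | None:
    """Rank-biserial + two-sided Mann-Whitney U of dependency by mutation.

    Negative effect means mutants are more dependent (lower scores).
    Returns None (excluded) when there are fewer than ``min_mutants``
    mutants, or no wild-type samples, on the common complete samples.
    """
    common = dep_row.index.intersection(mut_row.index)
    dep = dep_row.reindex(common).to_numpy(dtype=float)
    mut = mut_row.reindex(common).to_numpy(dtype=float)
    mask = np.isfinite(dep) & np.isfinite(mut)
    dep, mut = dep[mask], mut[mask].astype(bool)
    n_mut = int(mut.sum())
    n_wt = int((~mut).sum())
    if n_mut < min_mutants or n_wt == 0 or n_mut == len(mut):
        return None
    mutant, wildtype = dep[mut], dep[~mut]
    effect = rank_biserial(mutant, wildtype)
    _, p = stats.mannwhitneyu(mutant, wildtype, alternative="two-sided")
    return AssociationResult(feature=feature, effect=effect, p=float(p), n=n_mut + n_wt)


def signed_q(results: list[AssociationResult], alpha: float = 0.01) -> pd.DataFrame:
    """BH-adjust the family and attach signed q-values.

    signed_q = sign(effect) * -log10(q); the returned frame is sorted by
    signed_q ascending (strongest negative associations first).
    """
    tested = [r for r in results if np.isfinite(r.p)]
    if not tested:
        raise ValueError("signed_q: empty family of tested results")
    pvals = np.array([r.p for r in tested])
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for r, q in zip(tested, qvals):
        r.q = float(q)
        r.signed_q = float(np.sign(r.effect) * -np.log10(max(q, _Q_FLOOR)))
    frame = pd.DataFrame(
        {
            "feature": [r.feature for r in tested],
            "effect": [r.effect for r in tested],
            "p": [r.p for r in tested],
            "q": [r.q for r in tested],
            "signed_q": [r.signed_q for r in tested],
            "n": [r.n for r in tested],
        }
    )
    return frame.sort_values("signed_q", kind="mergesort").reset_index(drop=True)


def cluster_codependency(
    genes: list[str],
    matrix: pd.DataFrame,
    min_n: int = DEFAULT_MIN_N,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Pairwise Pearson matrix on a gene subset with Ward clustering.

    Distances are 1 - r; undefined correlations are imputed as 0 with a
    warning. Returns (correlation matrix, linkage, leaf-ordered genes).
    """
    if len(genes) < 3:
        raise ValueError("cluster_codependency requires >= 3 genes")
    sub = matrix.loc[list(genes)]
    corr = sub.T.corr(min_periods=min_n)
    if corr.isna().any().any():
        logger.warning("cluster_codependency: undefined correlations imputed as 0")
        corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    dist = 1.0 - corr.to_numpy()
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    order = [corr.index[i] for i in leaves_list(z)]
    return corr, z, order


# ---------------------------------------------------------------------------
# Molecular-feature prefilters used ahead of marker association scans


def filter_expression(
    tpm: pd.DataFrame, min_sd: float = 0.25, log_transform: bool = True
) -> pd.DataFrame:
    """log2(TPM + 1) transform, then drop features with SD below 0.25."""
    x = np.log2(tpm + 1.0) if log_transform else tpm
    return x[x.std(axis=1, ddof=0) >= min_sd]


def filter_exon_inclusion(
    inclusion: pd.DataFrame, max_missing: int = 800, min_sd: float = 0.1
) -> pd.DataFrame:
    """Drop exons missing in more than ``max_missing`` samples or with SD
    below 0.1."""
    keep = (inclusion.isna().sum(axis=1) <= max_missing) & (
        inclusion.std(axis=1, ddof=0) >= min_sd
    )
    return inclusion[keep]


def filter_methylation(regions: pd.DataFrame, min_sd: float = 0.05) -> pd.DataFrame:
    """Drop methylation regions with SD below 0.05."""
    return regions[regions.std(axis=1, ddof=0) >= min_sd]
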