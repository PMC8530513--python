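"""Region-set enrichment of differentially methylated CpG islands.

CpG islands are ranked by the significance of methylation differences
between two sample groups (e.g. TERT-promoter mutant vs wild-type) with a
two-sided Mann-Whitney U test, keeping the islands hypomethylated in the
mutant group. The top-ranked islands form the interest set, all tested
islands the universe, and each annotated region set is tested for overlap
enrichment with a two-sided Fisher exact test on the 2x2 table

    a = interest overlapping set    b = interest not overlapping
    c = rest overlapping set        d = rest not overlapping

"Overlap" is any >= 1 bp intersection. A telomere-proximity variant
classifies a region as proximal when it starts within ``window`` bp of
either chromosome end. Families of region sets are BH-adjusted together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import logger
from .regions import Region, RegionSet

DEFAULT_TOP_N = 1000
DEFAULT_TELOMERE_WINDOW = 10_000_000


@dataclass
class EnrichmentResult:
    region_set: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float | None = None
    continuity_corrected: bool = False


@dataclass
class DifferentialCGI:
    """Per-island group comparison."""

    name: str
    p: float
    rank_biserial: float  # negative: hypomethylated in the focal group
    n_focal: int
    n_other: int


def rank_differential_cgis(
    cgi_methylation: pd.DataFrame,
    group_labels: pd.Series,
    focal_group,
    direction: str = "hypo",
    min_group_size: int = 2,
) -> tuple[list[str], pd.DataFrame]:
    """Rank islands by group-difference significance in one direction.

    Parameters
    ----------
    cgi_methylation:
        samples x islands beta matrix (NaN allowed).
    group_labels:
        per-sample labels; ``focal_group`` picks the group whose
        hypomethylation ("hypo") or hypermethylation ("hyper") defines the
        direction of interest.

    Returns the ordered island names (ascending p within the chosen
    direction) and the full per-island statistics table.
    """
    if direction not in {"hypo", "hyper"}:
        raise ValueError("direction must be 'hypo' or 'hyper'")
    labels = group_labels.reindex(cgi_methylation.index)
    focal_mask = (labels == focal_group).to_numpy()
    other_mask = (labels.notna() & (labels != focal_group)).to_numpy()
    values = cgi_methylation.to_numpy(dtype=float)
    rows, skipped = [], 0
    complete = np.isfinite(values).all()
    if complete and focal_mask.sum() >= min_group_size and \
            other_mask.sum() >= min_group_size:
        # complete-case fast path: one vectorized test across all islands
        focal = values[focal_mask]
        other = values[other_mask]
        u, p = stats.mannwhitneyu(focal, other, axis=0, alternative="two-sided")
        rb = 2.0 * u / (focal.shape[0] * other.shape[0]) - 1.0
        rows = [
            DifferentialCGI(
                name=name, p=float(p[j]), rank_biserial=float(rb[j]),
                n_focal=focal.shape[0], n_other=other.shape[0],
            )
            for j, name in enumerate(cgi_methylation.columns)
        ]
    else:
        for j, name in enumerate(cgi_methylation.columns):
            col = values[:, j]
            focal = col[focal_mask & np.isfinite(col)]
            other = col[other_mask & np.isfinite(col)]
            if len(focal) < min_group_size or len(other) < min_group_size:
                skipped += 1
                continue
            u, p = stats.mannwhitneyu(focal, other, alternative="two-sided")
            rb = 2.0 * u / (len(focal) * len(other)) - 1.0
            rows.append(
                DifferentialCGI(
                    name=name, p=float(p), rank_biserial=float(rb),
                    n_focal=len(focal), n_other=len(other),
                )
            )
    if skipped:
        logger.info("rank_differential_cgis: %d islands skipped (group too small)", skipped)
    table = pd.DataFrame(
        {
            "cgi": [r.name for r in rows],
            "p": [r.p for r in rows],
            "rank_biserial": [r.rank_biserial for r in rows],
            "n_focal": [r.n_focal for r in rows],
            "n_other": [r.n_other for r in rows],
        }
    )
    want_negative = direction == "hypo"
    directed = table[
        (table["rank_biserial"] < 0) if want_negative else (table["rank_biserial"] > 0)
    ]
    ordered = directed.sort_values(["p", "cgi"], kind="mergesort")["cgi"].tolist()
    return ordered, table


def select_interest(
    ranked: list[str],
    universe: RegionSet,
    n: int = DEFAULT_TOP_N,
) -> RegionSet:
    """The first ``n`` ranked islands as a RegionSet (all, with a warning,
    when fewer are available)."""
    if len(ranked) < n:
        logger.warning(
            "select_interest: only %d ranked regions available (< %d)", len(ranked), n
        )
    chosen = set(ranked[:n])
    by_name = {r.name: r for r in universe}
    missing = chosen - set(by_name)
    if missing:
        raise KeyError(f"ranked regions absent from universe: {sorted(missing)[:5]}")
    return RegionSet("interest", [by_name[name] for name in chosen])


def _fisher(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Two-sided Fisher exact p (point-probability summation) and sample
    odds ratio, 0.5-continuity-corrected only when a zero cell occurs."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        return float(p), float(odds), True
    return float(p), a * d / (b * c), False


def overlap_enrichment(
    interest: RegionSet,
    universe: RegionSet,
    annotated: RegionSet,
) -> EnrichmentResult:
    """Fisher exact overlap enrichment of the interest set vs the rest of
    the universe against one annotated region set."""
    interest_names = {r.name for r in interest}
    universe_regions = list(universe)
    universe_names = {r.name for r in universe_regions}
    if not interest_names <= universe_names:
        raise ValueError("interest set must be a subset of the universe")
    if len(interest_names) == len(universe_names):
        raise ValueError("interest set equals the universe; no background remains")
    in_interest = np.array([r.name in interest_names for r in universe_regions])
    flags = annotated.overlap_flags(universe_regions)
    a = int((flags & in_interest).sum())
    b = int((~flags & in_interest).sum())
    c = int((flags & ~in_interest).sum())
    d = int((~flags & ~in_interest).sum())
    p, odds, corrected = _fisher(a, b, c, d)
    return EnrichmentResult(
        region_set=annotated.name, a=a, b=b, c=c, d=d,
        odds_ratio=odds, p=p, continuity_corrected=corrected,
    )


def telomere_proximity_enrichment(
    interest: RegionSet,
    universe: RegionSet,
    chrom_sizes: dict[str, int],
    window: int = DEFAULT_TELOMERE_WINDOW,
) -> EnrichmentResult:
    """Enrichment of the interest set among telomere-proximal regions.

    A region is proximal when its start lies within ``window`` bp of the
    chromosome start or its end within ``window`` bp of the chromosome
    end. Regions on chromosomes absent from ``chrom_sizes`` are excluded
    with a log entry.
    """
    interest_names = {r.name for r in interest}
    kept = [r for r in universe if r.chrom in chrom_sizes]
    n_dropped = len(universe) - len(kept)
    if n_dropped:
        logger.info(
            "telomere_proximity: %d regions on unknown chromosomes excluded", n_dropped
        )
    proximal = np.array(
        [
            r.start < window or r.end > chrom_sizes[r.chrom] - window
            for r in kept
        ]
    )
    in_interest = np.array([r.name in interest_names for r in kept])
    a = int((proximal & in_interest).sum())
    b = int((~proximal & in_interest).sum())
    c = int((proximal & ~in_interest).sum())
    d = int((~proximal & ~in_interest).sum())
    p, odds, corrected = _fisher(a, b, c, d)
    return EnrichmentResult(
        region_set=f"telomere_{window}bp", a=a, b=b, c=c, d=d,
        odds_ratio=odds, p=p, continuity_corrected=corrected,
    )


def enrich_region_sets(
    interest: RegionSet,
    universe: RegionSet,
    databases: list[RegionSet],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Test several annotated sets and BH-adjust them as one family."""
    if not databases:
        raise ValueError("no annotated region sets supplied")
    results = [overlap_enrichment(interest, universe, db) for db in databases]
    pvals = np.array([r.p for r in results])
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q = float(q)
    return pd.DataFrame(
        {
            "region_set": [r.region_set for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    ).sort_values("q", kind="mergesort").reset_index(drop=True)
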