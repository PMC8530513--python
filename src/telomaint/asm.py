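"""Allele-specific methylation (ASM) scoring of adjacent CpG pairs.

Reads covering two adjacent CpGs fall into four joint methylation states:
methylated-methylated (mm), methylated-unmethylated (mu), um, and uu. On
an allele-specifically methylated pair, reads come mostly from a fully
methylated allele or a fully unmethylated one, so mm and uu dominate.
The imbalance is scored with the mean square contingency coefficient:

    phi = (mm~ uu~ - mu~ um~) /
          sqrt((mm~ + mu~)(um~ + uu~)(mm~ + um~)(mu~ + uu~))

where x~ = x + 0.5; negative values are rounded to 0, so phi lies in
[0, 1] with positive values indicating ASM.

Per-sample observations pass through three filters before aggregation:
coverage >= 8 reads; the pair must be covered in >= 5% of cohort samples;
and both per-CpG marginal methylation levels must lie in [0.1, 0.9] (to
exclude fully methylated/demethylated pairs). Pair scores aggregate to
regions (the TERT locus subregions, CpG islands) by an unweighted mean
over pairs whose first CpG falls in the region, after excluding pairs
with < 25% valid observations across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import Region, RegionSet

MIN_PAIR_COVERAGE = 8
MIN_PAIR_PREVALENCE = 0.05
METHYLATION_BOUNDS = (0.1, 0.9)
MIN_VALID_FRACTION = 0.25
#: Minimum profiled CpGs per island: 8 for RRBS-style input, 4 for arrays.
MIN_CPGS_RRBS = 8
MIN_CPGS_ARRAY = 4

PAIR_COLUMNS = ["sample", "chrom", "pos_a", "pos_b", "mm", "mu", "um", "uu"]


@dataclass(frozen=True)
class CpGPairCount:
    """Joint methylation-state counts for one CpG pair in one sample."""

    sample: str
    chrom: str
    pos_a: int
    pos_b: int
    mm: int
    mu: int
    um: int
    uu: int

    def __post_init__(self) -> None:
        if self.pos_a >= self.pos_b:
            raise ValueError("pos_a must be < pos_b")
        if min(self.mm, self.mu, self.um, self.uu) < 0:
            raise ValueError("state counts must be >= 0")

    @property
    def coverage(self) -> int:
        return self.mm + self.mu + self.um + self.uu


def phi(mm, mu, um, uu):
    """Mean square contingency coefficient with 0.5 pseudocounts.

    Accepts scalars or aligned arrays; negative raw values are rounded
    to 0. Pseudocounts make the denominator strictly positive.
    """
    mm = np.asarray(mm, dtype=float) + 0.5
    mu = np.asarray(mu, dtype=float) + 0.5
    um = np.asarray(um, dtype=float) + 0.5
    uu = np.asarray(uu, dtype=float) + 0.5
    num = mm * uu - mu * um
    den = np.sqrt((mm + mu) * (um + uu) * (mm + um) * (mu + uu))
    out = np.maximum(num / den, 0.0)
    return float(out) if out.ndim == 0 else out


def phi_pair(pair: CpGPairCount) -> float:
    return phi(pair.mm, pair.mu, pair.um, pair.uu)


def pair_filters(
    pairs: pd.DataFrame,
    min_coverage: int = MIN_PAIR_COVERAGE,
    min_prevalence: float = MIN_PAIR_PREVALENCE,
    bounds: tuple[float, float] = METHYLATION_BOUNDS,
) -> pd.DataFrame:
    """Flag valid pair-sample observations across a cohort.

    Filter order: per-observation coverage, cohort prevalence (fraction of
    cohort samples in which the pair reaches the coverage floor), then the
    per-CpG marginal methylation boundary filter. Input is a long table
    with columns sample, chrom, pos_a, pos_b, mm, mu, um, uu; the returned
    copy adds coverage, m_a, m_b, phi and valid columns.
    """
    df = pairs.copy()
    cov = df[["mm", "mu", "um", "uu"]].sum(axis=1)
    df["coverage"] = cov
    covered = cov >= min_coverage
    n_samples = df["sample"].nunique()
    pair_key = df["chrom"].astype(str) + ":" + df["pos_a"].astype(str) + "-" + df[
        "pos_b"
    ].astype(str)
    df["pair_id"] = pair_key
    prevalence = (
        df.loc[covered].groupby("pair_id")["sample"].nunique() / n_samples
    )
    prevalent = pair_key.map(prevalence).fillna(0.0) >= min_prevalence
    with np.errstate(invalid="ignore", divide="ignore"):
        m_a = (df["mm"] + df["mu"]) / cov
        m_b = (df["mm"] + df["um"]) / cov
    df["m_a"], df["m_b"] = m_a, m_b
    lo, hi = bounds
    in_bounds = m_a.between(lo, hi) & m_b.between(lo, hi)
    df["valid"] = covered & prevalent & in_bounds
    df["phi"] = phi(df["mm"], df["mu"], df["um"], df["uu"])
    return df


def region_asm(
    scores: pd.DataFrame,
    region: Region,
    min_valid_fraction: float = MIN_VALID_FRACTION,
) -> pd.Series:
    """Per-sample mean ASM over valid pairs in a region.

    Pairs with < ``min_valid_fraction`` valid observations across the
    cohort are excluded first; a pair belongs to the region when its
    first CpG (pos_a) lies inside. NaN where a sample has no valid pair.
    """
    n_samples = scores["sample"].nunique()
    valid_frac = scores.groupby("pair_id")["valid"].sum() / n_samples
    keep_pairs = valid_frac[valid_frac >= min_valid_fraction].index
    sub = scores[
        scores["pair_id"].isin(keep_pairs)
        & (scores["chrom"] == region.chrom)
        & scores["pos_a"].between(region.start, region.end)
        & scores["valid"]
    ]
    means = sub.groupby("sample")["phi"].mean()
    return means.reindex(sorted(scores["sample"].unique()))


def region_asm_matrix(
    scores: pd.DataFrame,
    regions: RegionSet | list[Region],
    min_valid_fraction: float = MIN_VALID_FRACTION,
) -> pd.DataFrame:
    """Samples x regions matrix of mean ASM."""
    cols = {
        r.name: region_asm(scores, r, min_valid_fraction) for r in regions
    }
    return pd.DataFrame(cols)


def tert_locus_regions() -> list[Region]:
    """The five TERT-locus subregions (GRCh37, chr5, 1-based inclusive):
    promoter, three CpG-island segments, and the remaining gene body."""
    return [
        Region("promoter", "chr5", 1_295_246, 1_298_643),
        Region("CGI_1", "chr5", 1_294_872, 1_295_134),
        Region("CGI_2", "chr5", 1_291_374, 1_294_439),
        Region("CGI_3", "chr5", 1_289_695, 1_291_090),
        Region("gene_body", "chr5", 1_249_661, 1_289_359),
    ]


@dataclass(frozen=True)
class CGIMethylation:
    sample: str
    region: str
    mean_beta: float
    n_cpgs: int


def cgi_methylation(
    cpg_betas: pd.DataFrame,
    island: Region,
    min_cpgs: int = MIN_CPGS_RRBS,
) -> pd.Series:
    """Per-sample mean beta across CpGs profiled inside an island.

    ``cpg_betas`` is a long table with columns sample, chrom, pos, beta.
    NaN where a sample profiles fewer than ``min_cpgs`` CpGs in the
    island.
    """
    sub = cpg_betas[
        (cpg_betas["chrom"] == island.chrom)
        & cpg_betas["pos"].between(island.start, island.end)
        & cpg_betas["beta"].notna()
    ]
    grouped = sub.groupby("sample")["beta"]
    means, counts = grouped.mean(), grouped.size()
    means[counts < min_cpgs] = np.nan
    return means.reindex(sorted(cpg_betas["sample"].unique()))


def cgi_methylation_matrix(
    cpg_betas: pd.DataFrame,
    islands: RegionSet | list[Region],
    min_cpgs: int = MIN_CPGS_RRBS,
) -> pd.DataFrame:
    """Samples x islands matrix of mean beta values."""
    return pd.DataFrame(
        {r.name: cgi_methylation(cpg_betas, r, min_cpgs) for r in islands}
    )
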