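"""Allele-specific expression (ASE) calling from DNA/RNA allele counts.

A gene is monoallelically expressed (MAE) in a cell line when RNA reads at
a heterozygous SNP are skewed toward one allele far beyond the DNA allele
balance. The skew is quantified by an odds ratio over the 2x2 table
(context: DNA vs RNA) x (allele: major vs minor), with a 0.5 pseudocount
in every cell. The RNA-major allele anchors the denominator of both
ratios, so allelic skew in RNA relative to DNA inflates the odds ratio
above 1 and MAE detection is one-sided: OR > 5 (strict) calls MAE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import log_drop_report

#: Minimum DNA reads supporting each allele, and minimum RNA depth.
MIN_ALLELE_READS = 8

#: Strict odds-ratio threshold above which a call is MAE.
DEFAULT_OR_THRESHOLD = 5.0

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class AlleleCountRecord:
    """DNA/RNA ref/alt read counts at one heterozygous SNP."""

    sample: str
    gene: str
    snp_id: str
    dna_ref: int
    dna_alt: int
    rna_ref: int
    rna_alt: int
    dna_source: str = "WGS"
    passed_caller_filter: bool = True

    def __post_init__(self) -> None:
        for name in ("dna_ref", "dna_alt", "rna_ref", "rna_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rna_depth(self) -> int:
        return self.rna_ref + self.rna_alt

    @property
    def dna_depth(self) -> int:
        return self.dna_ref + self.dna_alt


@dataclass(frozen=True)
class ASECall:
    sample: str
    gene: str
    status: str  # MAE | BAE | unassessable
    odds_ratio: float | None = None
    chosen_snp: str | None = None


def filter_snps(records: list[AlleleCountRecord]) -> list[AlleleCountRecord]:
    """Keep SNPs with >= 8 DNA reads on both alleles, a passing caller
    filter, and >= 8 total RNA reads (all boundaries inclusive)."""
    kept, reasons = [], {"dna_support": 0, "caller_filter": 0, "rna_depth": 0}
    for r in records:
        if not r.passed_caller_filter:
            reasons["caller_filter"] += 1
        elif r.dna_ref < MIN_ALLELE_READS or r.dna_alt < MIN_ALLELE_READS:
            reasons["dna_support"] += 1
        elif r.rna_depth < MIN_ALLELE_READS:
            reasons["rna_depth"] += 1
        else:
            kept.append(r)
    log_drop_report("ase.filter_snps", reasons)
    return kept


def ase_odds_ratio(record: AlleleCountRecord) -> float:
    """Pseudocounted odds ratio anchored on the RNA-major allele.

    OR = (dna_minor~ / dna_major~) / (rna_minor~ / rna_major~), where ~
    denotes + 0.5 and major/minor are assigned from the RNA counts (exact
    RNA ties break by the DNA counts, keeping the statistic invariant
    under ref/alt relabeling; a double tie gives OR = 1 either way).
    """
    if (record.rna_alt, record.dna_alt) > (record.rna_ref, record.dna_ref):
        rna_major, rna_minor = record.rna_alt, record.rna_ref
        dna_major, dna_minor = record.dna_alt, record.dna_ref
    else:
        rna_major, rna_minor = record.rna_ref, record.rna_alt
        dna_major, dna_minor = record.dna_ref, record.dna_alt
    p = PSEUDOCOUNT
    return ((dna_minor + p) / (dna_major + p)) / ((rna_minor + p) / (rna_major + p))


def classify(
    record: AlleleCountRecord, threshold: float = DEFAULT_OR_THRESHOLD
) -> ASECall:
    """MAE iff OR > threshold (strict); otherwise BAE."""
    odds = ase_odds_ratio(record)
    status = "MAE" if odds > threshold else "BAE"
    return ASECall(
        sample=record.sample,
        gene=record.gene,
        status=status,
        odds_ratio=odds,
        chosen_snp=record.snp_id,
    )


def select_informative(records: list[AlleleCountRecord]) -> AlleleCountRecord | None:
    """Pick the single record to call from: per SNP keep the DNA source
    with greatest coverage, then take the SNP with the greatest RNA depth.

    Ties break by lexicographic snp_id then source tag; returns None when
    no records remain (unassessable).
    """
    if not records:
        return None
    best_per_snp: dict[str, AlleleCountRecord] = {}
    for r in sorted(records, key=lambda r: (r.snp_id, -r.dna_depth, r.dna_source)):
        best_per_snp.setdefault(r.snp_id, r)
    return min(
        best_per_snp.values(),
        key=lambda r: (-r.rna_depth, r.snp_id, r.dna_source),
    )


def call_ase(
    records: list[AlleleCountRecord], threshold: float = DEFAULT_OR_THRESHOLD
) -> list[ASECall]:
    """Filter, select one informative SNP per sample+gene, and classify."""
    filtered = filter_snps(records)
    grouped: dict[tuple[str, str], list[AlleleCountRecord]] = {}
    for r in filtered:
        grouped.setdefault((r.sample, r.gene), []).append(r)
    all_keys = {(r.sample, r.gene) for r in records}
    calls = []
    for sample, gene in sorted(all_keys):
        chosen = select_informative(grouped.get((sample, gene), []))
        if chosen is None:
            calls.append(ASECall(sample=sample, gene=gene, status="unassessable"))
        else:
            calls.append(classify(chosen, threshold=threshold))
    return calls


# ---------------------------------------------------------------------------
# Tabular front end


def records_from_frame(df: pd.DataFrame) -> list[AlleleCountRecord]:
    """Build records from a counts table (columns: sample, gene, snp_id,
    dna_source, dna_ref, dna_alt, rna_ref, rna_alt, filter)."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AlleleCountRecord(
                sample=str(row.sample),
                gene=str(row.gene),
                snp_id=str(row.snp_id),
                dna_ref=int(row.dna_ref),
                dna_alt=int(row.dna_alt),
                rna_ref=int(row.rna_ref),
                rna_alt=int(row.rna_alt),
                dna_source=str(getattr(row, "dna_source", "WGS")),
                passed_caller_filter=_truthy(getattr(row, "filter", "PASS")),
            )
        )
    return records


def _truthy(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).upper() in {"PASS", "TRUE", "1"}


def calls_to_frame(calls: list[ASECall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "gene": [c.gene for c in calls],
            "status": [c.status for c in calls],
            "odds_ratio": [c.odds_ratio for c in calls],
            "chosen_snp": [c.chosen_snp for c in calls],
        }
    )
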