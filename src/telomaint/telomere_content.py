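"""Telomere content estimation from raw sequencing reads.

A read is called telomeric when it contains at least ``motif_threshold``
non-overlapping copies of the canonical human telomeric repeat TTAGGG.
The telomeric read count T is normalized by coverage estimated from reads
whose GC fraction falls in a narrow band around the telomeric repeat's GC
content (default 48-52%), yielding a raw length in kilobases per
chromosome end:

    raw_length_kb = (T / S) * (L_gc / n_ends) / 1000

where S is the GC-band read count, L_gc the genome length within the GC
band, and n_ends the number of chromosome ends (46 for a diploid human
genome). Telomere *content* rather than length: interstitial and
extrachromosomal repeats are counted indistinguishably.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .io import logger

TELOMERE_MOTIF = "TTAGGG"
TELOMERE_MOTIF_RC = "CCCTAA"

#: Default motif count at or above which a read is called telomeric.
DEFAULT_MOTIF_THRESHOLD = 6

#: Default GC band used for coverage normalization.
DEFAULT_GC_BAND = (0.48, 0.52)

#: GRCh37 sequence length (bp) within the 48-52% GC band; override with a
#: genome-specific GC profile when available.
DEFAULT_GC_BAND_GENOME_BP = 332_720_800

#: Chromosome ends in a diploid human genome.
DEFAULT_N_ENDS = 46

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequencingRead:
    """One read; sequence is uppercased on construction."""

    sequence: str
    read_group: str = "rg0"
    sample: str = "sample"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be nonempty")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"read contains non-ACGTN characters: {seq[:20]}...")
        object.__setattr__(self, "sequence", seq)


@dataclass
class MotifProfile:
    """Per-sample distribution of exact per-read motif counts."""

    sample: str
    counts_by_motif: dict[int, int] = field(default_factory=dict)
    total_reads: int = 0

    def frequency(self, k: int) -> float:
        if self.total_reads == 0:
            return float("nan")
        return self.counts_by_motif.get(k, 0) / self.total_reads


@dataclass
class TelomereEstimate:
    """Raw telomere content for one sample (or one read group)."""

    sample: str
    telomeric_reads: int
    gc_band_reads: int
    gc_band_genome_bp: float
    n_chromosome_ends: int
    total_reads: int
    raw_length_kb: float
    source: str = ""
    read_groups: int = 1

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.raw_length_kb)


def count_motifs(sequence: str, motif: str = TELOMERE_MOTIF) -> int:
    """Count non-overlapping occurrences of ``motif``, scanned left to right."""
    if not motif:
        raise ValueError("motif must be nonempty")
    return sequence.upper().count(motif.upper())


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def is_telomeric(
    sequence: str,
    threshold: int = DEFAULT_MOTIF_THRESHOLD,
    rc_scan: bool = False,
) -> bool:
    """True if the read carries >= ``threshold`` telomeric repeats.

    With ``rc_scan`` the reverse-complement motif (CCCTAA) is also scanned
    and the larger of the two counts is compared against the threshold.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return telomere_motif_count(sequence, rc_scan=rc_scan) >= threshold


def telomere_motif_count(sequence: str, rc_scan: bool = False) -> int:
    n = count_motifs(sequence, TELOMERE_MOTIF)
    if rc_scan:
        n = max(n, count_motifs(sequence, TELOMERE_MOTIF_RC))
    return n


def gc_fraction(sequence: str) -> float:
    """GC fraction over called (non-N) bases; NaN for an all-N read."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    called = len(seq) - seq.count("N")
    if called == 0:
        return float("nan")
    return gc / called


def motif_profile(
    reads: Iterable[SequencingRead | str],
    sample: str = "sample",
    rc_scan: bool = False,
) -> MotifProfile:
    """Distribution of exact non-overlapping motif counts across reads."""
    counts: Counter[int] = Counter()
    total = 0
    for read in reads:
        seq = read.sequence if isinstance(read, SequencingRead) else read
        counts[telomere_motif_count(seq, rc_scan=rc_scan)] += 1
        total += 1
    return MotifProfile(sample=sample, counts_by_motif=dict(counts), total_reads=total)


def estimate_content(
    reads: Iterable[SequencingRead | str],
    sample: str = "sample",
    motif_threshold: int = DEFAULT_MOTIF_THRESHOLD,
    gc_low: float = DEFAULT_GC_BAND[0],
    gc_high: float = DEFAULT_GC_BAND[1],
    gc_band_genome_bp: float = DEFAULT_GC_BAND_GENOME_BP,
    n_ends: int = DEFAULT_N_ENDS,
    rc_scan: bool = False,
    source: str = "",
) -> TelomereEstimate:
    """Estimate raw telomere content (kb) from a collection of reads.

    A sample with no reads in the GC band gets a non-finite estimate and a
    logged warning; such samples are excluded downstream.
    """
    t = s = total = 0
    for read in reads:
        seq = read.sequence if isinstance(read, SequencingRead) else read
        total += 1
        if telomere_motif_count(seq, rc_scan=rc_scan) >= motif_threshold:
            t += 1
        gc = gc_fraction(seq)
        if gc == gc and gc_low <= gc <= gc_high:  # gc == gc: not NaN
            s += 1
    if s == 0:
        logger.warning("sample %s: no reads in GC band; estimate undefined", sample)
        raw_kb = float("nan")
    else:
        raw_kb = (t / s) * (gc_band_genome_bp / n_ends) / 1000.0
    return TelomereEstimate(
        sample=sample,
        telomeric_reads=t,
        gc_band_reads=s,
        gc_band_genome_bp=gc_band_genome_bp,
        n_chromosome_ends=n_ends,
        total_reads=total,
        raw_length_kb=raw_kb,
        source=source,
    )


def aggregate_read_groups(
    estimates: Sequence[TelomereEstimate],
    read_counts: Sequence[int] | None = None,
) -> TelomereEstimate:
    """Combine per-read-group estimates, weighted by total reads per group."""
    if not estimates:
        raise ValueError("at least one read-group estimate is required")
    if read_counts is None:
        read_counts = [e.total_reads for e in estimates]
    if len(read_counts) != len(estimates):
        raise ValueError("read_counts length must match estimates")
    if any(w <= 0 for w in read_counts):
        raise ValueError("read-group weights must be > 0")
    finite = [(e, w) for e, w in zip(estimates, read_counts) if e.is_finite]
    if not finite:
        raw_kb = float("nan")
    else:
        wsum = sum(w for _, w in finite)
        raw_kb = sum(e.raw_length_kb * w for e, w in finite) / wsum
    first = estimates[0]
    return TelomereEstimate(
        sample=first.sample,
        telomeric_reads=sum(e.telomeric_reads for e in estimates),
        gc_band_reads=sum(e.gc_band_reads for e in estimates),
        gc_band_genome_bp=first.gc_band_genome_bp,
        n_chromosome_ends=first.n_chromosome_ends,
        total_reads=sum(e.total_reads for e in estimates),
        raw_length_kb=raw_kb,
        source=first.source,
        read_groups=len(estimates),
    )


def estimate_sample(
    reads: Iterable[SequencingRead], sample: str = "sample", **params
) -> TelomereEstimate:
    """Group reads by read group, estimate each group, aggregate weighted."""
    by_group: dict[str, list[SequencingRead]] = {}
    for read in reads:
        by_group.setdefault(read.read_group, []).append(read)
    if not by_group:
        raise ValueError("no reads supplied")
    estimates = [
        estimate_content(group_reads, sample=sample, **params)
        for _, group_reads in sorted(by_group.items())
    ]
    return aggregate_read_groups(estimates)


# ---------------------------------------------------------------------------
# Read ingestion


def read_fastq(path: str | Path, sample: str = "sample") -> Iterator[SequencingRead]:
    """Iterate reads from a FASTQ file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # qualities
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header!r}")
            yield SequencingRead(sequence=seq, sample=sample)


def read_bam(path: str | Path, sample: str = "sample") -> Iterator[SequencingRead]:
    """Iterate reads from a BAM/SAM file; read group from the RG tag.

    Unaligned BAMs are accepted (no reference required).
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence
            if not seq:
                continue
            rg = aln.get_tag("RG") if aln.has_tag("RG") else "rg0"
            yield SequencingRead(sequence=seq, read_group=str(rg), sample=sample)


def estimates_to_frame(estimates: Sequence[TelomereEstimate]) -> pd.DataFrame:
    """Tabulate estimates in the canonical output column order."""
    return pd.DataFrame(
        {
            "sample": [e.sample for e in estimates],
            "source": [e.source for e in estimates],
            "read_groups": [e.read_groups for e in estimates],
            "total_reads": [e.total_reads for e in estimates],
            "telomeric_reads": [e.telomeric_reads for e in estimates],
            "gc_band_reads": [e.gc_band_reads for e in estimates],
            "raw_length_kb": [e.raw_length_kb for e in estimates],
        }
    )
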