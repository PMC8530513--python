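"""Genomic interval containers and overlap machinery.

Coordinates are 1-based inclusive internally (the convention used for the
printed TERT-locus intervals); BED input/output converts from/to 0-based
half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np


@dataclass(frozen=True)
class Region:
    """A named genomic interval, 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region {self.name}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class RegionSet:
    """An ordered collection of regions with a shared set name.

    Regions are kept sorted by (chrom, start, end); sortedness is an
    invariant relied on by the overlap search.
    """

    name: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions, key=lambda r: (r.chrom, r.start, r.end)
        )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __contains__(self, region: Region) -> bool:
        return region in set(self.regions)

    def chroms(self) -> set[str]:
        return {r.chrom for r in self.regions}

    def _merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Merged, sorted (starts, ends) arrays per chromosome."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[Region]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, regs in by_chrom.items():
            starts, ends = [], []
            for r in regs:  # already sorted by start
                if ends and r.start <= ends[-1] + 1:
                    ends[-1] = max(ends[-1], r.end)
                else:
                    starts.append(r.start)
                    ends.append(r.end)
            out[chrom] = (np.asarray(starts), np.asarray(ends))
        return out

    def overlap_flags(self, queries: Iterable[Region]) -> np.ndarray:
        """For each query region: does it intersect this set by >= 1 bp?

        Binary search against merged per-chromosome intervals; invariant to
        the order of intervals and to splitting intervals into adjacent
        pieces (adjacency is merged).
        """
        merged = self._merged_by_chrom()
        queries = list(queries)
        flags = np.zeros(len(queries), dtype=bool)
        by_chrom: dict[str, list[int]] = {}
        for i, q in enumerate(queries):
            by_chrom.setdefault(q.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            if chrom not in merged:
                continue
            starts, ends = merged[chrom]
            q_start = np.array([queries[i].start for i in idx])
            q_end = np.array([queries[i].end for i in idx])
            # rightmost merged interval starting at or before each q.end
            j = np.searchsorted(starts, q_end, side="right") - 1
            hit = (j >= 0) & (ends[np.clip(j, 0, None)] >= q_start)
            flags[np.asarray(idx)] = hit
        return flags


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a RegionSet (converting to 1-based inclusive).

    Raises ValueError with the offending line number on malformed input.
    """
    path = Path(path)
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start0 < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if start0 >= end0:
                raise ValueError(
                    f"{path}:{lineno}: start {start0} >= end {end0}"
                )
            rname = fields[3] if len(fields) > 3 and fields[3] else f"region_{lineno}"
            regions.append(Region(rname, chrom, start0 + 1, end0))
    return RegionSet(name or path.stem, regions)


def write_bed(region_set: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED4 (back to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in region_set:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-sizes file (chrom <tab> length-in-bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom and size")
            sizes[fields[0]] = int(fields[1])
    return sizes
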