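"""Genomic interval model and BED I/O.

All internal coordinates are 0-based half-open.  GTF input (1-based closed)
is converted at the parsing boundary in :mod:`utr3pred.annotation`; BED input
is already in the internal convention.  Regions without strand information
(e.g. expressed regions called from unstranded RNA-seq) carry an explicit
``"."`` strand so that downstream sequence features must decide strand
handling explicitly rather than silently assuming ``"+"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def read_regions(path: str | Path) -> list[GenomicRegion]:
    """Read a 3-6 column BED file into a list of :class:`GenomicRegion`.

    Column 4 becomes the region id and column 6 the strand when present.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    regions: list[GenomicRegion] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                regions.append(GenomicRegion(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as 6-column BED (score column fixed at 0)."""
    with open(path, "w") as handle:
        for region in regions:
            name = region.id if region.id is not None else "."
            handle.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{name}\t0\t{region.strand}\n"
            )


def merge_regions(regions: Sequence[GenomicRegion]) -> list[GenomicRegion]:
    """Merge overlapping or bookended intervals per chromosome, ignoring strand."""
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.chrom, []).append(region)
    merged: list[GenomicRegion] = []
    for chrom in sorted(by_chrom):
        intervals = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        current_start, current_end = intervals[0].start, intervals[0].end
        for region in intervals[1:]:
            if region.start <= current_end:
                current_end = max(current_end, region.end)
            else:
                merged.append(GenomicRegion(chrom, current_start, current_end))
                current_start, current_end = region.start, region.end
        merged.append(GenomicRegion(chrom, current_start, current_end))
    return merged


def overlap_fraction(
    query: GenomicRegion,
    targets: Sequence[GenomicRegion],
    stranded: bool = False,
) -> float:
    """Fraction of ``query`` bases covered by the union of ``targets``.

    Targets are merged first so mutually overlapping targets are not double
    counted.  Strand is ignored unless ``stranded`` is requested, in which
    case only targets on the query's strand contribute.
    """
    if stranded:
        targets = [t for t in targets if t.strand == query.strand]
    if not targets:
        return 0.0
    covered = 0
    for target in merge_regions(list(targets)):
        covered += query.overlap_length(target)
    return covered / query.length
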