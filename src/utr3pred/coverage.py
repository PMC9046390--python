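"""Per-base read-coverage (and conservation) tracks.

A :class:`CoverageTrack` answers point queries ``(chrom, start, end)`` with a
per-base vector.  Positions absent from the underlying track report depth 0,
but queries on chromosomes the track has never seen raise ``KeyError`` so
that genome/track mismatches surface early instead of silently yielding
zeros.  Tracks can be loaded from bedGraph or bigWig.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .regions import GenomicRegion


class CoverageTrack:
    """Sparse interval-valued track with dense per-base queries."""

    def __init__(self, tissue_label: str):
        self.tissue_label = tissue_label
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}

    @classmethod
    def from_intervals(
        cls,
        tissue_label: str,
        intervals: list[tuple[str, int, int, float]],
    ) -> "CoverageTrack":
        track = cls(tissue_label)
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if value < 0:
                raise ValueError(f"negative depth {value} at {chrom}:{start}-{end}")
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(ends[:-1] > starts[1:]):
                i = int(np.nonzero(ends[:-1] > starts[1:])[0][0])
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i+1]},{ends[i+1]})"
                )
            track._starts[chrom] = starts
            track._ends[chrom] = ends
            track._values[chrom] = values
        return track

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._starts)

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over ``[start, end)``; gaps report 0."""
        if chrom not in self._starts:
            raise KeyError(f"chromosome {chrom!r} not present in track {self.tissue_label!r}")
        if end <= start:
            raise ValueError(f"empty query {chrom}:{start}-{end}")
        out = np.zeros(end - start, dtype=np.float64)
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = values[i]
        return out

    def region_depth(self, region: GenomicRegion) -> np.ndarray:
        return self.depth(region.chrom, region.start, region.end)

    def mean_depth(self, region: GenomicRegion) -> float:
        return float(self.region_depth(region).mean())


def _read_bedgraph(path: str | Path, tissue_label: str) -> CoverageTrack:
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {value}")
            intervals.append((chrom, start, end, value))
    return CoverageTrack.from_intervals(tissue_label, intervals)


def _read_bigwig(path: str | Path, tissue_label: str) -> CoverageTrack:
    import pyBigWig

    intervals: list[tuple[str, int, int, float]] = []
    bw = pyBigWig.open(str(path))
    try:
        for chrom in bw.chroms():
            entries = bw.intervals(chrom)
            if entries is None:
                continue
            for start, end, value in entries:
                if value < 0:
                    raise ValueError(f"negative depth {value} at {chrom}:{start}-{end}")
                intervals.append((chrom, start, end, float(value)))
    finally:
        bw.close()
    return CoverageTrack.from_intervals(tissue_label, intervals)


def read_coverage(path: str | Path, tissue_label: str) -> CoverageTrack:
    """Load a coverage track from bedGraph (default) or bigWig (.bw/.bigwig)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".bw", ".bigwig"):
        return _read_bigwig(path, tissue_label)
    return _read_bedgraph(path, tissue_label)


def write_bedgraph(
    intervals: list[tuple[str, int, int, float]],
    path: str | Path,
) -> None:
    """Write (chrom, start, end, value) rows as bedGraph, merging equal runs."""
    with open(path, "w") as handle:
        rows = sorted(intervals)
        i = 0
        while i < len(rows):
            chrom, start, end, value = rows[i]
            j = i + 1
            while (
                j < len(rows)
                and rows[j][0] == chrom
                and rows[j][1] == end
                and rows[j][3] == value
            ):
                end = rows[j][2]
                j += 1
            handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
            i = j
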