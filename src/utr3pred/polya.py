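"""Validation of 3'UTR predictions against poly(A) site clusters.

Predictions overlapping an experimentally determined poly(A) cluster by at
least one base are considered validated.  The positive predictive value
(PPV) is the fraction of 3'UTR calls that validate and the false omission
rate (FOR) the fraction of non-3'UTR calls that do.  A permutation test
shuffles prediction locations uniformly within the allowed intergenic
space on the same chromosome (lengths and per-chromosome counts preserved;
shuffled intervals never intersect the excluded space, which comprises
genes of all biotypes plus the intergenic ERs themselves) and reports the
empirical exceedance p-value p = x/N, where x counts permutations with
more overlap than observed, together with z = (O_obs - median(O_perm)) /
SD(O_perm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .regions import GenomicRegion, merge_regions

__all__ = [
    "overlap_with_polya",
    "ppv_for",
    "permutation_test",
    "PermutationResult",
    "allowed_intergenic_space",
    "shuffle_intervals",
]


def _cluster_arrays(clusters: Sequence[GenomicRegion]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_regions(list(clusters))
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for region in merged:
        by_chrom.setdefault(region.chrom, ([], []))
        by_chrom[region.chrom][0].append(region.start)
        by_chrom[region.chrom][1].append(region.end)
    return {
        chrom: (np.array(starts), np.array(ends))
        for chrom, (starts, ends) in by_chrom.items()
    }


def overlap_with_polya(
    predictions: Sequence[GenomicRegion],
    clusters: Sequence[GenomicRegion],
) -> np.ndarray:
    """Boolean per prediction: >= 1 base overlap with any (merged) cluster.

    Strand is ignored; the expressed regions are unstranded.
    """
    arrays = _cluster_arrays(clusters)
    flags = np.zeros(len(predictions), dtype=bool)
    for i, prediction in enumerate(predictions):
        if prediction.chrom not in arrays:
            continue
        starts, ends = arrays[prediction.chrom]
        j = int(np.searchsorted(ends, prediction.start, side="right"))
        flags[i] = j < len(starts) and starts[j] < prediction.end
    return flags


def ppv_for(
    utr3_calls: Sequence[GenomicRegion],
    non_utr3_calls: Sequence[GenomicRegion],
    clusters: Sequence[GenomicRegion],
) -> tuple[float | None, float | None]:
    """(PPV, FOR) against poly(A)-cluster overlap.

    PPV = validated 3'UTR calls / all 3'UTR calls; FOR = validated
    non-3'UTR calls / all non-3'UTR calls.  An empty call set yields None,
    never 0.
    """
    ppv = (
        float(overlap_with_polya(utr3_calls, clusters).mean()) if utr3_calls else None
    )
    for_ = (
        float(overlap_with_polya(non_utr3_calls, clusters).mean())
        if non_utr3_calls
        else None
    )
    return ppv, for_


@dataclass
class PermutationResult:
    observed: int
    null: np.ndarray  # O_perm for each permutation
    n_permutations: int
    exceedances: int  # x = #{O_perm > O_obs}
    p_value: float  # x / N (one-sided, the printed formula)
    p_value_two_sided: float  # doubled smaller tail, capped at 1
    z_score: float | None  # (O_obs - median) / SD; None when SD == 0


def allowed_intergenic_space(
    chrom_sizes: Mapping[str, int],
    excluded: Sequence[GenomicRegion],
) -> dict[str, list[tuple[int, int]]]:
    """Complement of the merged excluded intervals within each chromosome."""
    merged: dict[str, list[GenomicRegion]] = {}
    for region in merge_regions(list(excluded)):
        merged.setdefault(region.chrom, []).append(region)
    allowed: dict[str, list[tuple[int, int]]] = {}
    for chrom, size in chrom_sizes.items():
        segments: list[tuple[int, int]] = []
        cursor = 0
        for region in sorted(merged.get(chrom, []), key=lambda r: r.start):
            if region.start > cursor:
                segments.append((cursor, min(region.start, size)))
            cursor = max(cursor, region.end)
        if cursor < size:
            segments.append((cursor, size))
        allowed[chrom] = segments
    return allowed


def _placement_table(
    length: int, segments: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative start-position counts for placing an interval of ``length``
    wholly inside the allowed segments."""
    seg_starts = []
    positions = []
    for start, end in segments:
        n = (end - start) - length + 1
        if n > 0:
            seg_starts.append(start)
            positions.append(n)
    return np.array(seg_starts, dtype=np.int64), np.array(positions, dtype=np.int64)


def shuffle_intervals(
    predictions: Sequence[GenomicRegion],
    allowed: Mapping[str, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> list[GenomicRegion]:
    """One permutation: each interval uniformly re-placed within the allowed
    space of its own chromosome, preserving its length.  Intervals may
    overlap each other."""
    placed = []
    for prediction in predictions:
        seg_starts, positions = _placement_table(
            prediction.length, allowed.get(prediction.chrom, [])
        )
        total = int(positions.sum())
        if total <= 0:
            raise ValueError(
                f"no allowed space for interval {prediction.id or prediction} "
                f"of length {prediction.length} on {prediction.chrom}"
            )
        u = int(rng.integers(0, total))
        seg = int(np.searchsorted(np.cumsum(positions), u, side="right"))
        offset = u - (int(np.cumsum(positions)[seg - 1]) if seg > 0 else 0)
        start = int(seg_starts[seg]) + offset
        placed.append(
            GenomicRegion(prediction.chrom, start, start + prediction.length, ".", prediction.id)
        )
    return placed


def permutation_test(
    predictions: Sequence[GenomicRegion],
    clusters: Sequence[GenomicRegion],
    chrom_sizes: Mapping[str, int],
    excluded: Sequence[GenomicRegion],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Interval-shuffling enrichment test of prediction/cluster overlap.

    Ties (O_perm == O_obs) count as non-exceedance.  The one-sided
    exceedance p is primary; a two-sided value (doubled smaller tail,
    capped at 1) is also reported.
    """
    rng = np.random.default_rng(seed)
    observed = int(overlap_with_polya(predictions, clusters).sum())
    arrays = _cluster_arrays(clusters)
    allowed = allowed_intergenic_space(chrom_sizes, excluded)

    # precompute placement tables and cluster arrays per prediction
    tables = []
    for prediction in predictions:
        seg_starts, positions = _placement_table(
            prediction.length, allowed.get(prediction.chrom, [])
        )
        total = int(positions.sum())
        if total <= 0:
            raise ValueError(
                f"no allowed space for interval {prediction.id or prediction} "
                f"of length {prediction.length} on {prediction.chrom}"
            )
        cum = np.cumsum(positions)
        cluster = arrays.get(prediction.chrom)
        tables.append((prediction.length, seg_starts, cum, total, cluster))

    null = np.zeros(n_permutations, dtype=np.int64)
    for length, seg_starts, cum, total, cluster in tables:
        u = rng.integers(0, total, size=n_permutations)
        seg = np.searchsorted(cum, u, side="right")
        offsets = u - np.where(seg > 0, cum[seg - 1], 0)
        starts = seg_starts[seg] + offsets
        if cluster is None:
            continue
        c_starts, c_ends = cluster
        j = np.searchsorted(c_ends, starts, side="right")
        hit = (j < len(c_starts)) & (c_starts[np.minimum(j, len(c_starts) - 1)] < starts + length)
        null += hit
    exceedances = int((null > observed).sum())
    p_value = exceedances / n_permutations
    lower = int((null < observed).sum()) / n_permutations
    p_two = min(1.0, 2.0 * min(p_value, lower))
    sd = float(np.std(null, ddof=1)) if n_permutations > 1 else 0.0
    z = (observed - float(np.median(null))) / sd if sd > 0 else None
    return PermutationResult(
        observed=observed,
        null=null,
        n_permutations=n_permutations,
        exceedances=exceedances,
        p_value=p_value,
        p_value_two_sided=p_two,
        z_score=z,
    )
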