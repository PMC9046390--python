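"""RBP motif-density scoring, a dinucleotide-shuffled null, set-vs-set
motif enrichment, and constrained non-conserved (CNC) scoring.

Motif collections (e.g. from curated RBP-motif databases) are filtered to
motifs of at least 7 nt with confidence >= 1, keeping one motif per RBP
(the longest, ties broken lexicographically).  Match density is reported as
motif matches per 100 nt of query sequence and summed across RBPs into an
overall binding score.  The negative control preserves dinucleotide
composition exactly via the Altschul-Erickson Euler-path shuffle.

String motifs are matched exactly (U mapped to T, overlapping occurrences
counted); probability-matrix motifs are matched at a log-odds score cutoff
whose null tail probability under a uniform background is computed exactly
by dynamic-programming convolution over positions (scores discretised at
0.01-bit granularity).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .regions import GenomicRegion

logger = logging.getLogger(__name__)

BASES = "ACGT"

MIN_MOTIF_LENGTH = 7
MIN_CONFIDENCE = 1.0
SCORE_GRANULARITY = 0.01  # bits
MAX_MATRIX_WIDTH = 30


@dataclass(frozen=True)
class MotifRecord:
    rbp_name: str
    motif: str  # DNA alphabet
    confidence: float

    @property
    def length(self) -> int:
        return len(self.motif)


def load_and_filter_motifs(path: str | Path) -> list[MotifRecord]:
    """Load a ``rbp<TAB>motif<TAB>confidence`` TSV and apply the filters:
    length >= 7, confidence >= 1, longest motif per RBP (lexicographically
    smallest on ties)."""
    table = pd.read_csv(path, sep="\t", names=["rbp", "motif", "confidence"], comment="#")
    records: dict[str, MotifRecord] = {}
    for row in table.itertuples(index=False):
        motif = str(row.motif).upper().replace("U", "T")
        confidence = float(row.confidence)
        if len(motif) < MIN_MOTIF_LENGTH or confidence < MIN_CONFIDENCE:
            continue
        candidate = MotifRecord(str(row.rbp), motif, confidence)
        current = records.get(candidate.rbp_name)
        if (
            current is None
            or candidate.length > current.length
            or (candidate.length == current.length and candidate.motif < current.motif)
        ):
            records[candidate.rbp_name] = candidate
    if not records:
        raise ValueError(f"no motifs retained from {path}")
    logger.info("retained %d RBP motifs", len(records))
    return [records[name] for name in sorted(records)]


# ---------------------------------------------------------------------------
# matrix motifs: exact null score distribution by DP


@dataclass
class MatrixMotif:
    """Log-odds motif with discretised scores and a p-value-derived cutoff."""

    name: str
    disc_log_odds: np.ndarray  # 4 x width, integer multiples of granularity
    granularity: float
    cutoff_units: int | None  # None when no score reaches the p cutoff

    @property
    def width(self) -> int:
        return self.disc_log_odds.shape[1]


def discretise_log_odds(
    matrix: np.ndarray,
    pseudocount: float = 0.01,
    granularity: float = SCORE_GRANULARITY,
) -> np.ndarray:
    """4 x L probability matrix -> integer log2-odds (vs uniform 0.25)."""
    if matrix.shape[0] != 4:
        raise ValueError("probability matrix must have 4 rows (A, C, G, T)")
    if matrix.shape[1] > MAX_MATRIX_WIDTH:
        raise ValueError(f"motif wider than {MAX_MATRIX_WIDTH} columns")
    probs = (matrix + pseudocount) / (matrix + pseudocount).sum(axis=0, keepdims=True)
    log_odds = np.log2(probs / 0.25)
    return np.round(log_odds / granularity).astype(np.int64)


def score_null_distribution(disc_log_odds: np.ndarray) -> dict[int, float]:
    """Exact distribution of the discretised window score under the uniform
    background, by convolution over positions."""
    dist: dict[int, float] = {0: 1.0}
    for column in disc_log_odds.T:
        new: dict[int, float] = {}
        for score, prob in dist.items():
            for value in column:
                key = score + int(value)
                new[key] = new.get(key, 0.0) + prob * 0.25
        dist = new
    return dist


def motif_score_threshold(
    matrix: np.ndarray,
    p_cut: float = 1e-5,
    pseudocount: float = 0.01,
    granularity: float = SCORE_GRANULARITY,
    name: str = "motif",
) -> MatrixMotif:
    """Cutoff = smallest score whose null tail probability is <= p_cut.

    With ``p_cut = 1`` the cutoff is the minimum score (every window
    matches).  Short motifs may have no achievable score with tail <=
    p_cut (the best possible word of a 7-mer has p = 4^-7 ~ 6e-5); the
    cutoff is then None and the motif can never match.
    """
    disc = discretise_log_odds(matrix, pseudocount, granularity)
    dist = score_null_distribution(disc)
    scores = sorted(dist, reverse=True)
    tail = 0.0
    cutoff: int | None = None
    for score in scores:
        tail += dist[score]
        if tail <= p_cut:
            cutoff = score
        else:
            break
    if cutoff is None:
        logger.warning(
            "motif %s: no score reaches tail probability <= %g; it cannot match",
            name, p_cut,
        )
    return MatrixMotif(name, disc, granularity, cutoff)


def count_matrix_matches(sequence: str, motif: MatrixMotif) -> int:
    """Overlapping windows scoring at or above the motif cutoff."""
    if motif.cutoff_units is None:
        return 0
    sequence = sequence.upper().replace("U", "T")
    index = {b: i for i, b in enumerate(BASES)}
    count = 0
    for i in range(len(sequence) - motif.width + 1):
        window = sequence[i : i + motif.width]
        score = 0
        ok = True
        for j, base in enumerate(window):
            if base not in index:
                ok = False
                break
            score += int(motif.disc_log_odds[index[base], j])
        if ok and score >= motif.cutoff_units:
            count += 1
    return count


def read_meme_motifs(path: str | Path) -> dict[str, np.ndarray]:
    """Read MEME-minimal motif files into name -> 4 x L probability matrices."""
    matrices: dict[str, np.ndarray] = {}
    name = None
    rows: list[list[float]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    matrices[name] = np.array(rows).T
                name = line.split()[1]
                rows = []
            elif name is not None and line and line[0].isdigit() or (line.startswith("0.") if line else False):
                parts = line.split()
                if len(parts) == 4:
                    rows.append([float(p) for p in parts])
    if name is not None and rows:
        matrices[name] = np.array(rows).T
    return matrices


# ---------------------------------------------------------------------------
# motif densities


def count_string_matches(sequence: str, motif: str) -> int:
    """Overlapping exact occurrences of ``motif`` in ``sequence``."""
    sequence = sequence.upper().replace("U", "T")
    motif = motif.upper().replace("U", "T")
    count = 0
    start = sequence.find(motif)
    while start != -1:
        count += 1
        start = sequence.find(motif, start + 1)
    return count


def normalized_motif_counts(
    sequence: str,
    motifs: Sequence[MotifRecord],
) -> dict[str, float]:
    """Per-RBP motif matches per 100 nt of query sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    length = len(sequence)
    return {
        record.rbp_name: count_string_matches(sequence, record.motif) * 100.0 / length
        for record in motifs
    }


def rbp_binding_score(counts: Mapping[str, float]) -> float:
    """Overall binding score: sum of the normalised counts across RBPs."""
    return float(sum(counts.values()))


# ---------------------------------------------------------------------------
# dinucleotide shuffle (Altschul-Erickson Euler-path construction)


def dinucleotide_shuffle(sequence: str, seed: int = 0) -> str:
    """Shuffle preserving the exact dinucleotide multiset.

    The output retains the input's first and last characters and its full
    dinucleotide count vector (Euler-path construction on the de Bruijn
    multigraph of adjacent pairs).  Deterministic under ``seed``.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        return sequence
    rng = random.Random(seed)
    adjacency: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adjacency.setdefault(a, []).append(b)
    vertices = sorted(adjacency.keys() | set(seq))
    first, last = seq[0], seq[-1]
    if len(vertices) == 1:
        return sequence

    def connected_to_last(last_edges: dict[str, str]) -> bool:
        for vertex in vertices:
            if vertex == last or vertex not in adjacency:
                continue
            current, steps = vertex, 0
            while current != last and steps <= len(vertices):
                current = last_edges.get(current)
                if current is None:
                    return False
                steps += 1
            if current != last:
                return False
        return True

    while True:
        last_edges = {
            vertex: rng.choice(adjacency[vertex])
            for vertex in vertices
            if vertex != last and vertex in adjacency
        }
        if connected_to_last(last_edges):
            break

    shuffled: dict[str, list[str]] = {}
    for vertex, successors in adjacency.items():
        pool = list(successors)
        if vertex != last and vertex in last_edges:
            pool.remove(last_edges[vertex])
        rng.shuffle(pool)
        if vertex != last and vertex in last_edges:
            pool.append(last_edges[vertex])
        shuffled[vertex] = pool

    result = [first]
    pointers = dict.fromkeys(shuffled, 0)
    current = first
    for _ in range(len(seq) - 1):
        successor = shuffled[current][pointers[current]]
        pointers[current] += 1
        result.append(successor)
        current = successor
    return "".join(result)


# ---------------------------------------------------------------------------
# set-vs-set enrichment


def motif_enrichment(
    query_sequences: Sequence[str],
    control_sequences: Sequence[str],
    motifs: Sequence[MotifRecord],
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Per-RBP one-sided exact test of motif presence in query vs control.

    For each RBP the sequences containing at least one match are counted in
    both sets, a one-sided Fisher exact test (greater) is computed, and the
    p-values are Benjamini-Hochberg adjusted across RBPs.  RBPs with
    adjusted p below ``alpha`` are flagged significant.
    """
    if not query_sequences or not control_sequences:
        raise ValueError("both query and control sets must be non-empty")
    rows = []
    for record in motifs:
        q_with = sum(count_string_matches(s, record.motif) > 0 for s in query_sequences)
        c_with = sum(count_string_matches(s, record.motif) > 0 for s in control_sequences)
        table = [
            [q_with, len(query_sequences) - q_with],
            [c_with, len(control_sequences) - c_with],
        ]
        _, p_value = fisher_exact(table, alternative="greater")
        rows.append(
            {
                "rbp": record.rbp_name,
                "query_with_match": q_with,
                "control_with_match": c_with,
                "p_value": float(p_value),
            }
        )
    result = pd.DataFrame(rows)
    _, adjusted, _, _ = multipletests(result["p_value"], method="fdr_bh")
    result["p_adjusted"] = adjusted
    result["significant"] = result["p_adjusted"] < alpha
    return result.sort_values("p_adjusted").reset_index(drop=True)


def hypergeometric_enrichment(
    n_hits: int, n_draws: int, n_category: int, n_universe: int
) -> float:
    """P(X >= n_hits) drawing ``n_draws`` from a universe with
    ``n_category`` marked elements (plain over-representation test)."""
    return float(hypergeom.sf(n_hits - 1, n_universe, n_category, n_draws))


# ---------------------------------------------------------------------------
# constrained non-conserved (CNC) scoring


WINDOW_WIDTH = 10


@dataclass
class CNCTrack:
    """Non-overlapping fixed-width 10-nt scored windows."""

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    values: dict[str, np.ndarray]

    @classmethod
    def from_file(cls, path: str | Path) -> "CNCTrack":
        table = pd.read_csv(
            path, sep="\t", names=["chrom", "start", "end", "score"], comment="#"
        )
        starts: dict[str, np.ndarray] = {}
        ends: dict[str, np.ndarray] = {}
        values: dict[str, np.ndarray] = {}
        for chrom, group in table.groupby("chrom", sort=True):
            group = group.sort_values("start")
            s = group["start"].to_numpy(dtype=np.int64)
            e = group["end"].to_numpy(dtype=np.int64)
            if np.any(e - s != WINDOW_WIDTH):
                raise ValueError(f"{path}: windows must be exactly {WINDOW_WIDTH} nt wide")
            if np.any(e[:-1] > s[1:]):
                raise ValueError(f"{path}: overlapping windows on {chrom}")
            starts[str(chrom)] = s
            ends[str(chrom)] = e
            values[str(chrom)] = group["score"].to_numpy(dtype=np.float64)
        return cls(starts, ends, values)


def mean_cnc(region: GenomicRegion, track: CNCTrack) -> float:
    """Mean CNC score over the 10-nt windows overlapping the region; NaN
    when the region falls entirely in a track gap (excluded downstream)."""
    if region.chrom not in track.starts:
        return float("nan")
    starts = track.starts[region.chrom]
    ends = track.ends[region.chrom]
    lo = int(np.searchsorted(ends, region.start, side="right"))
    hi = int(np.searchsorted(starts, region.end, side="left"))
    if hi <= lo:
        return float("nan")
    return float(track.values[region.chrom][lo:hi].mean())
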