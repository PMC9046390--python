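"""The 41-dimensional omic feature vector for a genomic region.

Composition (fixed order):

====================  ==  =======================================================
block                  n  description
====================  ==  =======================================================
pas_signal             1  binary: region contains a poly(A)-signal PWM match
freq_{A,C,G,T}         4  mono-nucleotide frequencies (count / region length)
freq_{AA..TT}         16  di-nucleotide frequencies (count / region length)
mean_conservation      1  mean per-base conservation score (gaps count as 0)
transposon_fraction    1  fraction of region covered by transposable elements
struct_*              16  mean DNA structural-property value over k-mer windows
mean_EE                1  entropy efficiency of read coverage, averaged per tissue
mean_PD                1  boundary percentage difference, averaged per tissue
====================  ==  =======================================================

The PAS position weight matrix is built from the 12 commonly occurring
polyadenylation-signal hexamers (AAUAAA and variants); a window is a match
when its relative log-odds score (score - min) / (max - min) reaches 0.95,
emulating the standard "min.score 95%" PWM-scanner convention.

Entropy efficiency EE(x) = -sum_i p(x_i) log p(x_i) / log(n) with
p(x_i) = x_i / sum_j x_j measures coverage uniformity (1 = perfectly
uniform).  Percentage difference PD = |r1 - r2| / mean(r1, r2) * 100
between the read depths at the two region boundaries (range 0-200).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import fetch_sequence, reverse_complement
from .regions import GenomicRegion, overlap_fraction

logger = logging.getLogger(__name__)

#: the 12 commonly occurring polyadenylation-signal hexamers (DNA alphabet)
PAS_HEXAMERS = (
    "AATAAA", "ATTAAA", "AGTAAA", "TATAAA", "AATATA", "AATACA",
    "CATAAA", "GATAAA", "ACTAAA", "AATAGA", "AATGAA", "AAGAAA",
)

#: transposable-element classes counted towards transposon_fraction
TRANSPOSON_CLASSES = frozenset({"LINE", "SINE", "LTR", "DNA", "RC"})

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

#: the 16 DNA structural properties of the default profile (property -> k)
STRUCTURAL_PROPERTIES: dict[str, int] = {
    "a_philicity": 2,
    "base_stacking": 2,
    "b_dna_twist": 2,
    "bendability": 3,
    "bending_stiffness": 2,
    "curvature": 3,
    "denaturation": 2,
    "duplex_disrupt_energy": 2,
    "duplex_free_energy": 2,
    "flexibility_shift": 2,
    "flexibility_slide": 2,
    "nucleosome_positioning": 3,
    "propeller_twist": 2,
    "protein_deformation": 2,
    "protein_dna_twist": 2,
    "z_dna": 2,
}

FEATURE_NAMES: tuple[str, ...] = (
    ("pas_signal",)
    + tuple(f"freq_{b}" for b in BASES)
    + tuple(f"freq_{d}" for d in DINUCLEOTIDES)
    + ("mean_conservation", "transposon_fraction")
    + tuple(f"struct_{name}" for name in STRUCTURAL_PROPERTIES)
    + ("mean_EE", "mean_PD")
)

_NEG_SENTINEL = -1e6  # stands in for log(0) when pseudocount is 0


# ---------------------------------------------------------------------------
# poly(A)-signal PWM


@dataclass
class PWMModel:
    """Log-odds PWM over the PAS hexamers with relative-score threshold."""

    probabilities: np.ndarray  # 4 x width, columns sum to 1
    log_odds: np.ndarray  # 4 x width, vs uniform 0.25 background
    min_score: float
    max_score: float
    relative_threshold: float = 0.95

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    def score(self, window: str) -> float:
        total = 0.0
        for position, base in enumerate(window):
            total += self.log_odds[BASES.index(base), position]
        return total

    def relative_score(self, window: str) -> float:
        return (self.score(window) - self.min_score) / (self.max_score - self.min_score)


def build_pas_pwm(
    hexamers: Sequence[str] = PAS_HEXAMERS,
    pseudocount: float = 0.1,
) -> PWMModel:
    """Build the consensus PWM from the PAS hexamer list (U mapped to T)."""
    motifs = [m.upper().replace("U", "T") for m in hexamers]
    width = len(motifs[0])
    for motif in motifs:
        if len(motif) != width:
            raise ValueError(f"motif {motif!r} length differs from {width}")
        if any(base not in BASES for base in motif):
            raise ValueError(f"motif {motif!r} contains a non-ACGU character")
    counts = np.zeros((4, width))
    for motif in motifs:
        for position, base in enumerate(motif):
            counts[BASES.index(base), position] += 1
    probabilities = (counts + pseudocount) / (len(motifs) + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probabilities / 0.25)
    log_odds[np.isneginf(log_odds)] = _NEG_SENTINEL
    min_score = float(log_odds.min(axis=0).sum())
    max_score = float(log_odds.max(axis=0).sum())
    return PWMModel(probabilities, log_odds, min_score, max_score)


def scan_pas(sequence: str, pwm: PWMModel | None = None, both_strands: bool = False) -> int:
    """Binary PAS occurrence: 1 iff any window reaches the relative threshold.

    Windows containing N are skipped.  For unstranded regions callers pass
    ``both_strands=True`` and the reverse complement is scanned as well.
    """
    if pwm is None:
        pwm = build_pas_pwm()
    sequence = sequence.upper().replace("U", "T")
    if len(sequence) < pwm.width:
        logger.warning("sequence shorter than PWM width (%d nt); PAS feature set to 0", len(sequence))
        return 0
    strands = [sequence, reverse_complement(sequence)] if both_strands else [sequence]
    for seq in strands:
        for i in range(len(seq) - pwm.width + 1):
            window = seq[i : i + pwm.width]
            if "N" in window:
                continue
            if pwm.relative_score(window) >= pwm.relative_threshold:
                return 1
    return 0


# ---------------------------------------------------------------------------
# sequence composition


def nucleotide_frequencies(sequence: str) -> dict[str, float]:
    """Mono- and di-nucleotide frequencies, both divided by region length.

    The di-nucleotide denominator is the full region length L (not L - 1),
    matching the definition of frequency as occurrences over region length;
    the resulting ~1/L downward bias is uniform across regions.  Units
    containing N are excluded from the counts.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper().replace("U", "T")
    length = len(sequence)
    freqs = {f"freq_{b}": sequence.count(b) / length for b in BASES}
    di_counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(length - 1):
        pair = sequence[i : i + 2]
        if pair in di_counts:
            di_counts[pair] += 1
    for pair, count in di_counts.items():
        freqs[f"freq_{pair}"] = count / length
    return freqs


# ---------------------------------------------------------------------------
# conservation / transposons


def mean_conservation(track: CoverageTrack, region: GenomicRegion) -> float:
    """Arithmetic mean of per-base conservation; unscored bases count as 0."""
    return float(track.region_depth(region).mean())


def transposon_fraction(
    repeats: Sequence[GenomicRegion],
    region: GenomicRegion,
    classes: frozenset[str] = TRANSPOSON_CLASSES,
) -> float:
    """Fraction of the region covered by (merged) transposable elements.

    When a repeat carries class information in its id, only LINE/SINE/LTR/
    DNA/RC elements are counted; repeats without class info all count.
    """
    selected = [r for r in repeats if r.id is None or r.id.split("/")[0] in classes]
    return overlap_fraction(region, selected)


# ---------------------------------------------------------------------------
# DNA structural properties


@dataclass
class ConversionTable:
    """A total mapping from k-mers to a numeric structural-property value."""

    property_name: str
    k: int
    mapping: Mapping[str, float]

    def __post_init__(self) -> None:
        expected = 4 ** self.k
        missing = [
            "".join(kmer)
            for kmer in itertools.product(BASES, repeat=self.k)
            if "".join(kmer) not in self.mapping
        ]
        if missing:
            raise ValueError(
                f"conversion table {self.property_name!r} missing "
                f"{len(missing)}/{expected} {self.k}-mers (e.g. {missing[0]})"
            )


def load_conversion_tables(path: str | Path) -> dict[str, ConversionTable]:
    """Load conversion tables from a ``property<TAB>kmer<TAB>value`` TSV."""
    table = pd.read_csv(path, sep="\t", names=["property", "kmer", "value"], comment="#")
    tables: dict[str, ConversionTable] = {}
    for name, group in table.groupby("property", sort=True):
        mapping = dict(zip(group["kmer"].str.upper(), group["value"].astype(float)))
        k = len(next(iter(mapping)))
        tables[str(name)] = ConversionTable(str(name), k, mapping)
    return tables


def validate_structural_profile(tables: Mapping[str, ConversionTable]) -> None:
    """The default profile requires exactly 16 structural properties."""
    if len(tables) != len(STRUCTURAL_PROPERTIES):
        raise ValueError(
            f"structural profile must contain exactly {len(STRUCTURAL_PROPERTIES)} "
            f"properties, got {len(tables)}"
        )


def structural_properties(
    sequence: str,
    tables: Mapping[str, ConversionTable],
) -> dict[str, float]:
    """Mean conversion-table value over all overlapping k-mer windows.

    Windows containing N are skipped; a sequence with no scorable window
    reports 0 with a warning.
    """
    sequence = sequence.upper().replace("U", "T")
    values: dict[str, float] = {}
    for name, table in tables.items():
        total, count = 0.0, 0
        for i in range(len(sequence) - table.k + 1):
            window = sequence[i : i + table.k]
            if "N" in window:
                continue
            total += table.mapping[window]
            count += 1
        if count == 0:
            logger.warning("no scorable %d-mer window for property %s; value set to 0", table.k, name)
            values[name] = 0.0
        else:
            values[name] = total / count
    return values


# ---------------------------------------------------------------------------
# transcriptomic features


def entropy_efficiency(depths: np.ndarray | Sequence[float]) -> float:
    """Normalised Shannon entropy of the per-base depth vector, in [0, 1].

    Zero-depth positions contribute 0 (0*log 0 := 0); an all-zero vector
    reports 0.  The result is log-base invariant since numerator and
    denominator share the base.
    """
    depths = np.asarray(depths, dtype=np.float64)
    n = depths.size
    if n < 2:
        raise ValueError("entropy efficiency requires a vector of length >= 2")
    total = depths.sum()
    if total == 0:
        return 0.0
    p = depths / total
    nonzero = p[p > 0]
    return float(-(nonzero * np.log(nonzero)).sum() / math.log(n))


def percentage_difference(
    depths: np.ndarray | Sequence[float],
    boundary_window: int = 1,
) -> float:
    """|r1 - r2| / mean(r1, r2) * 100 between the two region boundaries.

    r1 and r2 are the mean depths over the first and last ``boundary_window``
    bases (default: the single boundary base).  Both boundaries zero reports
    0 (no signal, no asymmetry); exactly one zero gives the maximum 200.
    """
    depths = np.asarray(depths, dtype=np.float64)
    if depths.size < 2:
        raise ValueError("percentage difference requires a vector of length >= 2")
    w = min(boundary_window, depths.size)
    r1 = float(depths[:w].mean())
    r2 = float(depths[-w:].mean())
    if r1 == 0.0 and r2 == 0.0:
        return 0.0
    return abs(r1 - r2) / ((r1 + r2) / 2.0) * 100.0


# ---------------------------------------------------------------------------
# full vector


def extract_features(
    region: GenomicRegion,
    genome,
    coverage_tracks: Sequence[CoverageTrack],
    conservation: CoverageTrack | None = None,
    repeats: Sequence[GenomicRegion] = (),
    tables: Mapping[str, ConversionTable] | None = None,
    pwm: PWMModel | None = None,
    strand: str | None = None,
    boundary_window: int = 1,
) -> pd.Series:
    """Compute the full 41-feature vector for one region.

    ``strand`` overrides the region strand (e.g. the strand of the
    associated gene for unstranded expressed regions).  When the effective
    strand is unknown (``"."``), PAS scanning covers both strands and
    composition/structural features use the plus strand.  EE and PD are
    computed per coverage track and arithmetic-averaged across tracks; with
    no track supplied the transcriptomic features are 0 (warned).
    """
    if pwm is None:
        pwm = build_pas_pwm()
    if tables is None:
        from .fixtures import synthetic_structural_tables

        tables = synthetic_structural_tables()
    validate_structural_profile(tables)

    effective_strand = strand if strand is not None else region.strand
    sequence = fetch_sequence(genome, region, strand=effective_strand)

    values: dict[str, float] = {}
    values["pas_signal"] = float(
        scan_pas(sequence, pwm, both_strands=(effective_strand == "."))
    )
    values.update(nucleotide_frequencies(sequence))
    values["mean_conservation"] = (
        mean_conservation(conservation, region) if conservation is not None else 0.0
    )
    values["transposon_fraction"] = transposon_fraction(repeats, region)
    for name, value in structural_properties(sequence, tables).items():
        values[f"struct_{name}"] = value

    if coverage_tracks:
        ee_values, pd_values = [], []
        for track in coverage_tracks:
            depths = track.region_depth(region)
            ee_values.append(entropy_efficiency(depths))
            pd_values.append(percentage_difference(depths, boundary_window))
        values["mean_EE"] = float(np.mean(ee_values))
        values["mean_PD"] = float(np.mean(pd_values))
    else:
        logger.warning("no coverage tracks supplied; transcriptomic features set to 0")
        values["mean_EE"] = 0.0
        values["mean_PD"] = 0.0

    vector = pd.Series(values, name=region.id).reindex(FEATURE_NAMES)
    assert not vector.isna().any(), "feature vector contains missing entries"
    return vector


def extract_feature_matrix(
    regions: Sequence[GenomicRegion],
    genome,
    coverage_tracks: Sequence[CoverageTrack],
    strands: Sequence[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Feature matrix (regions x 41) with one row per input region."""
    rows = []
    for i, region in enumerate(regions):
        strand = strands[i] if strands is not None else None
        rows.append(extract_features(region, genome, coverage_tracks, strand=strand, **kwargs))
    matrix = pd.DataFrame(rows)
    matrix.index = [r.id if r.id is not None else f"region_{i}" for i, r in enumerate(regions)]
    return matrix
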