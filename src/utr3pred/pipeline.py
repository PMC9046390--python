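"""Apply a trained classifier to intergenic expressed regions (ERs).

Candidate ERs (unstranded intervals of intergenic RNA-seq coverage) are
associated with a protein-coding gene (junction evidence wins over
proximity to the nearest expressed gene), filtered to plausible 3'UTR
candidates (downstream of the gene's 3' end, within 10 kb, longer than
40 nt and at most 2 kb), classified at a deployment probability threshold
of 0.6 (strict >), and finally categorised by tissue-specificity across
tissues and checked for overlap with reference 3'UTR annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotation import AnnotationModel
from .coverage import CoverageTrack
from .features import ConversionTable, PWMModel, extract_features
from .forest import POSITIVE_CLASS, ForestModel
from .regions import GenomicRegion, overlap_fraction

logger = logging.getLogger(__name__)

MAX_GENE_DISTANCE = 10_000
MIN_ER_LENGTH = 40  # ERs with length <= 40 are removed
MAX_ER_LENGTH = 2_000
PREDICTION_THRESHOLD = 0.6
MIN_EXPRESSION = 0.1


@dataclass
class Candidate:
    region: GenomicRegion
    gene_id: str
    association: str  # "junction" or "proximity"
    distance: int
    strand: str  # strand inherited from the associated gene


@dataclass
class PredictionRecord:
    region: GenomicRegion
    tissue: str
    probability: float
    call: str  # "UTR3" or "NON_UTR3"
    gene_id: str
    association: str
    distance_to_gene: int
    specificity_category: str = "unset"
    annotated_flag: bool | None = None


@dataclass
class FeatureResources:
    """Everything needed to build the feature matrix for one tissue."""

    genome: object
    coverage_tracks: Sequence[CoverageTrack]
    conservation: CoverageTrack | None = None
    repeats: Sequence[GenomicRegion] = ()
    tables: Mapping[str, ConversionTable] | None = None
    pwm: PWMModel | None = None
    boundary_window: int = 1


def _gene_gap(er: GenomicRegion, gene_region: GenomicRegion) -> int:
    """Gap in nt between the ER and the gene span (0 when adjacent/overlapping)."""
    if er.start >= gene_region.end:
        return er.start - gene_region.end
    if er.end <= gene_region.start:
        return gene_region.start - er.end
    return 0


def _is_downstream(er: GenomicRegion, gene_region: GenomicRegion, strand: str) -> bool:
    """True when the ER lies past the gene's 3' end (strand-aware)."""
    if strand == "+":
        return er.start >= gene_region.end
    if strand == "-":
        return er.end <= gene_region.start
    return False


def associate_gene(
    er: GenomicRegion,
    annotation: AnnotationModel,
    expression: Mapping[str, float],
    junction_map: Mapping[str, str] | None = None,
) -> tuple[str, str, int] | None:
    """Assign a gene to an ER: junction evidence first, else nearest
    expressed gene (expression > 0.1) on the same chromosome.

    Ties in distance break towards the smaller gene id.  Returns
    ``(gene_id, association, distance)`` or None when no expressed gene
    exists on the ER's chromosome (the ER is dropped with a log entry).
    """
    if junction_map and er.id is not None and er.id in junction_map:
        gene_id = junction_map[er.id]
        gene = annotation.genes[gene_id]
        return gene_id, "junction", _gene_gap(er, gene.region)
    best: tuple[int, str] | None = None
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        if gene.region.chrom != er.chrom:
            continue
        if expression.get(gene_id, 0.0) <= MIN_EXPRESSION:
            continue
        distance = _gene_gap(er, gene.region)
        if best is None or distance < best[0]:
            best = (distance, gene_id)
    if best is None:
        logger.info("ER %s dropped: no expressed gene on %s", er.id, er.chrom)
        return None
    return best[1], "proximity", best[0]


def orient_and_filter_ers(
    ers: Sequence[GenomicRegion],
    annotation: AnnotationModel,
    expression: Mapping[str, float],
    junction_map: Mapping[str, str] | None = None,
    max_distance: int = MAX_GENE_DISTANCE,
    min_length: int = MIN_ER_LENGTH,
    max_length: int = MAX_ER_LENGTH,
) -> list[Candidate]:
    """Keep ERs associated with a protein-coding gene, positioned downstream
    of its 3' end within ``max_distance``, with ``min_length`` < length <=
    ``max_length``."""
    candidates: list[Candidate] = []
    for er in ers:
        if er.length <= min_length or er.length > max_length:
            continue
        assigned = associate_gene(er, annotation, expression, junction_map)
        if assigned is None:
            continue
        gene_id, association, distance = assigned
        gene = annotation.genes[gene_id]
        if gene.biotype != "protein_coding":
            continue
        if distance > max_distance:
            continue
        if not _is_downstream(er, gene.region, gene.strand):
            continue
        candidates.append(Candidate(er, gene_id, association, distance, gene.strand))
    return candidates


def predict_ers(
    candidates: Sequence[Candidate],
    model: ForestModel,
    resources: FeatureResources,
    tissue: str,
    threshold: float = PREDICTION_THRESHOLD,
) -> list[PredictionRecord]:
    """Classify candidate ERs; a 3'UTR call requires probability strictly
    above the threshold.  Sequence-feature strand is inherited from the
    associated gene."""
    if not resources.coverage_tracks:
        raise ValueError("no coverage tracks supplied for feature extraction")
    records: list[PredictionRecord] = []
    for candidate in candidates:
        vector = extract_features(
            candidate.region,
            resources.genome,
            resources.coverage_tracks,
            conservation=resources.conservation,
            repeats=resources.repeats,
            tables=resources.tables,
            pwm=resources.pwm,
            strand=candidate.strand,
            boundary_window=resources.boundary_window,
        )
        proba = model.predict_proba(vector.to_frame().T)
        probability = float(proba[POSITIVE_CLASS].iloc[0])
        call = "UTR3" if probability > threshold else "NON_UTR3"
        records.append(
            PredictionRecord(
                region=candidate.region,
                tissue=tissue,
                probability=probability,
                call=call,
                gene_id=candidate.gene_id,
                association=candidate.association,
                distance_to_gene=candidate.distance,
            )
        )
    return records


def summarize_predictions(records: Sequence[PredictionRecord]) -> dict:
    """Per-tissue bookkeeping: counts, genomic space of 3'UTR calls, genes."""
    utr3 = [r for r in records if r.call == "UTR3"]
    return {
        "n_candidates": len(records),
        "n_utr3": len(utr3),
        "n_non_utr3": len(records) - len(utr3),
        "utr3_kb": sum(r.region.length for r in utr3) / 1000.0,
        "n_genes": len({r.gene_id for r in utr3}),
    }


def categorize_tissue_specificity(
    per_tissue: Mapping[str, Sequence[GenomicRegion]],
    brain_tissues: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Tissue-specificity category for every ER instance.

    Rules, applied in order per ER: (1) no >=1 nt overlap with any other
    tissue's ERs -> ``absolute_tissue_specific``; (2) brain fraction of the
    detecting tissues > 0.75 -> ``highly_brain_specific``; (3) detected in
    >= 5 tissues with all start and end coordinates pairwise within 10 nt
    -> ``shared``; (4) otherwise ``ambiguous``.  "Detected in a tissue"
    means a >= 1 nt overlap with an ER of that tissue; a tissue counts once
    regardless of how many of its ERs overlap.
    """
    if len(per_tissue) < 2:
        raise ValueError("categorisation requires at least 2 tissues")
    instances = [
        (tissue, region)
        for tissue, regions in per_tissue.items()
        for region in regions
    ]
    rows = []
    for tissue, region in instances:
        overlapping = [
            (other_tissue, other)
            for other_tissue, other in instances
            if other_tissue != tissue and region.overlaps(other)
        ]
        if not overlapping:
            category = "absolute_tissue_specific"
        else:
            detecting = {tissue} | {t for t, _ in overlapping}
            brain_fraction = sum(t in brain_tissues for t in detecting) / len(detecting)
            if brain_fraction > 0.75:
                category = "highly_brain_specific"
            else:
                group = [region] + [r for _, r in overlapping]
                starts = [r.start for r in group]
                ends = [r.end for r in group]
                within_window = (
                    max(starts) - min(starts) <= 10 and max(ends) - min(ends) <= 10
                )
                if len(detecting) >= 5 and within_window:
                    category = "shared"
                else:
                    category = "ambiguous"
        rows.append(
            {
                "tissue": tissue,
                "id": region.id,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def annotation_overlap_status(
    predictions: Sequence[GenomicRegion],
    reference_sets: Mapping[str, Sequence[GenomicRegion]],
    min_fraction: float = 0.5,
) -> list[bool]:
    """True per prediction iff >= 50% of it overlaps the 3'UTR union of ANY
    single reference annotation set (overlap split across sets does not
    count)."""
    flags = []
    for prediction in predictions:
        flags.append(
            any(
                overlap_fraction(prediction, list(regions)) >= min_fraction
                for regions in reference_sets.values()
            )
        )
    return flags
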