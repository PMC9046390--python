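"""Build the six-class labelled training set from a gene annotation.

Positive examples are known 3'UTR exons; negatives are 5'UTR exons,
internal coding exons (ICEs), and exons of lncRNA, ncRNA and pseudogene
biotypes.  For every class the pipeline is: keep transcripts with transcript
support level exactly 1, collapse the transcripts of each gene into a merged
"meta-transcript" (union of the selected exonic intervals), and keep merged
exons of width >= 40 nt.  ICEs are the coding exons of transcripts with at
least three coding exons, after removing the first and last coding exon in
transcription order (strand-aware: the first coding exon of a minus-strand
transcript is the genomically rightmost one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import AnnotationModel, Transcript
from .coverage import CoverageTrack
from .regions import GenomicRegion, merge_regions

logger = logging.getLogger(__name__)

LABELS = ("THREE_UTR", "FIVE_UTR", "ICE", "LNCRNA", "NCRNA", "PSEUDOGENE")

MIN_EXAMPLE_LENGTH = 40

LNCRNA_BIOTYPES = frozenset(
    {
        "non_coding", "3prime_overlapping_ncRNA", "antisense", "lincRNA",
        "sense_intronic", "sense_overlapping", "macro_lncRNA",
    }
)
NCRNA_BIOTYPES = frozenset(
    {"miRNA", "misc_RNA", "rRNA", "snRNA", "snoRNA", "vaultRNA"}
)
PSEUDOGENE_BIOTYPES = frozenset(
    {
        "pseudogene", "processed_pseudogene", "unprocessed_pseudogene",
        "transcribed_processed_pseudogene", "transcribed_unitary_pseudogene",
        "transcribed_unprocessed_pseudogene", "translated_processed_pseudogene",
        "unitary_pseudogene", "TR_V_pseudogene", "TR_J_pseudogene",
        "rRNA_pseudogene", "polymorphic_pseudogene", "IG_V_pseudogene",
        "IG_pseudogene", "IG_J_pseudogene", "IG_C_pseudogene",
    }
)


@dataclass(frozen=True)
class TrainingExample:
    region: GenomicRegion
    label: str
    gene_id: str


def select_tsl1_transcripts(annotation: AnnotationModel) -> list[Transcript]:
    """Transcripts with TSL exactly 1; missing TSL is excluded, never imputed."""
    selected = [t for t in annotation.transcripts.values() if t.tsl == 1]
    if not selected:
        logger.warning("no TSL-1 transcripts found in annotation")
    return selected


def build_meta_transcript(
    annotation: AnnotationModel,
    transcripts: list[Transcript],
    element_kind: str,
) -> list[GenomicRegion]:
    """Union of the selected exonic intervals of one gene's transcripts.

    ``element_kind`` is one of ``three_prime_utr``, ``five_prime_utr``,
    ``CDS`` or ``exon``.  Overlapping intervals are merged; disjoint ones
    retained separately; strand is preserved on the output.
    """
    if not transcripts:
        return []
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(gene_ids)}")
    strands = {t.strand for t in transcripts}
    if len(strands) > 1:
        raise ValueError(f"mixed strands within gene {gene_ids.pop()!r}")
    strand = strands.pop()
    intervals: list[GenomicRegion] = []
    for transcript in transcripts:
        intervals.extend(annotation.children(transcript.id, element_kind))
    if not intervals:
        return []
    return [
        GenomicRegion(r.chrom, r.start, r.end, strand)
        for r in merge_regions(intervals)
    ]


def extract_ice_regions(
    annotation: AnnotationModel,
    transcripts: list[Transcript],
) -> list[GenomicRegion]:
    """Internal coding exons of one gene, merged across its transcripts.

    Transcripts with fewer than three coding exons contribute nothing (they
    cannot contain an internal exon).
    """
    if not transcripts:
        return []
    strands = {t.strand for t in transcripts}
    if len(strands) > 1:
        raise ValueError("mixed strands within gene")
    strand = strands.pop()
    internal: list[GenomicRegion] = []
    for transcript in transcripts:
        ordered = annotation.cds_in_transcription_order(transcript.id)
        if len(ordered) >= 3:
            internal.extend(ordered[1:-1])
    if not internal:
        return []
    return [
        GenomicRegion(r.chrom, r.start, r.end, strand)
        for r in merge_regions(internal)
    ]


def extract_class_regions(
    annotation: AnnotationModel,
    biotype_map: dict[str, frozenset[str]] | None = None,
) -> list[TrainingExample]:
    """All six labelled classes via TSL filter -> meta-transcript -> >=40 nt."""
    if biotype_map is None:
        biotype_map = {
            "LNCRNA": LNCRNA_BIOTYPES,
            "NCRNA": NCRNA_BIOTYPES,
            "PSEUDOGENE": PSEUDOGENE_BIOTYPES,
        }
    tsl1 = select_tsl1_transcripts(annotation)
    by_gene: dict[str, list[Transcript]] = {}
    for transcript in tsl1:
        by_gene.setdefault(transcript.gene_id, []).append(transcript)

    examples: list[TrainingExample] = []

    def add(regions: list[GenomicRegion], label: str, gene_id: str) -> None:
        for i, region in enumerate(regions):
            if region.length < MIN_EXAMPLE_LENGTH:
                continue
            named = GenomicRegion(
                region.chrom, region.start, region.end, region.strand,
                f"{gene_id}:{label}:{i}",
            )
            examples.append(TrainingExample(named, label, gene_id))

    for gene_id, transcripts in sorted(by_gene.items()):
        gene = annotation.genes[gene_id]
        if gene.biotype == "protein_coding":
            add(build_meta_transcript(annotation, transcripts, "three_prime_utr"), "THREE_UTR", gene_id)
            add(build_meta_transcript(annotation, transcripts, "five_prime_utr"), "FIVE_UTR", gene_id)
            add(extract_ice_regions(annotation, transcripts), "ICE", gene_id)
        else:
            label = next(
                (lab for lab, biotypes in biotype_map.items() if gene.biotype in biotypes),
                None,
            )
            if label is None:
                logger.info("skipping gene %s with unmapped biotype %r", gene_id, gene.biotype)
                continue
            add(build_meta_transcript(annotation, transcripts, "exon"), label, gene_id)
    return examples


def filter_expressed_known_utrs(
    utrs: list[GenomicRegion],
    tracks: list[CoverageTrack],
    brain_tissues: set[str] | frozenset[str] = frozenset(),
    min_mean_depth: float = 5.0,
) -> pd.DataFrame:
    """Keep 3'UTRs with mean depth >= 5 in at least one tissue, with grouping.

    Each kept 3'UTR is annotated with its expressed-tissue set and a
    tissue-specificity group: expressed in exactly one tissue ->
    ``absolute_tissue_specific``; >75% of expressing tissues brain ->
    ``highly_brain_specific``; expressed in >= 5 tissues -> ``shared``;
    otherwise ``ambiguous``.
    """
    if not tracks:
        raise ValueError("at least one coverage track is required")
    rows = []
    for region in utrs:
        expressed = [
            track.tissue_label
            for track in tracks
            if track.mean_depth(region) >= min_mean_depth
        ]
        kept = bool(expressed)
        if not kept:
            group = None
        elif len(expressed) == 1:
            group = "absolute_tissue_specific"
        else:
            brain_fraction = sum(t in brain_tissues for t in expressed) / len(expressed)
            if brain_fraction > 0.75:
                group = "highly_brain_specific"
            elif len(expressed) >= 5:
                group = "shared"
            else:
                group = "ambiguous"
        rows.append(
            {
                "id": region.id,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "kept": kept,
                "expressed_tissues": ",".join(expressed),
                "n_expressed": len(expressed),
                "group": group,
            }
        )
    return pd.DataFrame(rows)


def write_training_set(examples: list[TrainingExample], outdir: str | Path) -> tuple[Path, Path]:
    """Write the labelled set as a regions.bed + labels.tsv pair."""
    from .regions import write_regions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed = outdir / "regions.bed"
    labels = outdir / "labels.tsv"
    write_regions([e.region for e in examples], bed)
    pd.DataFrame(
        [
            {"id": e.region.id, "label": e.label, "gene_id": e.gene_id}
            for e in examples
        ]
    ).to_csv(labels, sep="\t", index=False)
    return bed, labels
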