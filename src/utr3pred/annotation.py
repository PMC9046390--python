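"""Gene annotation model built from GTF (via gffutils).

GTF coordinates (1-based closed) are converted to the internal 0-based
half-open convention here, at the parsing boundary.  A missing transcript
support level (TSL) is recorded as ``None``, never coerced to 1, because the
training-corpus builder keeps only transcripts with TSL exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .regions import GenomicRegion

logger = logging.getLogger(__name__)

# exon-like child feature types retained from the GTF
_CHILD_TYPES = ("exon", "CDS", "five_prime_utr", "three_prime_utr")


@dataclass
class Gene:
    id: str
    biotype: str
    region: GenomicRegion
    strand: str


@dataclass
class Transcript:
    id: str
    gene_id: str
    strand: str
    tsl: int | None = None


@dataclass
class AnnotationModel:
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    _children: dict[tuple[str, str], list[GenomicRegion]] = field(default_factory=dict)
    _gene_transcripts: dict[str, list[str]] = field(default_factory=dict)

    def add_child(self, transcript_id: str, feature_type: str, region: GenomicRegion) -> None:
        self._children.setdefault((transcript_id, feature_type), []).append(region)

    def children(self, transcript_id: str, feature_type: str) -> list[GenomicRegion]:
        """Child intervals of one transcript, sorted by genomic start."""
        intervals = self._children.get((transcript_id, feature_type), [])
        return sorted(intervals, key=lambda r: (r.start, r.end))

    def exons(self, transcript_id: str) -> list[GenomicRegion]:
        return self.children(transcript_id, "exon")

    def cds(self, transcript_id: str) -> list[GenomicRegion]:
        return self.children(transcript_id, "CDS")

    def utr3(self, transcript_id: str) -> list[GenomicRegion]:
        return self.children(transcript_id, "three_prime_utr")

    def utr5(self, transcript_id: str) -> list[GenomicRegion]:
        return self.children(transcript_id, "five_prime_utr")

    def cds_in_transcription_order(self, transcript_id: str) -> list[GenomicRegion]:
        """CDS exons ordered 5'->3' along the transcript (strand-aware)."""
        intervals = self.cds(transcript_id)
        if self.transcripts[transcript_id].strand == "-":
            return list(reversed(intervals))
        return intervals

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[t] for t in self._gene_transcripts.get(gene_id, [])]

    def genes_by_biotype(self, biotypes: set[str]) -> list[Gene]:
        return [g for g in self.genes.values() if g.biotype in biotypes]


def _parse_tsl(raw: str | None) -> int | None:
    if raw is None:
        return None
    token = raw.strip().split()[0] if raw.strip() else ""
    return int(token) if token.isdigit() else None


def _attr(feature: gffutils.Feature, key: str) -> str | None:
    values = feature.attributes.get(key)
    return values[0] if values else None


def read_annotation(path: str | Path) -> AnnotationModel:
    """Parse a GTF file with gene/transcript/exon/CDS/UTR records."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    model = AnnotationModel()
    for feature in db.all_features():
        region = GenomicRegion(
            feature.seqid,
            feature.start - 1,  # GTF 1-based closed -> 0-based half-open
            feature.end,
            feature.strand if feature.strand in ("+", "-") else ".",
        )
        if feature.featuretype == "gene":
            gene_id = _attr(feature, "gene_id")
            if gene_id is None:
                raise ValueError(f"gene feature without gene_id at {feature.seqid}:{feature.start}")
            biotype = _attr(feature, "gene_biotype") or _attr(feature, "gene_type") or "unknown"
            model.genes[gene_id] = Gene(gene_id, biotype, region, region.strand)
        elif feature.featuretype == "transcript":
            transcript_id = _attr(feature, "transcript_id")
            gene_id = _attr(feature, "gene_id")
            if transcript_id is None or gene_id is None:
                raise ValueError(
                    f"transcript feature missing transcript_id/gene_id at "
                    f"{feature.seqid}:{feature.start}"
                )
            tsl = _parse_tsl(_attr(feature, "transcript_support_level"))
            model.transcripts[transcript_id] = Transcript(transcript_id, gene_id, region.strand, tsl)
            model._gene_transcripts.setdefault(gene_id, []).append(transcript_id)
        elif feature.featuretype in _CHILD_TYPES:
            transcript_id = _attr(feature, "transcript_id")
            if transcript_id is None:
                raise ValueError(
                    f"{feature.featuretype} without parent transcript at "
                    f"{feature.seqid}:{feature.start}"
                )
            model.add_child(transcript_id, feature.featuretype, region)
    # structural check: every child belongs to a declared transcript, every
    # transcript to a declared gene
    for (transcript_id, ftype) in model._children:
        if transcript_id not in model.transcripts:
            raise ValueError(f"{ftype} references undeclared transcript {transcript_id!r}")
    for transcript in model.transcripts.values():
        if transcript.gene_id not in model.genes:
            raise ValueError(
                f"transcript {transcript.id!r} references undeclared gene {transcript.gene_id!r}"
            )
    return model
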