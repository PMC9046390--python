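"""Seeded synthetic fixtures: toy genomes, annotations, coverage and truth.

Every generator draws from its own named pseudo-random stream derived from a
single integer seed, so adding a generator never perturbs the output of
another and identical (seed, spec) pairs produce byte-identical files.

The training fixture plants the class contrasts the classifier is expected
to learn: true 3'UTRs receive a poly(A)-signal hexamer near their 3' end,
smooth read coverage that decays towards the distal boundary (high entropy
efficiency, high boundary percentage difference) and low conservation;
internal coding exons get high conservation and spiky, boundary-symmetric
coverage; lncRNAs are deliberately the most 3'UTR-like negative class
(occasional PAS, ramped but noisy coverage, low conservation), mirroring
the observation that 3'UTRs overlap most with lncRNAs in feature space.
A ``hard_mode`` flag weakens the planted contrasts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import write_bedgraph
from .features import STRUCTURAL_PROPERTIES, BASES, ConversionTable
from .genome import reverse_complement, write_fasta
from .regions import GenomicRegion, write_regions

CLASS_LABELS = ("THREE_UTR", "FIVE_UTR", "ICE", "LNCRNA", "NCRNA", "PSEUDOGENE")

#: conservation level planted per class (before noise)
_CONSERVATION = {
    "THREE_UTR": 0.15,
    "FIVE_UTR": 0.75,
    "ICE": 0.90,
    "LNCRNA": 0.20,
    "NCRNA": 0.50,
    "PSEUDOGENE": 0.45,
    "ER_TRUE": 0.15,
    "ER_NOISE": 0.40,
    "LNCRNA_MIMIC": 0.15,  # hard-mode lncRNAs indistinguishable from 3'UTRs
}

#: classes whose coverage ramps down towards the distal end (3'UTR-like)
_RAMPED = {"THREE_UTR", "LNCRNA", "ER_TRUE", "LNCRNA_MIMIC"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted toy dataset."""

    seed: int = 0
    chrom: str = "chr1"
    min_chrom_length: int = 50_000
    gc: float = 0.45
    n_tissues: int = 2
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {label: 50 for label in CLASS_LABELS}
    )
    pas_probability: float = 0.95
    lnc_pas_probability: float = 0.40
    hard_mode: bool = False
    n_er_true: int = 0
    n_er_noise: int = 0
    er_junction_fraction: float = 0.3

    def with_(self, **kwargs) -> "FixtureSpec":
        return replace(self, **kwargs)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One named, independent pseudo-random stream per generator."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(list("ACGT"), size=length, p=probs)


# ---------------------------------------------------------------------------
# genome


def generate_genome(spec: FixtureSpec, path: str | Path) -> Path:
    """Write a deterministic random single-chromosome FASTA."""
    if spec.min_chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    rng = _rng(spec.seed, "genome")
    seq = "".join(_random_bases(rng, spec.min_chrom_length, spec.gc))
    write_fasta({spec.chrom: seq}, path)
    return Path(path)


# ---------------------------------------------------------------------------
# structural-property tables


def synthetic_structural_tables(seed: int = 1903) -> dict[str, ConversionTable]:
    """Deterministic synthetic stand-in conversion tables (16 properties).

    The values are synthetic placeholders drawn once from a fixed stream,
    not laboratory-derived structural scales; real analyses should load the
    published tables via :func:`utr3pred.features.load_conversion_tables`.
    """
    import itertools

    tables: dict[str, ConversionTable] = {}
    for name, k in STRUCTURAL_PROPERTIES.items():
        rng = _rng(seed, f"structural/{name}")
        kmers = ["".join(t) for t in itertools.product(BASES, repeat=k)]
        values = rng.normal(loc=0.0, scale=1.0, size=len(kmers)).round(4)
        tables[name] = ConversionTable(name, k, dict(zip(kmers, values)))
    return tables


def write_structural_tables(tables: Mapping[str, ConversionTable], path: str | Path) -> Path:
    rows = []
    for name in sorted(tables):
        table = tables[name]
        for kmer in sorted(table.mapping):
            rows.append((name, kmer, table.mapping[kmer]))
    with open(path, "w") as handle:
        for name, kmer, value in rows:
            handle.write(f"{name}\t{kmer}\t{value:g}\n")
    return Path(path)


# ---------------------------------------------------------------------------
# training fixture


@dataclass
class TrainingFixture:
    """File paths and truth tables of one generated training dataset."""

    spec: FixtureSpec
    genome: Path
    gtf: Path
    truth: pd.DataFrame  # element_id, chrom, start, end, strand, label, gene_id
    coverage: dict[str, Path]  # tissue label -> bedGraph
    conservation: Path
    repeats: Path
    structural_tables: Path
    chrom_length: int
    er_bed: Path | None = None
    er_truth: pd.DataFrame | None = None  # er_id, start, end, is_utr3, gene_id
    er_junctions: Path | None = None
    er_expression: Path | None = None

    @property
    def tissues(self) -> list[str]:
        return sorted(self.coverage)


def _gtf_line(chrom, source, ftype, start, end, strand, attrs: dict[str, str]) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    # internal 0-based half-open -> GTF 1-based closed
    return f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_str}\n"


def generate_training_fixture(spec: FixtureSpec, outdir: str | Path) -> TrainingFixture:
    """Generate a toy genome + GTF + tracks with planted class contrasts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = _rng(spec.seed, "layout")
    counts = dict(spec.class_counts)
    for label in CLASS_LABELS:
        counts.setdefault(label, 0)
    n_utr3, n_utr5, n_ice = counts["THREE_UTR"], counts["FIVE_UTR"], counts["ICE"]
    n_pc = max(n_utr3, n_utr5, n_ice, spec.n_er_true, spec.n_er_noise)

    gtf_lines: list[str] = []
    truth_rows: list[dict] = []
    # elements carry (region, kind) where kind is a class label or ER_TRUE/ER_NOISE
    elements: list[tuple[GenomicRegion, str, str]] = []  # region, kind, gene_id
    er_rows: list[dict] = []
    pas_sites: list[tuple[int, str]] = []  # (genomic position of motif start, strand)
    repeat_rows: list[GenomicRegion] = []
    free_gaps: list[tuple[int, int]] = []

    cursor = 1000

    def add_truth(region: GenomicRegion, label: str, gene_id: str) -> None:
        truth_rows.append(
            {
                "element_id": region.id,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "strand": region.strand,
                "label": label,
                "gene_id": gene_id,
            }
        )

    # --- protein-coding genes -------------------------------------------
    for i in range(n_pc):
        gene_id = f"pcg{i:04d}"
        tx_id = f"{gene_id}.t1"
        hosts_er = i < max(spec.n_er_true, spec.n_er_noise)
        strand = "+" if (hosts_er or i % 2 == 0) else "-"
        has_u5 = i < n_utr5
        has_u3 = i < n_utr3
        n_cds = 3 if i < n_ice else 2

        # transcription-ordered element lengths
        parts: list[tuple[str, int]] = []
        if has_u5:
            parts.append(("five_prime_utr", int(layout.integers(60, 140))))
        for _ in range(n_cds):
            parts.append(("CDS", int(layout.integers(90, 180))))
        if has_u3:
            parts.append(("three_prime_utr", int(layout.integers(150, 400))))

        if strand == "-":  # genomic left-to-right order
            genomic_parts = list(reversed(parts))
        else:
            genomic_parts = parts

        intervals: list[tuple[str, int, int]] = []
        pos = cursor
        for j, (kind, length) in enumerate(genomic_parts):
            intervals.append((kind, pos, pos + length))
            pos += length
            if j < len(genomic_parts) - 1:
                pos += int(layout.integers(80, 300))
        gene_start, gene_end = cursor, pos

        gtf_lines.append(
            _gtf_line(
                spec.chrom, "fixture", "gene", gene_start, gene_end, strand,
                {"gene_id": gene_id, "gene_biotype": "protein_coding"},
            )
        )
        gtf_lines.append(
            _gtf_line(
                spec.chrom, "fixture", "transcript", gene_start, gene_end, strand,
                {
                    "gene_id": gene_id,
                    "transcript_id": tx_id,
                    "gene_biotype": "protein_coding",
                    "transcript_support_level": "1",
                },
            )
        )
        cds_intervals = [iv for iv in intervals if iv[0] == "CDS"]
        cds_tx_order = list(reversed(cds_intervals)) if strand == "-" else cds_intervals
        for kind, start, end in intervals:
            attrs = {"gene_id": gene_id, "transcript_id": tx_id}
            gtf_lines.append(_gtf_line(spec.chrom, "fixture", "exon", start, end, strand, attrs))
            if kind != "exon":
                gtf_lines.append(_gtf_line(spec.chrom, "fixture", kind, start, end, strand, attrs))
            if kind == "three_prime_utr":
                region = GenomicRegion(spec.chrom, start, end, strand, f"{gene_id}.utr3")
                elements.append((region, "THREE_UTR", gene_id))
                add_truth(region, "THREE_UTR", gene_id)
            elif kind == "five_prime_utr":
                region = GenomicRegion(spec.chrom, start, end, strand, f"{gene_id}.utr5")
                elements.append((region, "FIVE_UTR", gene_id))
                add_truth(region, "FIVE_UTR", gene_id)
        if n_cds >= 3:
            # internal coding exons: all but the first and last in
            # transcription order
            for k, (_, start, end) in enumerate(cds_tx_order[1:-1], start=2):
                region = GenomicRegion(spec.chrom, start, end, strand, f"{gene_id}.ice{k}")
                elements.append((region, "ICE", gene_id))
                add_truth(region, "ICE", gene_id)

        cursor = gene_end

        # --- expressed regions downstream of this gene (plus strand only:
        # ER-hosting genes are forced to "+" above)
        if hosts_er:
            if i < spec.n_er_true:
                er_len = int(layout.integers(120, 900))
                gap = int(layout.integers(150, 2500))
                er_start = gene_end + gap
                er = GenomicRegion(spec.chrom, er_start, er_start + er_len, ".", f"er_true{i:04d}")
                elements.append((er, "ER_TRUE", gene_id))
                er_rows.append(
                    {
                        "er_id": er.id, "chrom": er.chrom, "start": er.start, "end": er.end,
                        "is_utr3": True, "gene_id": gene_id,
                    }
                )
                cursor = er.end
            if i < spec.n_er_noise:
                er_len = int(layout.integers(120, 900))
                gap = int(layout.integers(400, 1500))
                er_start = cursor + gap
                er = GenomicRegion(spec.chrom, er_start, er_start + er_len, ".", f"er_noise{i:04d}")
                elements.append((er, "ER_NOISE", gene_id))
                er_rows.append(
                    {
                        "er_id": er.id, "chrom": er.chrom, "start": er.start, "end": er.end,
                        "is_utr3": False, "gene_id": gene_id,
                    }
                )
                cursor = er.end

        # ER-hosting genes get a wide downstream gap so the host gene stays
        # the nearest expressed gene for every ER it owns
        gap = int(layout.integers(6500, 9000)) if hosts_er else int(layout.integers(2500, 5000))
        free_gaps.append((cursor + 200, cursor + gap - 200))
        cursor += gap

    # --- non-coding gene classes ----------------------------------------
    noncoding = [
        ("LNCRNA", "lincRNA", counts["LNCRNA"], (150, 400)),
        ("NCRNA", "miRNA", counts["NCRNA"], (60, 160)),
        ("PSEUDOGENE", "processed_pseudogene", counts["PSEUDOGENE"], (150, 350)),
    ]
    mimic_rng = _rng(spec.seed, "mimic")
    for label, biotype, n_genes, (lo, hi) in noncoding:
        for i in range(n_genes):
            gene_id = f"{label.lower()}{i:04d}"
            tx_id = f"{gene_id}.t1"
            # in hard mode, half of the lncRNAs are planted feature-identical
            # to 3'UTRs, mirroring real feature-space overlap of the classes
            kind = label
            if label == "LNCRNA" and spec.hard_mode and mimic_rng.random() < 0.5:
                kind = "LNCRNA_MIMIC"
            strand = "+" if i % 2 == 0 else "-"
            length = int(layout.integers(lo, hi))
            start, end = cursor, cursor + length
            attrs_gene = {"gene_id": gene_id, "gene_biotype": biotype}
            gtf_lines.append(_gtf_line(spec.chrom, "fixture", "gene", start, end, strand, attrs_gene))
            gtf_lines.append(
                _gtf_line(
                    spec.chrom, "fixture", "transcript", start, end, strand,
                    {**attrs_gene, "transcript_id": tx_id, "transcript_support_level": "1"},
                )
            )
            gtf_lines.append(
                _gtf_line(
                    spec.chrom, "fixture", "exon", start, end, strand,
                    {"gene_id": gene_id, "transcript_id": tx_id},
                )
            )
            region = GenomicRegion(spec.chrom, start, end, strand, f"{gene_id}.exon")
            elements.append((region, kind, gene_id))
            add_truth(region, label, gene_id)
            if label == "PSEUDOGENE":
                # transposon-derived: cover ~60% of the exon with a LINE
                repeat_rows.append(
                    GenomicRegion(spec.chrom, start, start + int(0.6 * length), ".", "LINE")
                )
            gap = int(layout.integers(600, 1200))
            cursor = end + gap

    chrom_length = max(spec.min_chrom_length, cursor + 2000)

    # --- genome sequence with planted PAS hexamers ----------------------
    seq_rng = _rng(spec.seed, "sequence")
    seq = _random_bases(seq_rng, chrom_length, spec.gc)
    pas_rng = _rng(spec.seed, "pas")
    pas_prob = spec.pas_probability if not spec.hard_mode else 0.7
    lnc_prob = spec.lnc_pas_probability
    for region, kind, _gene in elements:
        if kind in ("THREE_UTR", "ER_TRUE", "LNCRNA_MIMIC"):
            plant = pas_rng.random() < pas_prob
        elif kind == "LNCRNA":
            plant = pas_rng.random() < lnc_prob
        else:
            continue
        if not plant:
            continue
        strand = region.strand if region.strand != "." else "+"
        if strand == "+":
            pos = region.end - 26
            seq[pos : pos + 6] = list("AATAAA")
        else:
            pos = region.start + 20
            seq[pos : pos + 6] = list(reverse_complement("AATAAA"))
        pas_sites.append((pos, strand))

    genome_path = outdir / "genome.fa"
    write_fasta({spec.chrom: "".join(seq)}, genome_path)

    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text("".join(gtf_lines))

    # --- conservation ----------------------------------------------------
    cons_rng = _rng(spec.seed, "conservation")
    cons_rows: list[tuple[str, int, int, float]] = []
    for region, kind, _gene in elements:
        base = _CONSERVATION[kind]
        noise_sd = 0.05 if not spec.hard_mode else 0.15
        values = np.clip(cons_rng.normal(base, noise_sd, region.length), 0.0, 1.0).round(3)
        for offset, value in enumerate(values):
            cons_rows.append((region.chrom, region.start + offset, region.start + offset + 1, float(value)))
    conservation_path = outdir / "conservation.bedgraph"
    write_bedgraph(cons_rows, conservation_path)

    # --- repeats ----------------------------------------------------------
    rep_rng = _rng(spec.seed, "repeats")
    for gap_start, gap_end in free_gaps[:15]:
        if gap_end - gap_start < 400:
            continue
        rep_len = int(rep_rng.integers(100, 300))
        rep_start = int(rep_rng.integers(gap_start, gap_end - rep_len))
        family = ["SINE", "LINE", "LTR"][int(rep_rng.integers(0, 3))]
        repeat_rows.append(GenomicRegion(spec.chrom, rep_start, rep_start + rep_len, ".", family))
    repeats_path = outdir / "repeats.bed"
    write_regions(repeat_rows, repeats_path)

    # --- coverage per tissue ---------------------------------------------
    coverage_paths: dict[str, Path] = {}
    for t in range(spec.n_tissues):
        tissue = f"tissue{t + 1:02d}"
        cov_rng = _rng(spec.seed, f"coverage/{tissue}")
        rows: list[tuple[str, int, int, float]] = []
        for region, kind, _gene in elements:
            depth = float(cov_rng.uniform(30, 80))
            length = region.length
            if kind in _RAMPED:
                # smooth decay towards the distal (3') boundary
                floor = 0.04 if not spec.hard_mode else 0.3
                values = np.linspace(depth, depth * floor, length)
                strand = region.strand if region.strand != "." else "+"
                if strand == "-":
                    values = values[::-1]
                if kind == "LNCRNA":
                    values = values * cov_rng.lognormal(0.0, 0.4, length)
            else:
                # spiky coverage confined to the interior; boundaries at 0
                values = np.zeros(length)
                a, b = int(0.3 * length), max(int(0.3 * length) + 2, int(0.75 * length))
                values[a:b] = depth * cov_rng.exponential(1.0, b - a)
            values = np.round(np.maximum(values, 0.0), 3)
            for offset, value in enumerate(values):
                rows.append((region.chrom, region.start + offset, region.start + offset + 1, float(value)))
        path = outdir / f"coverage_{tissue}.bedgraph"
        write_bedgraph(rows, path)
        coverage_paths[tissue] = path

    # --- structural tables ------------------------------------------------
    tables_path = write_structural_tables(synthetic_structural_tables(), outdir / "structural_tables.tsv")

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    er_bed = er_truth = er_junctions = er_expression = None
    if er_rows:
        er_truth = pd.DataFrame(er_rows)
        er_truth.to_csv(outdir / "er_truth.tsv", sep="\t", index=False)
        er_bed = outdir / "ers.bed"
        write_regions(
            [GenomicRegion(r["chrom"], r["start"], r["end"], ".", r["er_id"]) for r in er_rows],
            er_bed,
        )
        junction_rng = _rng(spec.seed, "junctions")
        junction_rows = [
            (r["er_id"], r["gene_id"])
            for r in er_rows
            if junction_rng.random() < spec.er_junction_fraction
        ]
        er_junctions = outdir / "er_junctions.tsv"
        with open(er_junctions, "w") as handle:
            for er_id, gene_id in junction_rows:
                handle.write(f"{er_id}\t{gene_id}\n")
        er_expression = outdir / "gene_expression.tsv"
        with open(er_expression, "w") as handle:
            for t in range(spec.n_tissues):
                tissue = f"tissue{t + 1:02d}"
                for i in range(n_pc):
                    handle.write(f"pcg{i:04d}\t{tissue}\t5.0\n")

    return TrainingFixture(
        spec=spec,
        genome=genome_path,
        gtf=gtf_path,
        truth=truth,
        coverage=coverage_paths,
        conservation=conservation_path,
        repeats=repeats_path,
        structural_tables=tables_path,
        chrom_length=chrom_length,
        er_bed=er_bed,
        er_truth=er_truth,
        er_junctions=er_junctions,
        er_expression=er_expression,
    )


# ---------------------------------------------------------------------------
# multi-tissue expressed-region sets with known tissue-specificity


DEFAULT_BRAIN_TISSUES = (
    "brain_cortex", "brain_cerebellum", "brain_hippocampus", "brain_striatum",
)
DEFAULT_NONBRAIN_TISSUES = ("liver", "lung", "heart", "kidney")


@dataclass
class MultiTissueFixture:
    beds: dict[str, Path]  # tissue -> BED path
    truth: pd.DataFrame  # er_group, category
    brain_tissues: tuple[str, ...]
    tissues: tuple[str, ...]


def generate_multitissue_er_sets(
    spec: FixtureSpec,
    outdir: str | Path,
    n_per_category: int = 5,
    brain_tissues: tuple[str, ...] = DEFAULT_BRAIN_TISSUES,
    nonbrain_tissues: tuple[str, ...] = DEFAULT_NONBRAIN_TISSUES,
) -> MultiTissueFixture:
    """Per-tissue ER BEDs planted to land in each tissue-specificity category.

    absolute_tissue_specific: present in exactly one tissue; no overlap.
    highly_brain_specific: overlapping copies in 4 tissues, all brain.
    shared: copies in 6 tissues (3 brain), boundary jitter <= 10 nt.
    ambiguous: copies in 4 tissues (2 brain) -- neither brain-dominated nor
    detected widely enough to be shared.
    """
    tissues = tuple(brain_tissues) + tuple(nonbrain_tissues)
    if len(tissues) < 6:
        raise ValueError("need at least 6 tissues with a brain/non-brain labelling")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec.seed, "multitissue")
    per_tissue: dict[str, list[GenomicRegion]] = {t: [] for t in tissues}
    truth_rows = []
    slot = 1000
    base_len = 300

    def place(group: str, category: str, detecting: list[str], jitter_max: int) -> None:
        nonlocal slot
        start, end = slot, slot + base_len
        for tissue in detecting:
            j1 = int(rng.integers(0, jitter_max + 1))
            j2 = int(rng.integers(0, jitter_max + 1))
            per_tissue[tissue].append(
                GenomicRegion(spec.chrom, start + j1, end + j2, ".", group)
            )
        truth_rows.append({"er_group": group, "category": category})
        slot += 3000

    for i in range(n_per_category):
        place(f"abs{i:03d}", "absolute_tissue_specific", [tissues[i % len(tissues)]], 0)
    for i in range(n_per_category):
        place(f"brain{i:03d}", "highly_brain_specific", list(brain_tissues[:4]), 3)
    for i in range(n_per_category):
        detecting = list(brain_tissues[:3]) + list(nonbrain_tissues[:3])
        place(f"shared{i:03d}", "shared", detecting, 5)
    for i in range(n_per_category):
        detecting = list(brain_tissues[:2]) + list(nonbrain_tissues[:2])
        place(f"ambig{i:03d}", "ambiguous", detecting, 3)

    beds: dict[str, Path] = {}
    for tissue in tissues:
        path = outdir / f"ers_{tissue}.bed"
        write_regions(per_tissue[tissue], path)
        beds[tissue] = path
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "category_truth.tsv", sep="\t", index=False)
    return MultiTissueFixture(beds, truth, tuple(brain_tissues), tissues)


# ---------------------------------------------------------------------------
# poly(A) clusters


def generate_polya_clusters(
    spec: FixtureSpec,
    true_3utrs: list[GenomicRegion],
    path: str | Path,
    chrom_length: int,
    offset: int = 0,
    n_decoys: int = 10,
    cluster_halfwidth: int = 10,
) -> list[GenomicRegion]:
    """One cluster at the distal end of each true 3'UTR plus random decoys."""
    rng = _rng(spec.seed, "polya")
    clusters: list[GenomicRegion] = []
    for i, region in enumerate(true_3utrs):
        distal = region.start if region.strand == "-" else region.end
        start = max(0, distal - cluster_halfwidth + offset)
        end = min(chrom_length, distal + cluster_halfwidth + offset)
        clusters.append(GenomicRegion(region.chrom, start, end, ".", f"pa{i:04d}"))
    placed = 0
    attempts = 0
    while placed < n_decoys and attempts < 10_000:
        attempts += 1
        start = int(rng.integers(0, chrom_length - 2 * cluster_halfwidth))
        decoy = GenomicRegion(spec.chrom, start, start + 2 * cluster_halfwidth, ".", f"decoy{placed:04d}")
        if any(decoy.overlaps(r) for r in true_3utrs) or any(decoy.overlaps(c) for c in clusters):
            continue
        clusters.append(decoy)
        placed += 1
    write_regions(clusters, path)
    return clusters
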