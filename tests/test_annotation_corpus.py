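"""GTF parsing and training-corpus assembly (TSL filter, meta-transcripts,
internal coding exons, length threshold)."""

import textwrap

import pytest

from utr3pred.annotation import read_annotation
from utr3pred.corpus import (
    MIN_EXAMPLE_LENGTH,
    build_meta_transcript,
    extract_class_regions,
    extract_ice_regions,
    filter_expressed_known_utrs,
    select_tsl1_transcripts,
)
from utr3pred.coverage import CoverageTrack
from utr3pred.regions import GenomicRegion


def _gtf(tmp_path, body: str):
    path = tmp_path / "a.gtf"
    path.write_text(textwrap.dedent(body).lstrip())
    return path


@pytest.fixture()
def small_annotation(tmp_path):
    """Two genes: a plus-strand coding gene with two TSL-1 transcripts and a
    minus-strand coding gene with three CDS exons."""
    path = _gtf(
        tmp_path,
        """
        chr1\tx\tgene\t1001\t3000\t.\t+\t.\tgene_id "gA"; gene_biotype "protein_coding";
        chr1\tx\ttranscript\t1001\t3000\t.\t+\t.\tgene_id "gA"; transcript_id "tA1"; transcript_support_level "1";
        chr1\tx\texon\t1001\t1100\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
        chr1\tx\tthree_prime_utr\t1001\t1100\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
        chr1\tx\ttranscript\t1001\t3000\t.\t+\t.\tgene_id "gA"; transcript_id "tA2"; transcript_support_level "1";
        chr1\tx\texon\t1051\t1250\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
        chr1\tx\tthree_prime_utr\t1051\t1250\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
        chr1\tx\ttranscript\t2001\t3000\t.\t+\t.\tgene_id "gA"; transcript_id "tA3"; transcript_support_level "2";
        chr1\tx\texon\t2001\t3000\t.\t+\t.\tgene_id "gA"; transcript_id "tA3";
        chr1\tx\tgene\t5001\t6000\t.\t-\t.\tgene_id "gB"; gene_biotype "protein_coding";
        chr1\tx\ttranscript\t5001\t6000\t.\t-\t.\tgene_id "gB"; transcript_id "tB1"; transcript_support_level "1";
        chr1\tx\texon\t5001\t5100\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
        chr1\tx\tCDS\t5001\t5100\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
        chr1\tx\texon\t5301\t5400\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
        chr1\tx\tCDS\t5301\t5400\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
        chr1\tx\texon\t5801\t6000\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
        chr1\tx\tCDS\t5801\t6000\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
        chr1\tx\ttranscript\t5001\t6000\t.\t-\t.\tgene_id "gB"; transcript_id "tB2";
        chr1\tx\texon\t5001\t6000\t.\t-\t.\tgene_id "gB"; transcript_id "tB2";
        """,
    )
    return read_annotation(path)


class TestAnnotationParsing:
    def test_coordinate_convention_and_structure(self, small_annotation):
        ann = small_annotation
        assert len(ann.genes) == 2
        # GTF "1001 1100" becomes internal (1000, 1100)
        utr = ann.utr3("tA1")[0]
        assert (utr.start, utr.end) == (1000, 1100)
        assert len(ann.exons("tB1")) == 3

    def test_missing_tsl_is_missing_not_one(self, small_annotation):
        assert small_annotation.transcripts["tB2"].tsl is None
        assert small_annotation.transcripts["tA3"].tsl == 2

    def test_orphan_exon_is_an_error(self, tmp_path):
        path = _gtf(
            tmp_path,
            """
            chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "g"; gene_biotype "protein_coding";
            chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "ghost";
            """,
        )
        with pytest.raises(ValueError, match="ghost"):
            read_annotation(path)


class TestTSLAndMetaTranscript:
    def test_tsl1_only(self, small_annotation):
        selected = {t.id for t in select_tsl1_transcripts(small_annotation)}
        assert selected == {"tA1", "tA2", "tB1"}

    def test_overlapping_utrs_merge(self, small_annotation):
        ann = small_annotation
        tx = [ann.transcripts["tA1"], ann.transcripts["tA2"]]
        merged = build_meta_transcript(ann, tx, "three_prime_utr")
        assert [(r.start, r.end, r.strand) for r in merged] == [(1000, 1250, "+")]

    def test_disjoint_exons_kept_separate(self, small_annotation):
        ann = small_annotation
        merged = build_meta_transcript(ann, [ann.transcripts["tB1"]], "exon")
        assert len(merged) == 3

    def test_union_matches_per_base_oracle(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(42)
        lines = ['chr1\tx\tgene\t1\t5000\t.\t+\t.\tgene_id "g"; gene_biotype "protein_coding";']
        base_sets = []
        for t in range(5):
            lines.append(
                f'chr1\tx\ttranscript\t1\t5000\t.\t+\t.\tgene_id "g"; '
                f'transcript_id "t{t}"; transcript_support_level "1";'
            )
            for _ in range(rng.integers(1, 4)):
                start = int(rng.integers(0, 4000))
                end = start + int(rng.integers(50, 400))
                base_sets.append(set(range(start, end)))
                lines.append(
                    f'chr1\tx\texon\t{start + 1}\t{end}\t.\t+\t.\t'
                    f'gene_id "g"; transcript_id "t{t}";'
                )
        path = tmp_path / "rand.gtf"
        path.write_text("\n".join(lines) + "\n")
        ann = read_annotation(path)
        merged = build_meta_transcript(ann, list(ann.transcripts.values()), "exon")
        merged_bases = set()
        for r in merged:
            merged_bases |= set(range(r.start, r.end))
        assert merged_bases == set().union(*base_sets)


class TestICEExtraction:
    def test_minus_strand_removes_terminal_exons_in_transcription_order(self, small_annotation):
        ann = small_annotation
        # tB1 (minus strand): transcription order is (5800,6000), (5300,5400),
        # (5000,5100); only the genomic-middle exon is internal
        ices = extract_ice_regions(ann, [ann.transcripts["tB1"]])
        assert [(r.start, r.end) for r in ices] == [(5300, 5400)]

    def test_two_cds_exons_contribute_nothing(self, tmp_path):
        path = _gtf(
            tmp_path,
            """
            chr1\tx\tgene\t1\t1000\t.\t+\t.\tgene_id "g"; gene_biotype "protein_coding";
            chr1\tx\ttranscript\t1\t1000\t.\t+\t.\tgene_id "g"; transcript_id "t"; transcript_support_level "1";
            chr1\tx\tCDS\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";
            chr1\tx\tCDS\t201\t300\t.\t+\t.\tgene_id "g"; transcript_id "t";
            """,
        )
        ann = read_annotation(path)
        assert extract_ice_regions(ann, [ann.transcripts["t"]]) == []

    def test_ices_never_touch_terminal_cds(self, training_fixture):
        ann = read_annotation(training_fixture.gtf)
        for gene_id, gene in ann.genes.items():
            if gene.biotype != "protein_coding":
                continue
            transcripts = ann.transcripts_of(gene_id)
            ices = extract_ice_regions(ann, transcripts)
            cds_bases = set()
            terminal_bases = set()
            for tx in transcripts:
                ordered = ann.cds_in_transcription_order(tx.id)
                for r in ordered:
                    cds_bases |= set(range(r.start, r.end))
                if ordered:
                    for r in (ordered[0], ordered[-1]):
                        terminal_bases |= set(range(r.start, r.end))
            for ice in ices:
                bases = set(range(ice.start, ice.end))
                assert bases <= cds_bases
                assert not bases & terminal_bases


class TestClassExtraction:
    def test_width_threshold_boundary(self, tmp_path):
        path = _gtf(
            tmp_path,
            f"""
            chr1\tx\tgene\t1\t2000\t.\t+\t.\tgene_id "g39"; gene_biotype "lincRNA";
            chr1\tx\ttranscript\t1\t2000\t.\t+\t.\tgene_id "g39"; transcript_id "t39"; transcript_support_level "1";
            chr1\tx\texon\t1\t{MIN_EXAMPLE_LENGTH - 1}\t.\t+\t.\tgene_id "g39"; transcript_id "t39";
            chr1\tx\tgene\t3001\t5000\t.\t+\t.\tgene_id "g40"; gene_biotype "lincRNA";
            chr1\tx\ttranscript\t3001\t5000\t.\t+\t.\tgene_id "g40"; transcript_id "t40"; transcript_support_level "1";
            chr1\tx\texon\t3001\t{3000 + MIN_EXAMPLE_LENGTH}\t.\t+\t.\tgene_id "g40"; transcript_id "t40";
            """,
        )
        examples = extract_class_regions(read_annotation(path))
        assert [e.gene_id for e in examples] == ["g40"]
        assert examples[0].label == "LNCRNA"
        assert examples[0].region.length == MIN_EXAMPLE_LENGTH

    def test_unknown_biotype_skipped(self, tmp_path):
        path = _gtf(
            tmp_path,
            """
            chr1\tx\tgene\t1\t500\t.\t+\t.\tgene_id "g"; gene_biotype "TEC";
            chr1\tx\ttranscript\t1\t500\t.\t+\t.\tgene_id "g"; transcript_id "t"; transcript_support_level "1";
            chr1\tx\texon\t1\t500\t.\t+\t.\tgene_id "g"; transcript_id "t";
            """,
        )
        assert extract_class_regions(read_annotation(path)) == []

    def test_fixture_truth_reproduced_exactly(self, training_fixture):
        ann = read_annotation(training_fixture.gtf)
        examples = extract_class_regions(ann)
        extracted = {(e.region.start, e.region.end, e.label) for e in examples}
        truth = {
            (r.start, r.end, r.label) for r in training_fixture.truth.itertuples()
        }
        assert extracted == truth
        assert all(e.region.length >= MIN_EXAMPLE_LENGTH for e in examples)
        # (region, label) pairs are unique
        keys = [(e.region.chrom, e.region.start, e.region.end, e.label) for e in examples]
        assert len(keys) == len(set(keys))


class TestExpressedUTRFilter:
    def _track(self, label, depth):
        return CoverageTrack.from_intervals(label, [("chr1", 0, 100, depth)])

    def test_mean_depth_boundary(self):
        utr = GenomicRegion("chr1", 10, 60, "+", "u")
        kept = filter_expressed_known_utrs([utr], [self._track("a", 5.0)])
        removed = filter_expressed_known_utrs([utr], [self._track("a", 4.9)])
        assert bool(kept["kept"].iloc[0])
        assert not bool(removed["kept"].iloc[0])

    def test_specificity_grouping(self):
        utr = GenomicRegion("chr1", 10, 60, "+", "u")
        brain = {"b1", "b2", "b3", "b4"}
        # expressed only in one tissue
        one = filter_expressed_known_utrs(
            [utr], [self._track("b1", 9.0), self._track("liver", 0.0)], brain
        )
        assert one["group"].iloc[0] == "absolute_tissue_specific"
        # 4/4 expressing tissues are brain
        brainy = filter_expressed_known_utrs(
            [utr],
            [self._track(t, 9.0) for t in ["b1", "b2", "b3", "b4"]]
            + [self._track("liver", 0.0)],
            brain,
        )
        assert brainy["group"].iloc[0] == "highly_brain_specific"
        # 5 expressing tissues, 3/5 brain
        shared = filter_expressed_known_utrs(
            [utr],
            [self._track(t, 9.0) for t in ["b1", "b2", "b3", "liver", "lung"]],
            brain,
        )
        assert shared["group"].iloc[0] == "shared"
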