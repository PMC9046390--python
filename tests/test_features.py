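"""The 41-feature vector: PAS PWM scanning, composition, conservation,
transposons, structural properties, entropy efficiency and boundary
percentage difference."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utr3pred.coverage import CoverageTrack
from utr3pred.features import (
    BASES,
    FEATURE_NAMES,
    PAS_HEXAMERS,
    ConversionTable,
    build_pas_pwm,
    entropy_efficiency,
    extract_features,
    mean_conservation,
    nucleotide_frequencies,
    percentage_difference,
    scan_pas,
    structural_properties,
    transposon_fraction,
)
from utr3pred.genome import reverse_complement
from utr3pred.regions import GenomicRegion

dna = st.text(alphabet="ACGT", min_size=2, max_size=200)


class TestPasPwm:
    def test_twelve_hexamers_and_column_sums(self):
        assert len(PAS_HEXAMERS) == 12
        pwm = build_pas_pwm()
        assert pwm.probabilities.shape == (4, 6)
        assert np.allclose(pwm.probabilities.sum(axis=0), 1.0, atol=1e-9)

    def test_final_position_is_nearly_always_A(self):
        # 11 of the 12 hexamers end in A (counted from the motif list)
        pwm = build_pas_pwm(pseudocount=0.1)
        assert pwm.probabilities[BASES.index("A"), 5] > 0.9

    def test_consensus_achieves_max_score(self):
        pwm = build_pas_pwm()
        best = max(
            ("".join(w) for w in itertools.product(BASES, repeat=6)),
            key=pwm.score,
        )
        assert best == "AATAAA"
        assert pwm.score("AATAAA") == pytest.approx(pwm.max_score)

    def test_zero_pseudocount_uses_finite_sentinel(self):
        pwm = build_pas_pwm(pseudocount=0.0)
        assert np.isfinite(pwm.log_odds).all()
        assert pwm.min_score < -1e5

    def test_rejects_bad_motifs(self):
        with pytest.raises(ValueError):
            build_pas_pwm(["AATAAA"] * 11 + ["AAXAAA"])
        with pytest.raises(ValueError):
            build_pas_pwm(["AATAA"] + ["AATAAA"] * 11)


class TestScanPas:
    def test_planted_and_absent_consensus(self):
        assert scan_pas("CCCAATAAACCC") == 1
        assert scan_pas("CCCCCCCCCCCC") == 0

    def test_short_sequence_reports_zero(self):
        assert scan_pas("ACG") == 0

    def test_agrees_with_brute_force_over_all_hexamers(self):
        pwm = build_pas_pwm()
        matching = {
            "".join(w)
            for w in itertools.product(BASES, repeat=6)
            if pwm.relative_score("".join(w)) >= pwm.relative_threshold
        }
        for word in itertools.product(BASES, repeat=6):
            hexamer = "".join(word)
            assert scan_pas("CC" + hexamer + "GG", pwm) == int(hexamer in matching)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=60))
    def test_unstranded_scan_is_strand_symmetric(self, seq):
        assert scan_pas(seq, both_strands=True) == scan_pas(
            reverse_complement(seq), both_strands=True
        )


class TestNucleotideFrequencies:
    def test_hand_counts(self):
        f = nucleotide_frequencies("AAAA")
        assert f["freq_A"] == 1.0
        assert f["freq_AA"] == pytest.approx(3 / 4)
        f = nucleotide_frequencies("ACGT")
        assert all(f[f"freq_{b}"] == 0.25 for b in BASES)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dna)
    def test_matches_counting_oracle(self, seq):
        f = nucleotide_frequencies(seq)
        L = len(seq)
        for b in BASES:
            assert f[f"freq_{b}"] == pytest.approx(seq.count(b) / L)
        for a in BASES:
            for b in BASES:
                count = sum(seq[i : i + 2] == a + b for i in range(L - 1))
                assert f[f"freq_{a}{b}"] == pytest.approx(count / L)
        assert sum(f[f"freq_{b}"] for b in BASES) == pytest.approx(1.0)


class TestConservationAndTransposons:
    def test_constant_track(self):
        track = CoverageTrack.from_intervals("c", [("chr1", 0, 100, 0.8)])
        assert mean_conservation(track, GenomicRegion("chr1", 10, 50)) == pytest.approx(0.8)

    def test_gap_counts_as_zero(self):
        track = CoverageTrack.from_intervals("c", [("chr1", 0, 50, 1.0)])
        assert mean_conservation(track, GenomicRegion("chr1", 0, 100)) == pytest.approx(0.5)

    def test_transposon_fraction_merges_and_filters(self):
        region = GenomicRegion("chr1", 0, 100)
        assert transposon_fraction([], region) == 0.0
        line = GenomicRegion("chr1", 0, 200, ".", "LINE")
        assert transposon_fraction([line], region) == 1.0
        # overlapping repeats are not double counted
        reps = [GenomicRegion("chr1", 0, 60, ".", "SINE"), GenomicRegion("chr1", 40, 80, ".", "LINE")]
        assert transposon_fraction(reps, region) == pytest.approx(0.8)
        # non-transposon class excluded when class info present
        assert transposon_fraction([GenomicRegion("chr1", 0, 100, ".", "Simple_repeat")], region) == 0.0


class TestStructuralProperties:
    def test_constant_table(self):
        table = ConversionTable(
            "const", 2, {a + b: 2.5 for a in BASES for b in BASES}
        )
        assert structural_properties("ACGTACGT", {"const": table})["const"] == pytest.approx(2.5)

    def test_hand_computed_mean(self):
        mapping = dict.fromkeys((a + b for a in BASES for b in BASES), 0.0)
        mapping.update({"AC": 1.0, "CG": 2.0, "GT": 3.0})
        table = ConversionTable("toy", 2, mapping)
        assert structural_properties("ACGT", {"toy": table})["toy"] == pytest.approx(2.0)

    def test_incomplete_table_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            ConversionTable("bad", 2, {"AA": 1.0})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=100), st.integers(0, 10_000))
    def test_matches_sliding_window_oracle(self, seq, salt):
        rng = np.random.default_rng(salt)
        for k in (2, 3):
            kmers = ["".join(t) for t in itertools.product(BASES, repeat=k)]
            mapping = dict(zip(kmers, rng.normal(size=len(kmers))))
            table = ConversionTable("p", k, mapping)
            windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
            expected = float(np.mean([mapping[w] for w in windows]))
            got = structural_properties(seq, {"p": table})["p"]
            assert got == pytest.approx(expected)


class TestEntropyEfficiency:
    def test_closed_forms(self):
        assert entropy_efficiency([5, 5, 5, 5]) == pytest.approx(1.0)
        assert entropy_efficiency([0, 0, 9, 0]) == pytest.approx(0.0)
        assert entropy_efficiency([0, 0, 0, 0]) == 0.0
        # EE([1,3]) = -(1/4 log 1/4 + 3/4 log 3/4) / log 2
        expected = -(0.25 * math.log(0.25) + 0.75 * math.log(0.75)) / math.log(2)
        assert entropy_efficiency([1, 3]) == pytest.approx(expected)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_requires_length_two(self):
        with pytest.raises(ValueError):
            entropy_efficiency([5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=50),
        st.floats(0.01, 1000),
    )
    def test_scale_invariant_and_bounded(self, depths, scale):
        ee = entropy_efficiency(depths)
        assert 0.0 <= ee <= 1.0 + 1e-12
        assert entropy_efficiency(np.array(depths) * scale) == pytest.approx(ee, abs=1e-9)


class TestPercentageDifference:
    def test_closed_forms(self):
        assert percentage_difference([7, 1, 9, 7]) == 0.0
        assert percentage_difference([30, 5, 10]) == pytest.approx(100.0)
        assert percentage_difference([0, 3, 8]) == pytest.approx(200.0)
        assert percentage_difference([0, 5, 0]) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=50))
    def test_symmetric_under_reversal_and_bounded(self, depths):
        pd_value = percentage_difference(depths)
        assert 0.0 <= pd_value <= 200.0
        assert percentage_difference(depths[::-1]) == pytest.approx(pd_value)


class TestFullVector:
    def test_exactly_41_named_features(self, training_fixture, loaded_resources):
        assert len(FEATURE_NAMES) == 41
        fx, res = training_fixture, loaded_resources
        row = fx.truth.iloc[0]
        region = GenomicRegion(row.chrom, row.start, row.end, row.strand, row.element_id)
        vector = extract_features(
            region, res["genome"], res["tracks"],
            conservation=res["conservation"], repeats=res["repeats"], tables=res["tables"],
        )
        assert list(vector.index) == list(FEATURE_NAMES)
        assert len(vector) == 41
        assert np.isfinite(vector.to_numpy(dtype=float)).all()

    def test_uniform_coverage_gives_ee1_pd0(self, training_fixture, loaded_resources):
        fx, res = training_fixture, loaded_resources
        row = fx.truth.iloc[0]
        region = GenomicRegion(row.chrom, row.start, row.end, row.strand, row.element_id)
        uniform = CoverageTrack.from_intervals("u", [(region.chrom, 0, fx.chrom_length, 7.0)])
        vector = extract_features(
            region, res["genome"], [uniform],
            conservation=res["conservation"], repeats=res["repeats"], tables=res["tables"],
        )
        assert vector["mean_EE"] == pytest.approx(1.0)
        assert vector["mean_PD"] == pytest.approx(0.0)

    def test_transcriptomic_features_average_across_tracks(self, training_fixture, loaded_resources):
        fx, res = training_fixture, loaded_resources
        row = fx.truth.iloc[0]
        region = GenomicRegion(row.chrom, row.start, row.end, row.strand, row.element_id)
        kwargs = dict(
            conservation=res["conservation"], repeats=res["repeats"], tables=res["tables"]
        )
        singles = [
            extract_features(region, res["genome"], [track], **kwargs)
            for track in res["tracks"]
        ]
        combined = extract_features(region, res["genome"], res["tracks"], **kwargs)
        assert combined["mean_EE"] == pytest.approx(np.mean([s["mean_EE"] for s in singles]))
        assert combined["mean_PD"] == pytest.approx(np.mean([s["mean_PD"] for s in singles]))

    def test_no_tracks_warns_and_zeroes(self, training_fixture, loaded_resources, caplog):
        fx, res = training_fixture, loaded_resources
        row = fx.truth.iloc[0]
        region = GenomicRegion(row.chrom, row.start, row.end, row.strand, row.element_id)
        import logging

        with caplog.at_level(logging.WARNING):
            vector = extract_features(
                region, res["genome"], [],
                conservation=res["conservation"], repeats=res["repeats"], tables=res["tables"],
            )
        assert vector["mean_EE"] == 0.0
        assert vector["mean_PD"] == 0.0
        assert any("coverage" in r.message for r in caplog.records)


class TestPlantedContrasts:
    def test_fixture_contrasts_recoverable(self, feature_matrix):
        """The generator's planted PAS/EE/conservation contrasts between
        3'UTRs and internal coding exons are detectable by rank-sum tests."""
        from scipy.stats import mannwhitneyu

        matrix, labels = feature_matrix
        utr3 = matrix[labels == "THREE_UTR"]
        ice = matrix[labels == "ICE"]
        for column, direction in [
            ("pas_signal", "greater"),
            ("mean_EE", "greater"),
            ("mean_conservation", "less"),
        ]:
            _, p = mannwhitneyu(utr3[column], ice[column], alternative=direction)
            assert p < 0.01, f"{column}: p={p}"
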