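"""Composition statistics: GC, segments, matrices, shuffle and test oracles."""

from collections import Counter
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirsig.composition import (
    compare_distributions,
    dinucleotide_position_frequency,
    dinucleotide_shuffle,
    gc_by_segment,
    gc_content,
    gc_ratio_track,
    position_frequency_matrix,
    random_sample_control,
)
from mirsig.seqio import PrecursorRecord, reverse_complement
from mirsig.signature import OSA_MIR528_5P
from mirsig.synthetic_data import gen_mirnas, gen_precursor, signature_pfm

rna = st.text(alphabet="ACGU", min_size=1, max_size=30)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0),
        ("AUAU", 0.0),
        ("ACGU", 0.5),
    ])
    def test_simple_fractions(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_mature_mir528_is_62_percent(self):
        # monocot miR528-5p: 13 G/C over 21 nt
        assert round(gc_content(OSA_MIR528_5P), 2) == 0.62

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            gc_content("")

    @given(rna)
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_reverse_complement(self, seq):
        assert gc_content(reverse_complement(seq)) == pytest.approx(gc_content(seq))


class TestGcBySegment:
    def test_constructed_precursor_segments(self):
        pre = PrecursorRecord(id="p", sequence="AAAAGGCCUUUUGGCCAAAA",
                              mature5p_span=(5, 8), mature3p_span=(13, 16))
        seg = gc_by_segment(pre)
        assert seg.gc["arm5"] == 0.0
        assert seg.gc["mature5p"] == 1.0
        assert seg.gc["loop"] == 0.0
        assert seg.gc["mature3p"] == 1.0
        assert seg.gc["arm3"] == 0.0
        assert sum(seg.lengths.values()) == pre.length

    def test_empty_loop_reports_undefined_gc_and_full_lengths(self):
        pre = PrecursorRecord(id="p", sequence="GGGGAAAA",
                              mature5p_span=(1, 4), mature3p_span=(5, 8))
        seg = gc_by_segment(pre)
        assert seg.gc["loop"] is None
        assert seg.lengths["loop"] == 0
        assert sum(seg.lengths.values()) == 8

    def test_missing_span_is_an_error(self):
        pre = PrecursorRecord(id="p", sequence="ACGUACGU", mature5p_span=(1, 4))
        with pytest.raises(ValueError):
            gc_by_segment(pre)

    def test_recovers_planted_arm_vs_duplex_gc(self):
        # oracle: the generator's planted parameters (arm 0.30, duplex 0.52)
        rng = np.random.default_rng(7)
        mature = "UGCUUGUCGACUCAUUCGCUC"  # 11/21 GC = 0.524
        mature_gc, arm_gc = [], []
        for _ in range(500):
            pre = gen_precursor(mature, arm_gc=0.30, rng=rng)
            seg = gc_by_segment(pre)
            mature_gc.append(seg.gc["mature5p"])
            arm_gc.append((seg.gc["arm5"] + seg.gc["arm3"]) / 2)
        diff = np.mean(mature_gc) - np.mean(arm_gc)
        assert abs(diff - (0.524 - 0.30)) < 0.02


class TestPositionFrequencyMatrix:
    def test_two_sequence_example(self):
        pfm = position_frequency_matrix(["AU", "GC"])
        df = pfm.to_dataframe().set_index("position")
        assert df.loc[1, "A"] == 0.5 and df.loc[1, "G"] == 0.5
        assert df.loc[2, "U"] == 0.5 and df.loc[2, "C"] == 0.5

    def test_single_sequence_is_one_hot(self):
        pfm = position_frequency_matrix(["AA"])
        assert pfm.freq[0, 0] == 1.0 and pfm.freq[1, 0] == 1.0

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix(["AU", "ACG"])

    def test_columns_sum_to_one(self):
        pfm = position_frequency_matrix(["ACGU", "UGCA", "AAAA"])
        assert np.allclose(pfm.freq.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_planted_matrix_within_sampling_error(self):
        # oracle: binomial sampling bound at n = 10,000
        planted = signature_pfm()
        seqs = gen_mirnas(planted, n=10_000, seed=11)
        est = position_frequency_matrix(seqs)
        assert np.abs(est.freq - planted.freq).max() < 0.02

    def test_abundance_weighting_with_equal_counts_matches_unique(self):
        seqs = ["ACGU", "UGCA", "GGGG"]
        unique = position_frequency_matrix(seqs)
        weighted = position_frequency_matrix(seqs, weighting="abundance",
                                             counts=[5, 5, 5])
        assert np.allclose(unique.freq, weighted.freq)

    def test_abundance_weighting_counts_redundant_reads(self):
        weighted = position_frequency_matrix(["A", "G"], weighting="abundance",
                                             counts=[3, 1])
        assert weighted.freq[0, 0] == pytest.approx(0.75)


class TestGcRatioTrack:
    def test_track_is_g_plus_c(self):
        pfm = position_frequency_matrix(["GA", "CA", "GA", "AA"])
        track = gc_ratio_track(pfm)
        assert track.values[0] == pytest.approx(0.75)
        assert track.values[1] == pytest.approx(0.0)

    def test_au_and_gc_tracks_sum_to_one(self):
        pfm = position_frequency_matrix(["ACGU", "UGCA", "GGAU"])
        track = gc_ratio_track(pfm)
        assert np.allclose(track.values + track.au, 1.0)


class TestDinucleotideFrequency:
    def test_alternating_sequence(self):
        res = dinucleotide_position_frequency(["AUAU"])
        di = dict(zip(
            [a + b for a in "ACGU" for b in "ACGU"], range(16)))
        assert res.freq[0, di["AU"]] == 1.0
        assert res.freq[1, di["UA"]] == 1.0
        assert res.freq[2, di["AU"]] == 1.0

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            dinucleotide_position_frequency([])

    def test_rows_sum_to_one(self):
        res = dinucleotide_position_frequency(["ACGU", "GGCC", "AAUU"])
        assert np.allclose(res.freq.sum(axis=1), 1.0)

    def test_shuffled_set_preserves_pooled_dinucleotide_counts(self):
        # oracle: multiset comparison, position-free
        rng = np.random.default_rng(3)
        seqs = gen_mirnas(signature_pfm(), n=50, seed=4)
        shuffled = [dinucleotide_shuffle(s, rng=rng) for s in seqs]
        orig = Counter(s[i:i + 2] for s in seqs for i in range(len(s) - 1))
        shuf = Counter(s[i:i + 2] for s in shuffled for i in range(len(s) - 1))
        assert orig == shuf


class TestDinucleotideShuffle:
    def test_homopolymer_is_fixed(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    def test_same_seed_is_deterministic(self):
        a = dinucleotide_shuffle("ACGUACGUGGCCAU", seed=42)
        b = dinucleotide_shuffle("ACGUACGUGGCCAU", seed=42)
        assert a == b

    @pytest.mark.parametrize("seq", ["ACGUAC", "GGCAUG", "AUAUGC", "CCGAU", "ACGU"])
    def test_output_is_a_valid_shuffle_against_brute_force(self, seq):
        # oracle: exhaustive enumeration of permutations with the same
        # dinucleotide multiset (and same endpoints)
        target = Counter(seq[i:i + 2] for i in range(len(seq) - 1))
        valid = {
            "".join(p) for p in permutations(seq)
            if Counter("".join(p)[i:i + 2] for i in range(len(seq) - 1)) == target
        }
        rng = np.random.default_rng(9)
        for _ in range(20):
            out = dinucleotide_shuffle(seq, rng=rng)
            assert out in valid

    @given(st.text(alphabet="ACGU", min_size=2, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_dinucleotide_multiset_and_endpoints_preserved(self, seq):
        out = dinucleotide_shuffle(seq, seed=1)
        assert Counter(out[i:i + 2] for i in range(len(out) - 1)) == \
               Counter(seq[i:i + 2] for i in range(len(seq) - 1))
        assert out[0] == seq[0] and out[-1] == seq[-1]
        assert Counter(out) == Counter(seq)


class TestRandomSampleControl:
    def test_full_sample_is_identity(self):
        seqs = ["AA", "CC", "GG"]
        assert random_sample_control(seqs, 3, seed=0) == seqs

    def test_zero_sample_is_empty(self):
        assert random_sample_control(["AA"], 0, seed=0) == []

    def test_fixed_seed_reproduces_subset(self):
        seqs = [f"{'ACGU'[i % 4]}{'ACGU'[(i + 1) % 4]}" for i in range(20)]
        assert random_sample_control(seqs, 7, seed=5) == \
               random_sample_control(seqs, 7, seed=5)

    def test_oversampling_is_an_error(self):
        with pytest.raises(ValueError):
            random_sample_control(["AA"], 2, seed=0)


class TestCompareDistributions:
    def test_identical_samples_not_significant(self):
        sample = [i / 10 for i in range(1, 10)]
        _, p = compare_distributions(sample, sample)
        assert p > 0.9

    def test_u_statistics_sum_to_product_of_sizes(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.5, 0.1, 30).tolist()
        b = rng.normal(0.4, 0.1, 40).tolist()
        u_ab, _ = compare_distributions(a, b)
        u_ba, _ = compare_distributions(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_separated_samples_match_permutation_oracle(self):
        # oracle: permutation test on the difference in means
        rng = np.random.default_rng(8)
        a = rng.normal(0.52, 0.03, 100)
        b = rng.normal(0.30, 0.03, 100)
        _, p = compare_distributions(a.tolist(), b.tolist())
        assert p < 0.001

        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:100].mean() - perm[100:].mean()) >= observed:
                hits += 1
        assert (hits + 1) / (n_perm + 1) < 0.001

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([0.5], [0.4, 0.3])
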