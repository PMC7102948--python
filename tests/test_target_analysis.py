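"""Target-site GC structure: profiles, backgrounds, normalization, pairing."""

import numpy as np
import pytest

from mirsig.composition import gc_content
from mirsig.seqio import SeqRecord, reverse_complement
from mirsig.target_analysis import (
    TargetSite,
    background_position_gc,
    find_site_naive,
    mirna_target_position_map,
    normalized_site_gc,
    sliding_window_gc,
)
from mirsig.synthetic_data import (
    gen_random_cdnas,
    gen_signature_read,
    gen_target_mrna,
)
from mirsig.signature import default_signature_model


class TestSlidingWindowGc:
    def test_21nt_input_is_a_single_value(self):
        seq = "ACGU" * 5 + "A"
        prof = sliding_window_gc(seq)
        assert len(prof.values) == 1
        assert prof.values[0] == pytest.approx(gc_content(seq))

    def test_poly_a_is_all_zero(self):
        prof = sliding_window_gc("A" * 50)
        assert np.all(prof.values == 0.0)

    def test_window_count_formula(self):
        prof = sliding_window_gc("ACGU" * 20, window=21, step=2)
        assert len(prof.values) == (80 - 21) // 2 + 1

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            sliding_window_gc("ACGU")

    def test_profile_maximum_localizes_a_planted_gc_site(self):
        # oracle: the generator's planted coordinates. The background must
        # be GC-poor enough that no random 21-nt window plausibly reaches
        # the site's >= 9 G/C bases: at background_gc=0.10 the per-window
        # tail P(Bin(21, 0.1) >= 9) is ~1e-5, so the site dominates.
        rng = np.random.default_rng(17)
        model = default_signature_model()
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            mirna = gen_signature_read(model, rng)  # ~52% GC site
            mrna, site = gen_target_mrna(mirna, mrna_length=200,
                                         background_gc=0.10,
                                         site_position=int(rng.integers(1, 180)),
                                         rng=rng)
            prof = sliding_window_gc(mrna.sequence)
            best_start = int(np.argmax(prof.values)) + 1
            if site.span[0] - 20 <= best_start <= site.span[1]:
                hits += 1
        assert hits / n_rep >= 0.95


class TestBackgroundPositionGc:
    def test_uniform_pool_gives_flat_background(self):
        cdnas = gen_random_cdnas(50, length=300, gc=0.5, seed=2)
        bg = background_position_gc(cdnas, n_windows=10_000, seed=3)
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert np.all(np.abs(bg.values - 0.5) < 3 * se + 0.01)

    def test_fixed_seed_is_reproducible(self):
        cdnas = gen_random_cdnas(10, length=100, gc=0.4, seed=4)
        a = background_position_gc(cdnas, n_windows=500, seed=5)
        b = background_position_gc(cdnas, n_windows=500, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_single_all_g_cdna(self):
        bg = background_position_gc([SeqRecord(id="g", sequence="G" * 21)],
                                    n_windows=5, seed=0)
        assert np.all(bg.values == 1.0)

    def test_no_eligible_cdna_is_an_error(self):
        with pytest.raises(ValueError):
            background_position_gc([SeqRecord(id="s", sequence="ACGU")],
                                   n_windows=10, seed=0)


class TestNormalizedSiteGc:
    def test_background_sites_normalize_to_one(self):
        # sites drawn from the background itself converge to ratio 1
        rng = np.random.default_rng(6)
        cdnas = gen_random_cdnas(100, length=300, gc=0.42, seed=7)
        mrnas = {c.id: c.sequence for c in cdnas}
        sites = []
        for _ in range(10_000):
            c = cdnas[rng.integers(len(cdnas))]
            start = int(rng.integers(1, 300 - 20))
            sites.append(TargetSite(mrna_id=c.id, span=(start, start + 20)))
        bg = background_position_gc(cdnas, n_windows=10_000, seed=8)
        res = normalized_site_gc(sites, mrnas, bg)
        se = np.sqrt(0.42 * 0.58 / 10_000) / 0.42
        assert np.all(np.abs(res.site_ratio - 1.0) < 3 * se + 3 * se)

    def test_planted_complementary_sites_mirror_the_signature(self):
        # oracle: the generator's planted complementarity
        rng = np.random.default_rng(9)
        model = default_signature_model()
        mirna = gen_signature_read(model, rng)
        mrnas = {}
        sites = []
        for i in range(500):
            rec, site = gen_target_mrna(mirna, mrna_length=300,
                                        background_gc=0.42, site_position=140,
                                        rng=rng, mrna_id=f"m{i}")
            mrnas[rec.id] = rec.sequence
            sites.append(site)
        cdnas = gen_random_cdnas(200, length=300, gc=0.42, seed=10)
        bg = background_position_gc(cdnas, n_windows=10_000, seed=11)
        res = normalized_site_gc(sites, mrnas, bg)
        for i in sorted(model.core_gc_positions):
            j = mirna_target_position_map(i)
            assert res.site_ratio[j - 1] > 1.5  # G/C on miRNA -> C/G on site
        for i in sorted(model.core_au_positions):
            j = mirna_target_position_map(i)
            assert res.site_ratio[j - 1] < 0.5
        assert np.abs(res.upstream_ratio - 1.0).max() < 0.25
        assert np.abs(res.downstream_ratio - 1.0).max() < 0.25

    def test_empty_site_list_is_an_error(self):
        bg = background_position_gc([SeqRecord(id="g", sequence="G" * 30)],
                                    n_windows=5, seed=0)
        with pytest.raises(ValueError):
            normalized_site_gc([], {}, bg)

    def test_sites_near_ends_drop_from_adjacent_windows(self):
        seq = "G" * 60
        mrnas = {"m": seq}
        sites = [TargetSite(mrna_id="m", span=(1, 21))]  # no upstream room
        bg = background_position_gc([SeqRecord(id="g", sequence=seq)],
                                    n_windows=100, seed=1)
        res = normalized_site_gc(sites, mrnas, bg)
        assert res.n_upstream == 0
        assert res.upstream_ratio is None
        assert res.n_downstream == 1


class TestPositionMap:
    @pytest.mark.parametrize("i,j", [(12, 10), (1, 21), (11, 11), (21, 1)])
    def test_known_pairings(self, i, j):
        assert mirna_target_position_map(i) == j

    def test_involution_over_all_positions(self):
        for i in range(1, 22):
            assert mirna_target_position_map(mirna_target_position_map(i)) == i

    @pytest.mark.parametrize("i", [0, 22, -3])
    def test_out_of_range_is_an_error(self, i):
        with pytest.raises(ValueError):
            mirna_target_position_map(i)


class TestFindSiteNaive:
    def test_exact_reverse_complement_scores_21(self):
        mirna = "UGCUUGUCGACUCAUUCGCUC"
        mrna = "A" * 40 + reverse_complement(mirna) + "A" * 40
        hit = find_site_naive(mirna, mrna)
        assert hit.score == pytest.approx(21.0)
        assert hit.site.span == (41, 61)

    def test_tie_breaks_to_smallest_start(self):
        hit = find_site_naive("A" * 21, "A" * 50)
        assert hit.site.span == (1, 21)
        # A:A does not pair; U rows would: score comes out zero here
        assert hit.score == pytest.approx(0.0)

    def test_planted_site_with_mismatches_recovered(self):
        # oracle: brute-force planted span, score 21 - #mismatches
        rng = np.random.default_rng(13)
        model = default_signature_model()
        recovered = 0
        for _ in range(100):
            mirna = gen_signature_read(model, rng)
            pos = int(rng.integers(1, 160))
            mrna, site = gen_target_mrna(mirna, mrna_length=180,
                                         background_gc=0.42, site_position=pos,
                                         mismatch_positions=(5, 16), rng=rng)
            hit = find_site_naive(mirna, mrna.sequence)
            if hit.site.span == site.span:
                recovered += 1
                assert hit.score == pytest.approx(19.0)
        assert recovered >= 95  # random context rarely beats 19 matches

    def test_wobble_counts_half(self):
        mirna = "G" * 21
        mrna = "U" * 30  # every window pairs G:U at all 21 positions
        hit = find_site_naive(mirna, mrna)
        assert hit.score == pytest.approx(10.5)
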