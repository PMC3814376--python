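"""Promoter geometry, divergent-pair detection, TFBS binning, composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromarch.promoter_sequence import (GeneModel, conservation_meta_profile,
                                         find_bidirectional_pairs,
                                         promoter_region, sliding_composition,
                                         tfbs_bin_matrix, tss_meta_profile)
from chromarch.symcurv import reverse_complement


def ann(*rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


class TestGeneModel:
    def test_tss_follows_strand(self):
        assert GeneModel("g", "c", 100, 200, "+").tss == 100
        assert GeneModel("g", "c", 100, 200, "-").tss == 199

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", 200, 100, "+")


class TestPromoterRegion:
    def test_plus_strand_upstream_gap(self):
        a = ann(("up", "c", 500, 700, "+"), ("g", "c", 1000, 2000, "+"))
        region = promoter_region("g", a, {"c": 5000})
        assert (region.start, region.end, region.length) == (700, 1000, 300)

    def test_minus_strand_flips_direction(self):
        a = ann(("g", "c", 1000, 2000, "-"), ("dn", "c", 2400, 2800, "+"))
        region = promoter_region("g", a, {"c": 5000})
        assert (region.start, region.end, region.length) == (2000, 2400, 400)

    def test_mirrored_coordinates_give_mirrored_promoter(self):
        # strand-flip oracle: mirror every interval in a 3000 bp chromosome
        L = 3000
        a = ann(("up", "c", 500, 700, "+"), ("g", "c", 1000, 2000, "+"))
        fwd = promoter_region("g", a, {"c": L})
        mirrored = ann(("up", "c", L - 700, L - 500, "-"),
                       ("g", "c", L - 2000, L - 1000, "-"))
        rev = promoter_region("g", mirrored, {"c": L})
        assert (rev.start, rev.end) == (L - fwd.end, L - fwd.start)

    def test_abutting_neighbor_gives_zero_length(self):
        a = ann(("up", "c", 500, 1000, "+"), ("g", "c", 1000, 2000, "+"))
        assert promoter_region("g", a, {"c": 5000}).length == 0

    def test_never_overlaps_gene_bodies(self, small_world):
        a = small_world.annotation
        for gid in a["gene_id"].sample(20, random_state=0):
            region = promoter_region(gid, a, small_world.chrom_lengths)
            same = a.loc[a["chrom"] == region.chrom]
            overlap = (same["start"] < region.end) & (same["end"] > region.start)
            assert not overlap.any()


class TestBidirectionalPairs:
    def test_divergent_within_span_paired(self):
        a = ann(("l", "c", 1000, 2000, "-"), ("r", "c", 2399, 3000, "+"))
        pairs = find_bidirectional_pairs(a, 600)  # TSS-to-TSS = 400
        assert list(pairs[["minus_gene", "plus_gene"]].iloc[0]) == ["l", "r"]

    def test_span_beyond_limit_not_paired(self):
        a = ann(("l", "c", 1000, 2000, "-"), ("r", "c", 2699, 3000, "+"))
        assert len(find_bidirectional_pairs(a, 600)) == 0  # span 700

    def test_convergent_orientation_not_paired(self):
        a = ann(("l", "c", 1000, 2000, "+"), ("r", "c", 2100, 3000, "-"))
        assert len(find_bidirectional_pairs(a, 600)) == 0

    def test_each_gene_in_at_most_one_pair(self, small_world):
        pairs = find_bidirectional_pairs(small_world.annotation, 600)
        members = list(pairs["minus_gene"]) + list(pairs["plus_gene"])
        assert len(members) == len(set(members))
        assert (pairs["span"] <= 600).all()


class TestTfbsMatrix:
    def test_no_sites_gives_zero_matrix(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        tf = pd.DataFrame(columns=["chrom", "start", "end", "factor"])
        mat = tfbs_bin_matrix(tf, a, {"g"})
        assert mat.matrix.empty

    def test_site_at_tss_lands_in_offset_zero_bin(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        tf = pd.DataFrame([("c", 1000, 1001, "F")],
                          columns=["chrom", "start", "end", "factor"])
        mat = tfbs_bin_matrix(tf, a, {"g"}, upstream=500, downstream=300,
                              bin_size=20)
        assert mat.matrix.loc["F", 0] == 1
        assert mat.matrix.to_numpy().sum() == 1

    def test_mirrored_construction_gives_identical_matrix(self):
        L = 4000
        a_fwd = ann(("g", "c", 1000, 2000, "+"))
        sites = [("c", 800, 801, "F"), ("c", 950, 951, "F"), ("c", 1100, 1101, "G")]
        tf_fwd = pd.DataFrame(sites, columns=["chrom", "start", "end", "factor"])
        a_rev = ann(("g", "c", L - 2000, L - 1000, "-"))
        tf_rev = pd.DataFrame([(c, L - 1 - s, L - s, f) for c, s, _, f in sites],
                              columns=["chrom", "start", "end", "factor"])
        m1 = tfbs_bin_matrix(tf_fwd, a_fwd, {"g"})
        m2 = tfbs_bin_matrix(tf_rev, a_rev, {"g"})
        pd.testing.assert_frame_equal(m1.matrix, m2.matrix)

    def test_zscore_rows_standardized_and_flat_rows_flagged(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        tf = pd.DataFrame([("c", 900, 901, "F"), ("c", 950, 951, "F")],
                          columns=["chrom", "start", "end", "factor"])
        mat = tfbs_bin_matrix(tf, a, {"g"}, normalize="zscore")
        row = mat.matrix.loc["F"].to_numpy()
        assert row.mean() == pytest.approx(0.0, abs=1e-12)
        assert row.std(ddof=0) == pytest.approx(1.0)
        assert mat.flagged_factors == []


class TestSlidingComposition:
    def test_all_gc_window_is_one(self):
        vals, _ = sliding_composition("GCGCGC", window=4)
        assert np.nanmax(vals) == 1.0 and np.nanmin(vals) == 1.0

    def test_balanced_at_gives_zero_skew(self):
        vals, _ = sliding_composition("ATAT", window=4, statistic="at_skew")
        assert vals[2] == 0.0

    def test_hand_counted_at_skew(self):
        vals, _ = sliding_composition("AAAT", window=4, statistic="at_skew")
        assert vals[2] == pytest.approx(0.5)  # (3-1)/(3+1)

    def test_zero_denominator_flagged_not_dropped(self):
        vals, flags = sliding_composition("GGGG", window=4, statistic="at_skew")
        assert vals[2] == 0.0 and flags[2]

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            sliding_composition("ACG", window=100)

    @given(st.text(alphabet="ACGT", min_size=12, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_at_skew_antisymmetric_under_reverse_complement(self, seq):
        window = 10
        fwd, _ = sliding_composition(seq, window, statistic="at_skew")
        rev, _ = sliding_composition(reverse_complement(seq), window,
                                     statistic="at_skew")
        f = fwd[~np.isnan(fwd)]
        r = rev[~np.isnan(rev)]
        assert np.allclose(f, -r[::-1], atol=1e-12)


class TestTssMetaProfile:
    def test_constant_track_gives_constant_profile(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        prof = tss_meta_profile({"c": np.full(3000, 2.5)}, a, {"g"}, 100, 100)
        assert np.allclose(prof.values, 2.5)

    def test_delta_at_tss_peaks_at_offset_zero(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        track = np.zeros(3000)
        track[1000] = 1.0
        prof = tss_meta_profile({"c": track}, a, {"g"}, 100, 100)
        assert prof.offsets[np.argmax(prof.values)] == 0

    def test_reverse_complement_mirror_gene_gives_identical_skew_profile(self):
        rng = np.random.default_rng(11)
        core = "".join(rng.choice(list("ACGT"), size=1200))
        pad = "A" * 400
        seq_fwd = pad + core + pad
        seq_rev = reverse_complement(seq_fwd)
        L = len(seq_fwd)
        a = ann(("f", "c1", 400, 400 + 1200, "+"),
                ("r", "c2", L - 400 - 1200, L - 400, "-"))
        # odd window so the assigned center position is strand-symmetric
        tracks = {
            "c1": sliding_composition(seq_fwd, 101, statistic="at_skew")[0],
            "c2": sliding_composition(seq_rev, 101, statistic="at_skew")[0],
        }
        p_f = tss_meta_profile(tracks, a, {"f"}, 200, 200, flip_sign=True)
        p_r = tss_meta_profile(tracks, a, {"r"}, 200, 200, flip_sign=True)
        assert np.allclose(p_f.values, p_r.values, atol=1e-12)

    def test_empty_gene_set_rejected(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        with pytest.raises(ValueError):
            tss_meta_profile({"c": np.zeros(3000)}, a, set(), 100, 100)

    def test_edge_crossing_genes_dropped_and_counted(self):
        a = ann(("edge", "c", 50, 900, "+"), ("ok", "c", 1500, 2400, "+"))
        prof = tss_meta_profile({"c": np.ones(3000)}, a, {"edge", "ok"}, 200, 200)
        assert prof.n_genes == 1 and prof.n_dropped == 1


class TestConservationProfile:
    def test_full_coverage_unit_track(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        prof = conservation_meta_profile({"c": np.ones(3000)}, a, {"g"}, 100, 100)
        assert np.allclose(prof.values, 1.0)

    def test_two_genes_average(self):
        a = ann(("g1", "c1", 1000, 2000, "+"), ("g2", "c2", 1000, 2000, "+"))
        tracks = {"c1": np.zeros(3000), "c2": np.ones(3000)}
        prof = conservation_meta_profile(tracks, a, {"g1", "g2"}, 100, 100)
        assert np.allclose(prof.values, 0.5)

    def test_missing_positions_averaged_over_present_only(self):
        # 3 genes; at one offset only two genes have data -> mean of those two
        a = ann(("g1", "c1", 1000, 2000, "+"), ("g2", "c2", 1000, 2000, "+"),
                ("g3", "c3", 1000, 2000, "+"))
        t1 = np.full(3000, 0.2)
        t2 = np.full(3000, 0.8)
        t3 = np.full(3000, np.nan)
        prof = conservation_meta_profile({"c1": t1, "c2": t2, "c3": t3},
                                         a, {"g1", "g2", "g3"}, 10, 10)
        assert np.allclose(prof.values, 0.5)

    def test_mostly_missing_track_warns(self):
        a = ann(("g", "c", 1000, 2000, "+"))
        track = np.full(3000, np.nan)
        track[995:1005] = 1.0
        with pytest.warns(UserWarning, match="missing"):
            conservation_meta_profile({"c": track}, a, {"g"}, 100, 100)
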