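"""Spacing, occupancy profiles, dynamic overlap, remodelers, histone marks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromarch.nucleosome_chromatin import (dynamic_overlap_profile,
                                            gene_nucleosome_spacing,
                                            histone_mark_enrichment,
                                            occupancy_meta_profile,
                                            remodeler_enrichment,
                                            spacing_table)


def gene(gene_id="g", chrom="c", start=0, end=2000, strand="+"):
    return pd.Series({"gene_id": gene_id, "chrom": chrom, "start": start,
                      "end": end, "strand": strand})


def nuc(intervals, chrom="c", label="bulk"):
    return pd.DataFrame([(chrom, s, e, label) for s, e in intervals],
                        columns=["chrom", "start", "end", "label"])


class TestSpacing:
    def test_single_linker_of_21(self):
        res = gene_nucleosome_spacing(gene(), nuc([(0, 147), (168, 315)]))
        assert res.defined and res.mean_spacing == 21.0

    def test_single_nucleosome_undefined(self):
        res = gene_nucleosome_spacing(gene(), nuc([(0, 147)]))
        assert not res.defined and np.isnan(res.mean_spacing)

    def test_mean_of_two_gaps(self):
        res = gene_nucleosome_spacing(
            gene(), nuc([(0, 147), (167, 314), (354, 501)]))  # gaps 20, 40
        assert res.mean_spacing == 30.0

    def test_midpoint_rule_excludes_outside_nucleosomes(self):
        # only the nucleosome whose midpoint falls in [100, 400) is assigned
        res = gene_nucleosome_spacing(gene(start=100, end=400),
                                      nuc([(0, 147), (150, 297), (350, 497)]))
        assert res.n_nucleosomes == 1 and not res.defined

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True)
    def test_translation_invariance(self, shift):
        base = [(0, 147), (170, 317), (340, 487)]
        r0 = gene_nucleosome_spacing(gene(), nuc(base))
        r1 = gene_nucleosome_spacing(
            gene(start=shift, end=2000 + shift),
            nuc([(s + shift, e + shift) for s, e in base]))
        assert r1.mean_spacing == r0.mean_spacing
        assert r1.n_nucleosomes == r0.n_nucleosomes

    def test_planted_linkers_recovered_on_world(self, small_world):
        for cls, linker in (("down", 21), ("up", 29)):
            table = spacing_table(small_world.annotation,
                                  small_world.truth[cls],
                                  small_world.nucleosomes)
            mean = table.loc[table["defined"], "mean_spacing"].mean()
            assert mean == pytest.approx(linker, abs=1.0)


def brute_force_bin_fractions(intervals, lo, hi, bin_size):
    """Per-bp coverage counting oracle over window [lo, hi)."""
    covered = np.zeros(hi - lo, dtype=bool)
    for s, e in intervals:
        for pos in range(max(s, lo), min(e, hi)):
            covered[pos - lo] = True
    return covered.reshape(-1, bin_size).mean(axis=1)


class TestOccupancy:
    def test_full_tiling_gives_ones(self):
        ann = pd.DataFrame([("g", "c", 1000, 2000, "+")],
                           columns=["gene_id", "chrom", "start", "end", "strand"])
        prof = occupancy_meta_profile(nuc([(0, 3000)]), ann, {"g"}, {"c": 3000})
        assert np.allclose(prof.values, 1.0)

    def test_no_nucleosomes_gives_zeros(self):
        ann = pd.DataFrame([("g", "c", 1000, 2000, "+")],
                           columns=["gene_id", "chrom", "start", "end", "strand"])
        prof = occupancy_meta_profile(nuc([]), ann, {"g"}, {"c": 3000})
        assert np.allclose(prof.values, 0.0)

    def test_matches_per_bp_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            ann = pd.DataFrame([("g", "c", 1000, 2000, "+")],
                               columns=["gene_id", "chrom", "start", "end",
                                        "strand"])
            intervals = sorted((int(s), int(s) + 147)
                               for s in rng.integers(400, 2500, size=6))
            prof = occupancy_meta_profile(nuc(intervals), ann, {"g"},
                                          {"c": 3000}, 500, 500, 10)
            oracle = brute_force_bin_fractions(intervals, 500, 1500, 10)
            assert np.allclose(prof.values, oracle, atol=1e-12)

    def test_minus_strand_window_is_mirrored(self):
        ann = pd.DataFrame([("g", "c", 1000, 2000, "-")],
                           columns=["gene_id", "chrom", "start", "end", "strand"])
        intervals = [(2050, 2197)]  # upstream of the '-' TSS at 1999
        prof = occupancy_meta_profile(nuc(intervals), ann, {"g"}, {"c": 3000})
        covered = prof.offsets[prof.values > 0]
        assert covered.max() < 0  # appears upstream in gene orientation

    def test_zscore_normalization(self):
        ann = pd.DataFrame([("g", "c", 1000, 2000, "+")],
                           columns=["gene_id", "chrom", "start", "end", "strand"])
        prof = occupancy_meta_profile(nuc([(900, 1047), (1200, 1347)]), ann,
                                      {"g"}, {"c": 3000}, normalize="zscore")
        assert prof.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.values.std(ddof=0) == pytest.approx(1.0)


class TestDynamicOverlap:
    def _ann(self):
        return pd.DataFrame([("g", "c", 1000, 2000, "+")],
                            columns=["gene_id", "chrom", "start", "end",
                                     "strand"])

    def test_absent_label_gives_zero_percent(self):
        nucs = nuc([(1000, 1147)], label="bulk")
        prof = dynamic_overlap_profile(nucs, "appearing", self._ann(), {"g"},
                                       {"c": 3000})
        assert np.allclose(prof.values, 0.0)

    def test_label_identical_to_bulk_gives_bulk_times_100(self):
        intervals = [(900, 1047), (1200, 1347)]
        both = pd.concat([nuc(intervals, label="bulk"),
                          nuc(intervals, label="fragile")], ignore_index=True)
        bulk = occupancy_meta_profile(both, self._ann(), {"g"}, {"c": 3000},
                                      label="bulk")
        frag = dynamic_overlap_profile(both, "fragile", self._ann(), {"g"},
                                       {"c": 3000})
        assert np.allclose(frag.values, bulk.values * 100.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            dynamic_overlap_profile(nuc([]), "bulk", self._ann(), {"g"},
                                    {"c": 3000})

    def test_planted_appearing_nucleosome_peaks_downstream(self, small_world):
        prof = dynamic_overlap_profile(small_world.nucleosomes, "appearing",
                                       small_world.annotation,
                                       small_world.truth["down"],
                                       small_world.chrom_lengths)
        peak = prof.bin_centers[np.argmax(prof.values)]
        assert 0 < peak < 200


class TestRemodelerEnrichment:
    def test_target_equal_universe_gives_ratio_one_p_one(self):
        u = {f"g{i}" for i in range(100)}
        res = remodeler_enrichment({"down": {f"g{i}" for i in range(10)}},
                                   {"R1": u}, u, n_trials=200, seed=0)
        assert res[0].ratio == pytest.approx(1.0)
        assert res[0].p_value == 1.0

    def test_planted_enrichment_in_all_lists_detected(self):
        rng = np.random.default_rng(5)
        u = {f"g{i}" for i in range(1000)}
        down = {f"g{i}" for i in range(60)}
        targets = {}
        for j in range(8):
            rest = rng.choice(sorted(u - down), size=70, replace=False)
            targets[f"R{j}"] = set(rng.choice(sorted(down), 30, replace=False)) | set(rest)
        res = remodeler_enrichment({"down": down}, targets, u,
                                   n_trials=1000, seed=1)
        assert len(res) == 8
        assert all(r.ratio > 1 and r.p_value < 0.01 for r in res)

    def test_seed_reproducibility(self):
        u = {f"g{i}" for i in range(300)}
        targets = {"R1": {f"g{i}" for i in range(50)}}
        dereg = {"up": {f"g{i}" for i in range(25, 45)}}
        p1 = remodeler_enrichment(dereg, targets, u, 500, seed=9)[0].p_value
        p2 = remodeler_enrichment(dereg, targets, u, 500, seed=9)[0].p_value
        assert p1 == p2

    def test_empty_target_list_skipped_with_warning(self):
        u = {f"g{i}" for i in range(50)}
        with pytest.warns(UserWarning, match="no targets"):
            res = remodeler_enrichment({"up": {"g1"}}, {"R1": {"zzz"}}, u,
                                       n_trials=100, seed=0)
        assert res == []


class TestHistoneMarks:
    def _marks(self, shift=0.0, n=600, n_sub=60, seed=6):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(n)]
        rows = []
        for gid in ids:
            delta = shift if gid in set(ids[:n_sub]) else 0.0
            rows.append((gid, "H3K9ac", rng.standard_normal() + delta,
                         rng.standard_normal() + delta))
        return (pd.DataFrame(rows, columns=["gene_id", "mark",
                                            "promoter_score", "orf_score"]),
                set(ids[:n_sub]), set(ids))

    def test_null_subset_not_flagged(self):
        marks, subset, universe = self._marks(shift=0.0)
        res = histone_mark_enrichment(marks, subset, universe)
        assert not res["significant"].any()

    def test_planted_depletion_recovered_with_direction(self):
        marks, subset, universe = self._marks(shift=-1.0)
        res = histone_mark_enrichment(marks, subset, universe)
        assert (res["direction"] == "depleted").all()
        assert res["significant"].all()

    def test_subset_equal_universe_rejected(self):
        marks, _, universe = self._marks()
        with pytest.raises(ValueError, match="complement"):
            histone_mark_enrichment(marks, universe, universe)

    def test_sparsely_scored_mark_skipped(self):
        marks, subset, universe = self._marks()
        marks.loc[marks["gene_id"].isin(list(subset)[:55]),
                  "promoter_score"] = np.nan
        with pytest.warns(UserWarning, match="under half"):
            res = histone_mark_enrichment(marks, subset, universe)
        assert "promoter" not in set(res["compartment"])

    def test_planted_acetylation_loss_on_world(self, small_world):
        res = histone_mark_enrichment(small_world.marks,
                                      small_world.truth["up"],
                                      set(small_world.annotation["gene_id"]))
        acetyl = res[res["mark"].str.endswith("ac")]
        assert (acetyl["direction"] == "depleted").all()
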