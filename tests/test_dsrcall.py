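import numpy as np
import pandas as pd
import pytest

import ovinescan as ov


def make_track(fst, chrom="1", spacing=100_000, top01=None, top5=None):
    m = len(fst)
    df = pd.DataFrame(
        {
            "name": [f"m{i}" for i in range(m)],
            "chrom": [chrom] * m,
            "pos": [(i + 1) * spacing for i in range(m)],
            "fst": np.asarray(fst, dtype=float),
        }
    )
    if top01 is not None:
        df["in_top01"] = top01
        df["in_top5"] = top5
    return df


class TestRankAndFlag:
    def test_unique_values_give_exact_counts(self, rng):
        track = make_track(rng.permutation(np.linspace(0.01, 0.99, 1000)))
        flagged = ov.rank_and_flag(track)
        assert flagged["in_top01"].sum() == 1
        assert flagged["in_top5"].sum() == 50

    def test_ties_at_the_maximum_all_flagged(self):
        vals = np.linspace(0.01, 0.5, 994).tolist() + [1.0] * 6
        flagged = ov.rank_and_flag(make_track(vals))
        assert flagged["in_top01"].sum() == 6
        assert (flagged.loc[flagged["in_top01"], "fst"] == 1.0).all()

    def test_all_equal_values_flag_everything(self):
        flagged = ov.rank_and_flag(make_track([0.5] * 100))
        assert flagged["in_top01"].all() and flagged["in_top5"].all()

    def test_top01_subset_of_top5(self, rng):
        flagged = ov.rank_and_flag(make_track(rng.uniform(0, 1, 2000)))
        assert (~flagged["in_top01"] | flagged["in_top5"]).all()

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            ov.rank_and_flag(make_track([]))


class TestGrowRegion:
    def test_stop_rule_walkthrough(self):
        # seed; 3 non-top5; one top5; then 4 non-top5 -> region reaches the
        # interior top-5% marker and stops
        top5 = [True, False, False, False, True, False, False, False, False]
        top01 = [True] + [False] * 8
        track = make_track([0.9, 0.1, 0.1, 0.1, 0.5, 0.1, 0.1, 0.1, 0.1],
                           top01=top01, top5=top5)
        region = ov.grow_region(track, 0)
        assert region.start_bp == track["pos"].iloc[0]
        assert region.end_bp == track["pos"].iloc[4]
        assert region.n_top5 == 2 and region.n_top01 == 1

    def test_four_consecutive_misses_stop_the_scan(self):
        # a top-5% marker past 4 consecutive misses is NOT reached
        top5 = [True, False, False, False, False, True]
        top01 = [True] + [False] * 5
        track = make_track([0.9, 0.1, 0.1, 0.1, 0.1, 0.5], top01=top01, top5=top5)
        region = ov.grow_region(track, 0)
        assert region.start_bp == region.end_bp == track["pos"].iloc[0]

    def test_isolated_seed_gives_single_marker_region(self):
        top5 = [False] * 4 + [True] + [False] * 4
        top01 = [False] * 4 + [True] + [False] * 4
        track = make_track([0.1] * 4 + [0.9] + [0.1] * 4, top01=top01, top5=top5)
        region = ov.grow_region(track, 4)
        assert region.start_bp == region.end_bp == track["pos"].iloc[4]
        assert region.n_top01 == region.n_top5 == 1

    def test_seed_at_chromosome_edge(self):
        top5 = [True, True, False, False, False, False]
        top01 = [True] + [False] * 5
        track = make_track([0.9, 0.5, 0.1, 0.1, 0.1, 0.1], top01=top01, top5=top5)
        region = ov.grow_region(track, 0)
        assert region.start_bp == track["pos"].iloc[0]
        assert region.end_bp == track["pos"].iloc[1]

    def test_unflagged_seed_rejected(self):
        track = make_track([0.1, 0.9], top01=[False, True], top5=[False, True])
        with pytest.raises(ValueError, match="seed"):
            ov.grow_region(track, 0)


class TestTruncateAndMerge:
    def test_over_long_region_capped_around_peak(self):
        # 41 markers at 100 kb: span 4 Mb, peak at the center
        fst = [0.2] * 20 + [0.9] + [0.2] * 20
        top5 = [True] * 41
        top01 = [False] * 20 + [True] + [False] * 20
        track = make_track(fst, top01=top01, top5=top5)
        region = ov.grow_region(track, 20)
        assert region.span_bp == 4_000_000
        final = ov.truncate_and_merge([region], track)
        assert len(final) == 1
        assert final[0].span_bp <= 3_000_000
        assert final[0].start_bp == region.peak_pos - 1_500_000
        assert final[0].end_bp == region.peak_pos + 1_500_000

    def test_disjoint_regions_unchanged(self):
        track = make_track([0.9] + [0.0] * 50 + [0.8] + [0.0] * 48,
                           top01=[True] + [False] * 50 + [True] + [False] * 48,
                           top5=[True] + [False] * 50 + [True] + [False] * 48)
        r1 = ov.grow_region(track, 0)
        r2 = ov.grow_region(track, 51)
        final = ov.truncate_and_merge([r1, r2], track)
        assert len(final) == 2

    def test_overlapping_regions_union_with_higher_peak(self):
        track = make_track([0.9, 0.5, 0.95, 0.5, 0.1, 0.1, 0.1, 0.1],
                           top01=[True, False, True, False] + [False] * 4,
                           top5=[True, True, True, True] + [False] * 4)
        r1 = ov.grow_region(track, 0)
        r2 = ov.grow_region(track, 2)
        final = ov.truncate_and_merge([r1, r2], track)
        assert len(final) == 1
        assert final[0].peak_fst == 0.95
        assert final[0].start_bp == track["pos"].iloc[0]
        assert final[0].end_bp == track["pos"].iloc[3]


class TestCallRegions:
    def test_every_region_contains_a_seed_and_regions_disjoint(self, rng):
        fst = rng.beta(0.5, 8, size=3000)
        track = make_track(fst)
        regions = ov.call_regions(track)
        assert all(r.n_top01 >= 1 for r in regions)
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1:]:
                assert not r1.overlaps(r2)

    def test_deterministic_and_name_invariant(self, rng):
        fst = rng.beta(0.5, 8, size=2000)
        track = make_track(fst)
        r1 = ov.call_regions(track)
        renamed = track.copy()
        renamed["name"] = [f"other_{i}" for i in range(len(track))]
        r2 = ov.call_regions(renamed)
        assert [(r.chrom, r.start_bp, r.end_bp, r.peak_fst) for r in r1] == \
               [(r.chrom, r.start_bp, r.end_bp, r.peak_fst) for r in r2]


class TestAnnotation:
    @pytest.fixture
    def regions(self):
        return [ov.Region(chrom="1", start_bp=1_000_000, end_bp=2_000_000,
                          peak_name="m1", peak_pos=1_500_000, peak_fst=0.9,
                          n_top01=1, n_top5=3)]

    def test_gene_inside_region_reported(self, regions):
        genes = pd.DataFrame({"chrom": ["1"], "start": [1_200_000],
                              "end": [1_300_000], "name": ["GENE1"]})
        assert ov.annotate_regions(regions, genes) == [["GENE1"]]

    def test_gene_abutting_end_plus_one_not_reported(self, regions):
        genes = pd.DataFrame({"chrom": ["1"], "start": [2_000_001],
                              "end": [2_100_000], "name": ["GENE2"]})
        assert ov.annotate_regions(regions, genes) == [[]]

    def test_gene_spanning_boundary_reported(self, regions):
        genes = pd.DataFrame({"chrom": ["1"], "start": [1_900_000],
                              "end": [2_500_000], "name": ["GENE3"]})
        assert ov.annotate_regions(regions, genes) == [["GENE3"]]

    def test_bed_round_trip_preserves_coordinates(self, regions, tmp_path):
        bed = tmp_path / "regions.bed"
        ov.write_regions_bed(regions, bed)
        back = ov.dsrcall.read_regions_bed(bed)
        assert back == [("1", 1_000_000, 2_000_000)]

    def test_bed_gene_file_converted_to_1_based(self, regions, tmp_path):
        bed = tmp_path / "genes.bed"
        # 0-based half-open [999999, 1000000) = 1-based base 1,000,000 exactly
        bed.write_text("1\t999999\t1000000\tEDGE\n")
        genes = ov.read_gene_intervals(bed)
        assert genes.loc[0, "start"] == 1_000_000
        assert genes.loc[0, "end"] == 1_000_000
        assert ov.annotate_regions(regions, genes) == [["EDGE"]]
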