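import shutil
import subprocess

import numpy as np
import pytest

from cooccupy.intervals import (
    BedParseError,
    GenomicInterval,
    PeakSet,
    TSSEntry,
    TSSTable,
    annotate_nearest_tss,
    classify_cooccupancy,
    cooccupancy_chi2,
    fraction_overlapping,
    merge_intervals,
    read_bed,
    read_genome_sizes,
    read_tss_table,
    venn_region_counts,
    write_bed,
)

from conftest import per_base_union, random_peak_set, runs_of


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", 0, 100, strand="x")

    def test_overlap_is_shared_base(self):
        a = GenomicInterval("chr2L", 0, 100)
        assert not a.overlaps(GenomicInterval("chr2L", 100, 200))
        assert a.overlaps(GenomicInterval("chr2L", 99, 200))
        assert not a.overlaps(GenomicInterval("chr3R", 50, 60))

    def test_center_floor(self):
        assert GenomicInterval("c", 990, 1010).center == 1000
        assert GenomicInterval("c", 0, 3).center == 1


class TestBedIO:
    def test_three_column_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\n")
        ps = read_bed(p)
        (iv,) = ps.intervals
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr2L", 100, 200, ".")

    def test_inverted_coordinates_raise_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t1\t2\nchr2L\t200\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_non_integer_coordinates_raise(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\tx\t200\n")
        with pytest.raises(BedParseError, match=":1"):
            read_bed(p)

    def test_six_column_strand_preserved(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\tpk1\t5.5\t-\n")
        (iv,) = read_bed(p).intervals
        assert iv.strand == "-" and iv.name == "pk1" and iv.score == 5.5

    def test_round_trip(self, tmp_path, rng):
        ps = random_peak_set(rng, "x", 50, {"chr2L": 100_000})
        write_bed(ps, tmp_path / "x.bed")
        back = read_bed(tmp_path / "x.bed")
        assert [(i.chrom, i.start, i.end) for i in back] == [
            (i.chrom, i.start, i.end) for i in ps
        ]

    def test_genome_sizes(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("chr2L\t23513712\nchr3R\t32079331\n")
        assert read_genome_sizes(p) == {"chr2L": 23513712, "chr3R": 32079331}


class TestMerge:
    def test_overlapping_pair_merges(self):
        out = merge_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)]
        )
        assert [(i.start, i.end) for i in out] == [(0, 150)]

    def test_disjoint_unchanged(self):
        out = merge_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)], gap=0
        )
        assert [(i.start, i.end) for i in out] == [(0, 100), (200, 300)]

    def test_touching_merges_at_gap_zero(self):
        out = merge_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 100, 200)]
        )
        assert [(i.start, i.end) for i in out] == [(0, 200)]

    def test_gap_parameter(self):
        ivs = [GenomicInterval("c", 0, 100), GenomicInterval("c", 130, 200)]
        assert len(merge_intervals(ivs, gap=29)) == 2
        assert len(merge_intervals(ivs, gap=30)) == 1

    def test_matches_per_base_oracle(self, rng):
        chrom_lengths = {"chrSim": 100_000}
        ps = random_peak_set(rng, "m", 500, chrom_lengths)
        merged = merge_intervals(ps.intervals)
        (covered, _) = per_base_union([ps], chrom_lengths)["chrSim"]
        assert [(i.start, i.end) for i in merged] == runs_of(covered)

    @pytest.mark.skipif(shutil.which("bedtools") is None,
                        reason="bedtools unavailable")
    def test_matches_bedtools_merge(self, tmp_path, rng):
        ps = random_peak_set(rng, "m", 300, {"chrSim": 100_000})
        srt = sorted(ps.intervals, key=lambda i: (i.chrom, i.start))
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"{i.chrom}\t{i.start}\t{i.end}\n" for i in srt))
        out = subprocess.run(
            ["bedtools", "merge", "-i", str(bed)], capture_output=True, text=True,
            check=True,
        ).stdout
        expected = [
            (int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.strip().split("\n"))
        ]
        assert [(i.start, i.end) for i in merge_intervals(ps.intervals)] == expected


class TestClassifyCooccupancy:
    def test_overlapping_sets_single_region(self):
        A = PeakSet("A", [GenomicInterval("c", 0, 100)])
        B = PeakSet("B", [GenomicInterval("c", 50, 150)])
        (r,) = classify_cooccupancy([A, B])
        assert (r.region.start, r.region.end) == (0, 150)
        assert r.members == {"A", "B"}

    def test_disjoint_sets_two_regions(self):
        A = PeakSet("A", [GenomicInterval("c", 0, 100)])
        B = PeakSet("B", [GenomicInterval("c", 200, 300)])
        regions = classify_cooccupancy([A, B])
        assert [(r.region.start, r.region.end, set(r.members)) for r in regions] == [
            (0, 100, {"A"}),
            (200, 300, {"B"}),
        ]

    def test_duplicate_labels_rejected(self):
        A = PeakSet("A", [GenomicInterval("c", 0, 100)])
        with pytest.raises(ValueError, match="duplicate"):
            classify_cooccupancy([A, A])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_membership_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_lengths = {"chrSim": 100_000}
        sets = [
            random_peak_set(rng, lbl, 200, chrom_lengths) for lbl in "ABC"
        ]
        regions = classify_cooccupancy(sets)
        covered, per_label = per_base_union(sets, chrom_lengths)["chrSim"]
        oracle_runs = runs_of(covered)
        assert [(r.region.start, r.region.end) for r in regions] == oracle_runs
        for r in regions:
            expected = {
                lbl
                for lbl, mask in per_label.items()
                if mask[r.region.start : r.region.end].any()
            }
            assert set(r.members) == expected

    def test_partition_property(self, rng):
        # disjointness + coverage of the merged union
        chrom_lengths = {"chrSim": 50_000}
        sets = [random_peak_set(rng, lbl, 100, chrom_lengths) for lbl in "AB"]
        regions = classify_cooccupancy(sets)
        for r1, r2 in zip(regions, regions[1:]):
            assert not r1.region.overlaps(r2.region)
        total = sum(len(r.region) for r in regions)
        covered, _ = per_base_union(sets, chrom_lengths)["chrSim"]
        assert total == int(covered.sum())


class TestVennCounts:
    def test_two_disjoint_regions(self):
        A = PeakSet("A", [GenomicInterval("c", 0, 100)])
        B = PeakSet("B", [GenomicInterval("c", 200, 300)])
        counts = venn_region_counts(classify_cooccupancy([A, B]), ["A", "B"])
        assert counts == {
            frozenset({"A"}): 1,
            frozenset({"B"}): 1,
            frozenset({"A", "B"}): 0,
        }

    def test_single_shared_region(self):
        A = PeakSet("A", [GenomicInterval("c", 0, 100)])
        B = PeakSet("B", [GenomicInterval("c", 50, 150)])
        counts = venn_region_counts(classify_cooccupancy([A, B]))
        assert counts[frozenset({"A", "B"})] == 1

    def test_four_set_counts_sum_to_region_count(self, rng):
        sets = [
            random_peak_set(rng, lbl, 80, {"chrSim": 200_000}) for lbl in "ABCD"
        ]
        regions = classify_cooccupancy(sets)
        counts = venn_region_counts(regions, "ABCD")
        assert len(counts) == 15
        assert sum(counts.values()) == len(regions)


class TestFractionOverlapping:
    def test_self_overlap_is_one(self, rng):
        ps = random_peak_set(rng, "q", 50, {"c": 100_000})
        assert fraction_overlapping(ps, ps) == 1.0

    def test_disjoint_is_zero(self):
        A = PeakSet("A", [GenomicInterval("c", 0, 100)])
        B = PeakSet("B", [GenomicInterval("c", 200, 300)])
        assert fraction_overlapping(A, B) == 0.0

    def test_empty_query_rejected(self):
        B = PeakSet("B", [GenomicInterval("c", 0, 100)])
        with pytest.raises(ValueError):
            fraction_overlapping(PeakSet("A", []), B)

    def test_invariant_under_normalization_and_subject_merge(self, rng):
        A = random_peak_set(rng, "A", 200, {"c": 100_000})
        B = random_peak_set(rng, "B", 200, {"c": 100_000})
        base = fraction_overlapping(A, B)
        assert fraction_overlapping(A.normalize(), B) == base
        assert fraction_overlapping(A, B.normalize()) == base


class TestCooccupancyChi2:
    GENOME = {"chrSim": 1_000_000}

    def test_whole_genome_subject_degenerate(self):
        q = PeakSet("q", [GenomicInterval("chrSim", i * 1000, i * 1000 + 100)
                          for i in range(10)])
        s = PeakSet("s", [GenomicInterval("chrSim", 0, 1_000_000)])
        with pytest.raises(ValueError, match="degenerate"):
            cooccupancy_chi2(q, s, self.GENOME)

    def test_statistic_matches_hand_formula(self):
        q = PeakSet("q", [GenomicInterval("chrSim", i * 10_000, i * 10_000 + 200)
                          for i in range(50)])
        s = PeakSet("s", [GenomicInterval("chrSim", i * 10_000 + 100,
                                          i * 10_000 + 300)
                          for i in range(30)])
        res = cooccupancy_chi2(q, s, self.GENOME)
        G = 1_000_000
        p = min(1.0, (30 * 200 + 30 * 200) / G)
        E = 50 * p
        O = res.observed_overlapping
        expected_stat = (O - E) ** 2 / E + ((50 - O) - (50 - E)) ** 2 / (50 - E)
        assert res.observed_overlapping == 30
        assert res.expected_overlapping == pytest.approx(E)
        assert res.statistic == pytest.approx(expected_stat)
        assert 0 <= res.p_value <= 1

    def test_null_pvalues_roughly_uniform(self):
        # independent random placements: at most ~10% of p-values below 0.05
        low = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            q = random_peak_set(rng, "q", 80, self.GENOME, max_len=200)
            s = random_peak_set(rng, "s", 80, self.GENOME, max_len=200)
            res = cooccupancy_chi2(q, s, self.GENOME)
            if res.p_value < 0.05:
                low += 1
        # binomial(200, 0.05): mean 10, 99% upper bound ~= 20
        assert low <= 20


class TestAnnotateNearestTSS:
    TSS = TSSTable(
        [
            TSSEntry("gB", "c", 1000, "+"),
            TSSEntry("gA", "c", 9000, "-"),
        ]
    )

    def test_peak_on_tss_is_promoter(self):
        peaks = PeakSet("p", [GenomicInterval("c", 990, 1010)])
        (a,) = annotate_nearest_tss(peaks, self.TSS)
        assert (a.gene, a.distance, a.category) == ("gB", 0, "promoter")

    def test_three_kb_boundary_inclusive(self):
        peaks = PeakSet("p", [GenomicInterval("c", 3990, 4010),
                              GenomicInterval("c", 3991, 4011)])
        a, b = annotate_nearest_tss(peaks, self.TSS)
        assert (a.distance, a.category) == (3000, "promoter")
        assert (b.distance, b.category) == (3001, "distal")

    def test_distal_beyond_cutoff(self):
        peaks = PeakSet("p", [GenomicInterval("c", 5490, 5510)])
        (a,) = annotate_nearest_tss(peaks, self.TSS)
        assert a.category == "distal" and a.gene == "gA" and a.distance == 3500

    def test_equidistant_tie_breaks_lexicographically(self):
        tss = TSSTable([TSSEntry("gZ", "c", 900, "+"), TSSEntry("gA", "c", 1100, "+")])
        peaks = PeakSet("p", [GenomicInterval("c", 990, 1010)])
        (a,) = annotate_nearest_tss(peaks, tss)
        assert a.gene == "gA" and a.distance == 100

    def test_unknown_chromosome_flagged(self):
        peaks = PeakSet("p", [GenomicInterval("chrU", 0, 100)])
        (a,) = annotate_nearest_tss(peaks, self.TSS)
        assert a.category == "unannotated" and a.gene is None

    def test_tss_table_formats(self, tmp_path):
        tsv = tmp_path / "tss.tsv"
        tsv.write_text("gA\tc\t5000\t+\n")
        bed = tmp_path / "tss.bed"
        bed.write_text("c\t5000\t6000\tgA\t0\t-\n")
        assert read_tss_table(tsv).nearest("c", 5000) == ("gA", 0)
        assert read_tss_table(bed).nearest("c", 5999) == ("gA", 0)
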