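"""Interval model, I/O round trips, and the overlap/shuffle engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regulink import (
    ChromSizes,
    CoverageTrack,
    FormatError,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ValidationError,
    merge_intervals,
    overlap_flags,
    overlap_pairs,
    read_bed,
    read_bedgraph,
    read_gene_table,
    shuffle_intervals,
    write_gene_table,
)

SIZES = ChromSizes({"chr1": 1_000_000, "chr2": 500_000, "chr3": 200_000})


def brute_force_pairs(a, b, min_overlap=1):
    """Independent oracle: plain all-pairs Python scan."""
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov >= min_overlap:
                out.append((i, j, ov))
    return sorted(out)


def random_set(rng, n, label="p"):
    ivs = []
    for k in range(n):
        chrom = rng.choice(list(SIZES))
        start = int(rng.integers(0, SIZES[chrom] - 5000))
        length = int(rng.integers(1, 5000))
        ivs.append(GenomicInterval(chrom, start, start + length, name=f"{label}{k}"))
    return PeakSet(label, ivs)


class TestIntervalModel:
    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 5)

    def test_length_and_midpoint_are_half_open(self):
        iv = GenomicInterval("chr1", 100, 201)
        assert iv.length == 101
        assert iv.midpoint == 150

    def test_overlap_respects_chromosomes(self):
        a = GenomicInterval("chr1", 100, 200)
        assert a.overlap(GenomicInterval("chr1", 150, 160)) == 10
        assert a.overlap(GenomicInterval("chr2", 100, 200)) == 0

    def test_gene_model_strand_conventions(self):
        GeneModel("g1", "S", "chr1", "+", 5000, 9000)
        GeneModel("g2", "S", "chr1", "-", 9000, 5000)  # minus strand: tss > tes
        with pytest.raises(ValidationError):
            GeneModel("g3", "S", "chr1", "+", 9000, 5000)
        with pytest.raises(ValidationError):
            GeneModel("g4", "S", "chr1", "-", 5000, 9000)


class TestBedIO:
    def test_single_line_maps_fields(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpk1\n")
        ps = read_bed(p)
        assert len(ps) == 1
        assert ps[0] == GenomicInterval("chr1", 100, 200, name="pk1")

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nchr1\t0\t10\n")
        assert len(read_bed(p)) == 1

    @pytest.mark.parametrize("line", ["chr1\tx\t200", "chr1\t300\t200", "chr1\t100"])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(FormatError, match=":2"):
            read_bed(p)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        ps = PeakSet("t", [
            GenomicInterval(
                rng.choice(["chr1", "chr2"]),
                int(s := rng.integers(0, 10_000)), int(s) + int(rng.integers(1, 500)),
                name=f"pk{k}", score=float(round(rng.uniform(0, 100), 3)),
                strand=rng.choice(["+", "-", "."]),
            )
            for k in range(1000)
        ])
        p = tmp_path / "rt.bed"
        ps.write_bed(p)
        assert read_bed(p, label="t") == ps


class TestGeneTable:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        genes = []
        for k in range(200):
            start = int(rng.integers(0, 90_000))
            end = start + int(rng.integers(1000, 5000))
            strand = rng.choice(["+", "-"])
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(f"g{k}", f"S{k}", "chr1", strand, tss, tes))
        p = tmp_path / "genes.tsv"
        write_gene_table(genes, p)
        assert read_gene_table(p) == genes

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\tchrom\tstrand\ttss\ttes\n"
                     "g1\tS\tchr1\t+\t0\t10\ng1\tS\tchr1\t+\t20\t30\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_gene_table(p)

    def test_strand_tss_inconsistency_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\tchrom\tstrand\ttss\ttes\n"
                     "g1\tS\tchr1\t-\t5000\t9000\n")
        with pytest.raises(FormatError):
            read_gene_table(p)


class TestBedgraph:
    def test_total_signal_is_value_times_width(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t10\t2.0\n")
        assert read_bedgraph(p).total_signal == pytest.approx(20.0)
        p.write_text("chr1\t0\t10\t1.0\nchr1\t20\t30\t3.0\n")
        assert read_bedgraph(p).total_signal == pytest.approx(40.0)

    def test_overlapping_steps_rejected(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t5\t15\t1.0\n")
        with pytest.raises(FormatError, match="overlap"):
            read_bedgraph(p)

    def test_unsorted_input_is_sorted(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t20\t30\t3.0\nchr1\t0\t10\t1.0\n")
        track = read_bedgraph(p)
        assert track.sum_range("chr1", 0, 30) == pytest.approx(40.0)

    def test_generated_track_matches_bookkeeping(self, tmp_path):
        rng = np.random.default_rng(11)
        rows, total = [], 0.0
        pos = 0
        for _ in range(500):
            pos += int(rng.integers(1, 50))
            w = int(rng.integers(1, 40))
            v = float(rng.uniform(0, 5))
            rows.append(("chr1", pos, pos + w, v))
            total += v * w
            pos += w
        track = CoverageTrack.from_steps(rows)
        assert track.total_signal == pytest.approx(total)

    def test_sum_range_partial_steps(self):
        track = CoverageTrack.from_steps([("chr1", 10, 20, 2.0), ("chr1", 30, 40, 1.0)])
        assert track.sum_range("chr1", 15, 35) == pytest.approx(2.0 * 5 + 1.0 * 5)
        assert track.sum_range("chr1", 0, 5) == 0.0
        assert track.sum_range("chrX", 0, 100) == 0.0


class TestOverlapEngine:
    def test_basic_pair_and_chrom_mismatch(self):
        a = PeakSet("a", [GenomicInterval("chr1", 100, 200)])
        assert overlap_pairs(a, PeakSet("b", [GenomicInterval("chr1", 150, 160)])) \
            == [(0, 0, 10)]
        assert overlap_pairs(a, PeakSet("b", [GenomicInterval("chr2", 100, 200)])) == []

    def test_min_overlap_threshold(self):
        a = PeakSet("a", [GenomicInterval("chr1", 0, 100)])
        b = PeakSet("b", [GenomicInterval("chr1", 90, 200)])
        assert overlap_pairs(a, b, min_overlap_bp=10) == [(0, 0, 10)]
        assert overlap_pairs(a, b, min_overlap_bp=11) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_set(rng, 300, "a")
        b = random_set(rng, 300, "b")
        got = overlap_pairs(a, b)
        assert got == brute_force_pairs(a, b)
        # symmetry: transpose of the reverse call
        rev = sorted((i, j, ov) for j, i, ov in overlap_pairs(b, a))
        assert rev == got

    def test_flags_agree_with_pairs(self):
        rng = np.random.default_rng(42)
        a = random_set(rng, 200, "a")
        b = random_set(rng, 200, "b")
        flags = overlap_flags(a, b)
        hit = {i for i, _j, _ov in overlap_pairs(a, b)}
        assert set(np.nonzero(flags)[0]) == hit

    def test_merge_intervals_with_gap(self):
        ps = PeakSet("p", [GenomicInterval("chr1", 0, 10),
                           GenomicInterval("chr1", 15, 25),
                           GenomicInterval("chr1", 100, 110)])
        merged = merge_intervals(ps, gap=5)
        assert [(m.start, m.end) for m in merged] == [(0, 25), (100, 110)]


class TestShuffle:
    def test_forced_placement_when_interval_fills_chromosome(self):
        sizes = ChromSizes({"c": 100})
        ps = PeakSet("p", [GenomicInterval("c", 0, 100)])
        out = shuffle_intervals(ps, sizes, seed=5)
        assert out[0].start == 0 and out[0].end == 100

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(0)
        ps = random_set(rng, 50)
        assert shuffle_intervals(ps, SIZES, seed=9) == shuffle_intervals(ps, SIZES, seed=9)

    def test_length_multiset_preserved(self):
        rng = np.random.default_rng(1)
        ps = random_set(rng, 100)
        out = shuffle_intervals(ps, SIZES, seed=2)
        assert sorted(iv.length for iv in out) == sorted(iv.length for iv in ps)

    def test_too_long_interval_rejected(self):
        sizes = ChromSizes({"c": 100})
        ps = PeakSet("p", [GenomicInterval("c", 0, 100)])
        with pytest.raises(ValidationError):
            shuffle_intervals(PeakSet("p", [GenomicInterval("c", 0, 100).shifted(0)]),
                              ChromSizes({"c": 50}), seed=0, match_chrom=False)
        with pytest.raises(ValidationError):
            shuffle_intervals(ps, ChromSizes({"c": 50}), seed=0)

    def test_start_distribution_uniform(self):
        """10,000 draws of a 100 bp interval on a 10 kb chromosome: chi-square
        against the uniform over the 9,901 valid starts, alpha = 0.01."""
        sizes = ChromSizes({"c": 10_000})
        template = PeakSet("p", [GenomicInterval("c", 0, 100)])
        rng = np.random.default_rng(123)
        starts = [shuffle_intervals(template, sizes, rng=rng)[0].start
                  for _ in range(10_000)]
        counts, _ = np.histogram(starts, bins=20, range=(0, 9901))
        _chi, p = stats.chisquare(counts)
        assert p > 0.01
        assert min(starts) >= 0 and max(starts) <= 9900


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(
    st.tuples(st.integers(0, 5000), st.integers(1, 300)), min_size=1, max_size=40,
))
def test_overlap_pairs_property_matches_oracle(spans):
    """Property: the sweep equals the brute-force scan on arbitrary inputs."""
    ivs = [GenomicInterval("chr1", s, s + w) for s, w in spans]
    a = PeakSet("a", ivs)
    b = PeakSet("b", list(reversed(ivs)))
    assert overlap_pairs(a, b) == brute_force_pairs(a, b)
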