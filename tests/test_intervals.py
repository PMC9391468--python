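"""Interval algebra against per-base brute-force oracles and bedtools."""

import subprocess

import numpy as np
import pytest

from thymotif.intervals import (
    CoverageTrack,
    GenomicInterval,
    IntervalError,
    IntervalSet,
    intersect_sets,
    mean_depth,
    merge_intervals,
    pad_intervals,
    subtract_intervals,
)
from thymotif import io as tio


def bases(s: IntervalSet) -> set[tuple[str, int]]:
    return {(iv.chrom, p) for iv in s for p in range(iv.start, iv.end)}


def random_set(rng, n=50, span=10_000, chroms=("chr1", "chr2")) -> IntervalSet:
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, span - 1))
        end = int(rng.integers(start + 1, min(span, start + 400) + 1))
        ivs.append(GenomicInterval(str(rng.choice(chroms)), start, end))
    return IntervalSet(ivs)


class TestMerge:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([("chr1", 10, 20), ("chr1", 15, 30)], [("chr1", 10, 30)]),
            ([("chr1", 10, 20), ("chr2", 10, 20)],
             [("chr1", 10, 20), ("chr2", 10, 20)]),
            # bookended half-open intervals coalesce
            ([("chr1", 10, 20), ("chr1", 20, 25)], [("chr1", 10, 25)]),
        ],
    )
    def test_examples(self, raw, expected):
        out = merge_intervals(IntervalSet.from_tuples(raw))
        assert out == IntervalSet.from_tuples(expected)

    def test_idempotent_and_base_preserving(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = random_set(rng, n=30, span=5000)
            m = merge_intervals(s)
            assert merge_intervals(m) == m
            assert bases(m) == bases(s)
            starts = [(iv.chrom, iv.start) for iv in m]
            assert starts == sorted(starts)

    def test_malformed_interval_names_record(self):
        with pytest.raises(IntervalError, match="chr1:30-20"):
            GenomicInterval("chr1", 30, 20)
        with pytest.raises(IntervalError, match="negative"):
            GenomicInterval("chr1", -1, 20)
        with pytest.raises(IntervalError, match="chromosome"):
            GenomicInterval("", 0, 20)


class TestIntersect:
    def test_examples(self):
        a = IntervalSet.from_tuples([("chr1", 10, 20)])
        b = IntervalSet.from_tuples([("chr1", 15, 30)])
        assert intersect_sets([a, b]) == IntervalSet.from_tuples([("chr1", 15, 20)])
        c = IntervalSet.from_tuples([("chr1", 30, 40)])
        assert len(intersect_sets([a, c])) == 0

    def test_three_way_matches_per_base_membership(self):
        sets = [
            IntervalSet.from_tuples([("chr1", 0, 100)]),
            IntervalSet.from_tuples([("chr1", 50, 150)]),
            IntervalSet.from_tuples([("chr1", 75, 200)]),
        ]
        out = intersect_sets(sets)
        assert out == IntervalSet.from_tuples([("chr1", 75, 100)])
        assert bases(out) == bases(sets[0]) & bases(sets[1]) & bases(sets[2])

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = random_set(rng, 25, 4000), random_set(rng, 25, 4000)
            assert bases(intersect_sets([a, b])) == bases(a) & bases(b)

    def test_fewer_than_two_sets_is_usage_error(self):
        with pytest.raises(IntervalError):
            intersect_sets([IntervalSet.from_tuples([("chr1", 0, 10)])])


class TestSubtract:
    def test_split_and_shadow(self):
        a = IntervalSet.from_tuples([("chr1", 10, 30)])
        assert subtract_intervals(
            a, IntervalSet.from_tuples([("chr1", 15, 20)])
        ) == IntervalSet.from_tuples([("chr1", 10, 15), ("chr1", 20, 30)])
        assert len(subtract_intervals(
            a, IntervalSet.from_tuples([("chr1", 0, 40)])
        )) == 0

    def test_random_instance_matches_brute_force(self):
        rng = np.random.default_rng(2)
        a, b = random_set(rng, 50, 8000), random_set(rng, 50, 8000)
        assert bases(subtract_intervals(a, b)) == bases(a) - bases(b)


class TestPad:
    def test_flank_20_and_clipping(self):
        sizes = {"chr1": 100_000}
        s = IntervalSet.from_tuples([("chr1", 100, 110)])
        assert pad_intervals(s, 20, sizes) == IntervalSet.from_tuples(
            [("chr1", 80, 130)]
        )
        edge = IntervalSet.from_tuples([("chr1", 5, 10)])
        assert pad_intervals(edge, 20, {"chr1": 100}) == IntervalSet.from_tuples(
            [("chr1", 0, 30)]
        )
        assert pad_intervals(s, 0, sizes) == s

    def test_unknown_chromosome_errors(self):
        s = IntervalSet.from_tuples([("chrX", 0, 10)])
        with pytest.raises(IntervalError, match="chrX"):
            pad_intervals(s, 5, {"chr1": 100})

    def test_pad_never_reduces_covered_bases(self):
        rng = np.random.default_rng(3)
        sizes = {"chr1": 10_000, "chr2": 10_000}
        for flank in (0, 5, 50):
            s = random_set(rng, 30, 9000)
            assert bases(s) <= bases(pad_intervals(s, flank, sizes))


class TestMeanDepth:
    def test_uniform_and_partial(self):
        track = CoverageTrack.from_records([("chr1", 0, 100, 2.0)])
        assert mean_depth(track, GenomicInterval("chr1", 0, 100)) == 2.0
        track2 = CoverageTrack.from_records([("chr1", 0, 10, 1.0)])
        assert mean_depth(track2, GenomicInterval("chr1", 0, 100)) == pytest.approx(0.1)

    def test_random_step_track_matches_per_base_mean(self):
        rng = np.random.default_rng(4)
        pos, records = 0, []
        while pos < 1500:
            step = int(rng.integers(5, 60))
            if rng.random() < 0.7:
                records.append(("chr1", pos, pos + step, float(rng.gamma(2, 1))))
            pos += step
        track = CoverageTrack.from_records(records)
        depth = np.zeros(2000)
        for _, s, e, d in records:
            depth[s:e] = d
        iv = GenomicInterval("chr1", 200, 1200)
        assert mean_depth(track, iv) == pytest.approx(
            depth[200:1200].mean(), abs=1e-9
        )

    def test_uncovered_switch(self):
        track = CoverageTrack.from_records([("chr1", 0, 10, 3.0)])
        iv = GenomicInterval("chr1", 0, 30)
        assert mean_depth(track, iv, uncovered="zero") == pytest.approx(1.0)
        assert mean_depth(track, iv, uncovered="nan") == pytest.approx(3.0)
        missing = GenomicInterval("chr2", 0, 10)
        assert mean_depth(track, missing) == 0.0
        assert np.isnan(mean_depth(track, missing, uncovered="nan"))


def test_merge_subtract_agree_with_bedtools(tmp_path):
    """Independent cross-check against the tool the protocol itself used."""
    rng = np.random.default_rng(7)
    a, b = random_set(rng, 40, 6000), random_set(rng, 40, 6000)
    pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
    tio.write_bed(pa, merge_intervals(a))
    tio.write_bed(pb, merge_intervals(b))

    def run(args):
        out = subprocess.run(args, capture_output=True, text=True, check=True).stdout
        ivs = [ln.split("\t") for ln in out.strip().splitlines() if ln]
        return IntervalSet.from_tuples((c, int(s), int(e)) for c, s, e in ivs)

    assert run(["bedtools", "merge", "-i", str(pa)]) == merge_intervals(a)
    got = run(["bedtools", "subtract", "-a", str(pa), "-b", str(pb)])
    assert bases(got) == bases(a) - bases(b)


class TestIO:
    def test_bed_roundtrip_preserves_extras(self, tmp_path):
        p = tmp_path / "x.bed"
        ivs = IntervalSet.from_tuples([("chr1", 0, 10), ("chr2", 5, 9)])
        tio.write_bed(p, ivs, extras=[["peak1", "7.5"], ["peak2", "3.0"]])
        back, extras = tio.read_bed(p)
        assert back == ivs and extras == [["peak1", "7.5"], ["peak2", "3.0"]]

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "x.bed.gz"
        ivs = IntervalSet.from_tuples([("chr1", 0, 10)])
        tio.write_bed(p, ivs)
        assert tio.read_bed(p)[0] == ivs

    def test_gff_exons_are_converted_to_half_open(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\texon\t11\t20\t.\t+\t.\tID=e1\n"
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        )
        exons = tio.read_gff_exons(p)
        assert exons == IntervalSet.from_tuples([("chr1", 10, 20)])

    def test_bedgraph_and_chrom_sizes_roundtrip(self, tmp_path):
        track = CoverageTrack.from_records(
            [("chr1", 0, 10, 1.5), ("chr1", 20, 30, 0.5)]
        )
        pb = tmp_path / "c.bedGraph"
        tio.write_bedgraph(pb, track)
        back = tio.read_bedgraph(pb)
        assert np.allclose(back.runs["chr1"], track.runs["chr1"])
        ps = tmp_path / "g.sizes"
        tio.write_chrom_sizes(ps, {"chr1": 1000})
        assert tio.read_chrom_sizes(ps) == {"chr1": 1000}
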