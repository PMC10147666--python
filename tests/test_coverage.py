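import numpy as np
import pytest

from conftest import make_track, naive_region_stat, random_track_and_mask
from epivector.coverage import (deduplicate, per_base_cpm_track,
                                read_bedgraph, region_coverage_stat,
                                write_bedgraph)
from epivector.errors import ParseError, ValidationError
from epivector.fragments import FragmentRecord, FragmentSet
from epivector.genome import IntervalSet


def fragset(meta, triples, dedup=False):
    return FragmentSet.from_records(
        [FragmentRecord(c, s, e, st) for c, s, e, st in triples], meta,
        dedup_applied=dedup)


class TestDeduplicate:
    def test_exact_duplicates_collapsed(self, meta):
        fs = fragset(meta, [("gAAV", 0, 10, "+"), ("gAAV", 0, 10, "+"),
                            ("gAAV", 0, 10, "-"), ("chrH", 5, 9, "+"),
                            ("gAAV", 20, 40, "+")])
        out = deduplicate(fs)
        # brute-force set oracle
        assert len(out) == len({("gAAV", 0, 10, "+"), ("gAAV", 0, 10, "-"),
                                ("chrH", 5, 9, "+"), ("gAAV", 20, 40, "+")})
        assert out.dedup_applied

    def test_no_duplicates_is_identity(self, meta):
        fs = fragset(meta, [("gAAV", 0, 10, "+"), ("gAAV", 0, 11, "+")])
        assert deduplicate(fs).key_multiset() == fs.key_multiset()

    def test_idempotent(self, meta):
        fs = fragset(meta, [("gAAV", 0, 10, "+")] * 3 + [("chrH", 1, 2, "-")])
        once = deduplicate(fs)
        with pytest.raises(ValidationError):
            deduplicate(once)  # flag blocks a second pass by contract
        # but forcing a second pass changes nothing
        again = deduplicate(FragmentSet(once.meta, once.contig, once.start,
                                        once.end, once.strand))
        assert again.key_multiset() == once.key_multiset()

    def test_empty_input_allowed(self, meta):
        out = deduplicate(fragset(meta, []))
        assert len(out) == 0


class TestCpmTrack:
    def test_single_fragment_track_is_1e6(self, build, meta):
        fs = fragset(meta, [("gAAV", 10, 20, "+")], dedup=True)
        track = per_base_cpm_track(fs, build, "gAAV")
        assert list(track.starts) == [10]
        assert list(track.ends) == [20]
        assert list(track.values) == [1e6]

    def test_overlapping_fragments_per_base_counting(self, build, meta):
        fs = fragset(meta, [("gAAV", 0, 10, "+"), ("gAAV", 5, 15, "+")],
                     dedup=True)
        track = per_base_cpm_track(fs, build, "gAAV")
        assert list(track.starts) == [0, 5, 10]
        assert list(track.ends) == [5, 10, 15]
        assert list(track.values) == [5e5, 1e6, 5e5]

    def test_n_counts_all_contigs(self, build, meta):
        fs = fragset(meta, [("gAAV", 0, 10, "+"), ("chrH", 0, 10, "+")],
                     dedup=True)
        track = per_base_cpm_track(fs, build, "gAAV")
        assert list(track.values) == [5e5]
        assert track.total_fragments_used == 2

    def test_cpm_invariant_under_library_duplication(self, build, meta):
        base = [("gAAV", 0, 10, "+"), ("gAAV", 5, 30, "-"),
                ("chrH", 100, 200, "+")]
        fs1 = fragset(meta, base, dedup=True)
        fs2 = fragset(meta, base * 2, dedup=False)
        t1 = per_base_cpm_track(fs1, build, "gAAV")
        t2 = per_base_cpm_track(fs2, build, "gAAV", require_dedup=False)
        assert t1.equals(t2)

    def test_track_independent_of_record_order(self, build, meta):
        rng = np.random.default_rng(0)
        base = [("gAAV", int(s), int(s) + 50, "+")
                for s in rng.integers(0, 3000, size=200)]
        perm = [base[i] for i in rng.permutation(len(base))]
        t1 = per_base_cpm_track(deduplicate(fragset(meta, base)), build,
                                "gAAV")
        t2 = per_base_cpm_track(deduplicate(fragset(meta, perm)), build,
                                "gAAV")
        assert t1.equals(t2)

    def test_dedup_required_and_empty_library_rejected(self, build, meta):
        fs = fragset(meta, [("gAAV", 0, 10, "+")])
        with pytest.raises(ValidationError):
            per_base_cpm_track(fs, build, "gAAV")
        with pytest.raises(ValidationError):
            per_base_cpm_track(fragset(meta, [], dedup=True), build, "gAAV")


class TestBedgraph:
    def test_format_line(self, tmp_path):
        track = make_track([(0, 5, 2.0)], length=10)
        write_bedgraph(track, tmp_path / "t.bedgraph")
        assert (tmp_path / "t.bedgraph").read_text() == "gAAV\t0\t5\t2.0\n"

    def test_round_trip_preserves_statistic_exactly(self, tmp_path):
        rng = np.random.default_rng(1)
        track, length, mask = random_track_and_mask(rng)
        write_bedgraph(track, tmp_path / "t.bedgraph")
        back = read_bedgraph(tmp_path / "t.bedgraph", contig_length=length)
        for mode in ("unmasked_length", "full_gAAV_size"):
            a = region_coverage_stat(track, length, mask, mode)
            b = region_coverage_stat(back, length, mask, mode)
            assert a.raw_value == b.raw_value

    def test_overlapping_intervals_rejected_on_read(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("gAAV\t0\t10\t1.0\ngAAV\t5\t15\t2.0\n")
        with pytest.raises(ParseError):
            read_bedgraph(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("gAAV\t0\t10\t1.0\ngAAV\tnope\t15\t2.0\n")
        with pytest.raises(ParseError) as exc:
            read_bedgraph(p)
        assert exc.value.line_number == 2


class TestRegionStat:
    def test_constant_track_mean_is_the_constant(self):
        track = make_track([(0, 2000, 2.5)], length=2000)
        for mode in ("unmasked_length", "full_gAAV_size"):
            stat = region_coverage_stat(track, 2000, None, mode)
            assert stat.raw_value == pytest.approx(2.5)

    def test_partial_track_against_hand_value(self):
        track = make_track([(0, 100, 10.0)], length=2000)
        stat = region_coverage_stat(track, 2000, None, "unmasked_length")
        assert stat.raw_value == pytest.approx(0.5)  # 1000/2000

    def test_mask_splits_intervals_at_boundaries(self):
        track = make_track([(0, 100, 10.0)], length=2000)
        mask = IntervalSet.from_intervals([("gAAV", 0, 50)])
        um = region_coverage_stat(track, 2000, mask, "unmasked_length")
        assert um.raw_value == pytest.approx((10 * 50) / 1950)  # ~0.25641
        full = region_coverage_stat(track, 2000, mask, "full_gAAV_size")
        assert full.raw_value == pytest.approx(0.25)
        assert um.masked_length == full.masked_length == 50

    def test_oracle_equivalence_on_randomized_fixtures(self):
        """Interval arithmetic equals a naive per-base loop (1e-9 rel)."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            track, length, mask = random_track_and_mask(rng)
            for mode in ("unmasked_length", "full_gAAV_size"):
                expected = naive_region_stat(
                    track, length, mask.on_contig("gAAV"), mode)
                got = region_coverage_stat(track, length, mask, mode).raw_value
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_mask_growth_full_size_mode_non_increasing(self):
        track = make_track([(0, 100, 10.0), (150, 300, 4.0)], length=400)
        prev = np.inf
        for end in (10, 60, 120, 200, 350):
            mask = IntervalSet.from_intervals([("gAAV", 0, end)])
            v = region_coverage_stat(track, 400, mask,
                                     "full_gAAV_size").raw_value
            assert v <= prev + 1e-12
            prev = v

    def test_constant_track_value_preserved_under_any_mask(self):
        track = make_track([(0, 400, 7.0)], length=400)
        for iv in [("gAAV", 0, 50), ("gAAV", 100, 399), ("gAAV", 5, 6)]:
            mask = IntervalSet.from_intervals([iv])
            v = region_coverage_stat(track, 400, mask,
                                     "unmasked_length").raw_value
            assert v == pytest.approx(7.0)

    def test_preconditions(self):
        track = make_track([(0, 100, 1.0)], length=100)
        with pytest.raises(ValidationError):
            region_coverage_stat(track, 50, None)  # region < extent
        mask = IntervalSet.from_intervals([("chrH", 0, 10)])
        with pytest.raises(ValidationError):
            region_coverage_stat(track, 100, mask)  # mask on other contig
        full_mask = IntervalSet.from_intervals([("gAAV", 0, 100)])
        with pytest.raises(ValidationError):
            region_coverage_stat(track, 100, full_mask, "unmasked_length")
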