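from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hairpinscan import (
    FilterConfig,
    PropensityProfile,
    ProteinRecord,
    composition_check,
    enumerate_pairs,
    find_stretches,
    ilv_fraction,
    length_filter,
    scan,
)
from hairpinscan.hairpin_filter import Stretch
from hairpinscan.sequence_io import AlignmentError

from brute_oracle import brute_scan, random_instance
from conftest import as_candidate_coords


def profile(scores, pid="P1"):
    return PropensityProfile(protein_id=pid, scores=tuple(scores))


def stretch(start, end, seq=None):
    length = end - start + 1
    return Stretch(start=start, end=end, subsequence=seq or "A" * length, mean_score=2.0)


class TestFindStretches:
    def test_single_interior_run(self, config):
        out = find_stretches(profile([0, 0, 5, 5, 5, 5, 5, 0]), config)
        assert [(s.start, s.end, s.length) for s in out] == [(3, 7, 5)]

    def test_all_zero_profile_empty(self, config):
        assert find_stretches(profile([0.0] * 12), config) == []

    def test_threshold_value_excluded_when_strict(self, config):
        out = find_stretches(profile([2, 1.06, 2]), config)
        assert [(s.start, s.end) for s in out] == [(1, 1), (3, 3)]

    def test_threshold_value_included_when_not_strict(self):
        cfg = FilterConfig(strict_greater=False)
        out = find_stretches(profile([2, 1.06, 2]), cfg)
        assert [(s.start, s.end) for s in out] == [(1, 3)]

    def test_run_reaching_sequence_end(self, config):
        out = find_stretches(profile([0, 9, 9]), config)
        assert [(s.start, s.end) for s in out] == [(2, 3)]

    def test_subsequence_and_mean_score(self, config):
        (s,) = find_stretches(profile([0, 4, 6, 0]), config, sequence="AKVG")
        assert s.subsequence == "KV"
        assert s.mean_score == pytest.approx(5.0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 1.0, 1.06, 1.5, 40.0]), min_size=1, max_size=50))
    def test_maximality_and_disjointness(self, scores):
        cfg = FilterConfig()
        out = find_stretches(profile(scores), cfg)
        covered = set()
        for s in out:
            for pos in range(s.start, s.end + 1):
                assert pos not in covered
                covered.add(pos)
                assert scores[pos - 1] > cfg.propensity_threshold
            if s.start > 1:
                assert scores[s.start - 2] <= cfg.propensity_threshold
            if s.end < len(scores):
                assert scores[s.end] <= cfg.propensity_threshold

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
        st.floats(0, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    def test_raising_threshold_never_grows_coverage(self, scores, t1, t2):
        lo, hi = sorted((t1, t2))
        n_lo = sum(s.length for s in find_stretches(profile(scores), FilterConfig(propensity_threshold=lo)))
        n_hi = sum(s.length for s in find_stretches(profile(scores), FilterConfig(propensity_threshold=hi)))
        assert n_hi <= n_lo


class TestLengthFilter:
    def test_inclusive_bounds_5_and_23(self, config):
        stretches = [stretch(1, 4), stretch(10, 14), stretch(30, 52), stretch(60, 83)]
        kept = length_filter(stretches, config)
        assert [s.length for s in kept] == [5, 23]

    def test_empty_and_uniform(self, config):
        assert length_filter([], config) == []
        ten = [stretch(1, 10), stretch(20, 29)]
        assert length_filter(ten, config) == ten


class TestEnumeratePairs:
    def test_gap_three_pairs(self, config):
        pairs = enumerate_pairs([stretch(1, 5), stretch(9, 13)], profile([0] * 13), config)
        assert len(pairs) == 1 and pairs[0][2] == 3

    def test_gap_ten_rejected(self, config):
        pairs = enumerate_pairs([stretch(1, 5), stretch(16, 20)], profile([0] * 20), config)
        assert pairs == []

    def test_middle_stretch_serves_both_roles(self, config):
        a, b, c = stretch(1, 5), stretch(8, 12), stretch(16, 20)
        pairs = enumerate_pairs([a, b, c], profile([0] * 20), config)
        assert [(p[0].start, p[1].start) for p in pairs] == [(1, 8), (8, 16)]

    def test_turn_requires_zero_switch(self):
        cfg = FilterConfig(turn_requires_zero=True)
        scores = [9] * 5 + [0, 0.5, 0] + [9] * 5
        strs = [stretch(1, 5), stretch(9, 13)]
        assert enumerate_pairs(strs, profile(scores), cfg) == []
        scores[6] = 0.0
        assert len(enumerate_pairs(strs, profile(scores), cfg)) == 1


class TestComposition:
    @pytest.mark.parametrize(
        "segment,expected",
        [("ILVILV", Fraction(1)), ("AAAAA", Fraction(0)), ("KLVFFAEDV", Fraction(3, 9))],
    )
    def test_ilv_fraction_exact(self, segment, expected, config):
        assert ilv_fraction(segment, config) == expected

    def test_empty_segment_rejected(self, config):
        with pytest.raises(ValueError):
            ilv_fraction("", config)

    def test_no_aromatic_raises_C4_1(self, config):
        _, reasons = composition_check(stretch(1, 5, "AALVL"), stretch(10, 14, "GILVA"), config)
        assert "C4_1" in reasons
        # with the ILV fraction inside its window, C4_1 is the sole reason
        _, reasons = composition_check(stretch(1, 5, "AATVL"), stretch(10, 14, "GILVA"), config)
        assert reasons == ["C4_1"]

    def test_n_ilv_over_half_raises_C4_2(self, config):
        _, reasons = composition_check(stretch(1, 5, "FLVLA"), stretch(10, 14, "GILVA"), config)
        assert reasons == ["C4_2"]

    def test_c_strand_point_six_ilv_passes(self, config):
        metrics, reasons = composition_check(stretch(1, 5, "FLVAA"), stretch(10, 14, "GILVA"), config)
        assert reasons == []
        assert metrics.c_ilv_fraction == Fraction(3, 5)

    def test_gly_bounds_inclusive(self, config):
        for c_seq, ok in [("GILVA", True), ("GGGIL", True), ("AILVA", False), ("GGGGI", False)]:
            _, reasons = composition_check(stretch(1, 5, "FLVAA"), stretch(10, 14, c_seq), config)
            assert ("C5_1" not in reasons) is ok, c_seq

    def test_exact_rational_boundary_8_of_25(self, config):
        n_seq = "F" + "L" * 8 + "A" * 16  # 8/25 == 0.32 exactly
        c_seq = "G" + "V" * 8 + "A" * 16
        _, reasons = composition_check(stretch(1, 25, n_seq), stretch(30, 54, c_seq), config)
        assert reasons == []

    def test_failure_reason_order_is_fixed(self, config):
        _, reasons = composition_check(stretch(1, 5, "AAAAA"), stretch(10, 14, "AAAAA"), config)
        assert reasons == ["C4_1", "C4_2", "C5_1", "C5_2"]

    def test_nonstandard_residues_count_length_not_class(self, config):
        # X/U/B/Z/O never count as aromatic, ILV or Gly but do count as length
        metrics, _ = composition_check(stretch(1, 5, "FXLVU"), stretch(10, 14, "GBLVZ"), config)
        assert metrics.n_aromatic == 1
        assert metrics.n_ilv_fraction == Fraction(2, 5)
        assert metrics.c_gly == 1


class TestScan:
    def test_alignment_mismatch_rejected(self, config):
        rec = ProteinRecord(id="A", sequence="MKV")
        with pytest.raises(AlignmentError):
            scan(rec, profile([0, 1]), config)

    def test_all_zero_profile_empty(self, make_pair, config):
        rec, prof = make_pair("MKVLFFAEDVGSNKGA", [0] * 16)
        assert scan(rec, prof, config) == []

    def test_single_spanning_stretch_no_pair(self, make_pair, config):
        rec, prof = make_pair("FLVAAGILVA", [9] * 10)
        assert scan(rec, prof, config) == []
        # length 10 stretch passes the length filter but has no partner
        assert scan(rec, prof, config, include_failed=True) == []

    def test_planted_motif_and_single_decoy(self, config):
        # strands FLVAA / GFLVA separated by 3-residue turn; the middle
        # stretch also serves as N-strand of a decoy pair whose C-strand
        # lacks glycine
        seq = "PPP" + "FLVAA" + "SSS" + "GFLVA" + "PPPP" + "AILVA" + "PP"
        scores = [0] * 3 + [9] * 5 + [0] * 3 + [9] * 5 + [0] * 4 + [9] * 5 + [0] * 2
        rec = ProteinRecord(id="A", sequence=seq)
        prof = profile(scores, "A")
        passing = scan(rec, prof, config)
        assert as_candidate_coords(passing) == [(4, 8, 12, 16)]
        everything = scan(rec, prof, config, include_failed=True)
        assert len(everything) == 2
        failed = [c for c in everything if not c.passed]
        assert failed[0].failure_reasons == ("C5_1",)

    def test_passing_candidates_reassert_all_criteria(self, config):
        rng = np.random.default_rng(11)
        for _ in range(300):
            seq, scores = random_instance(rng)
            rec = ProteinRecord(id="R", sequence=seq)
            for c in scan(rec, profile(scores, "R"), config):
                assert 5 <= c.n_strand.length <= 23
                assert 5 <= c.c_strand.length <= 23
                assert 1 <= c.turn_len <= 9
                assert c.turn_len == c.c_strand.start - c.n_strand.end - 1
                assert c.metrics.n_aromatic >= 1
                assert Fraction("0.32") <= c.metrics.n_ilv_fraction <= Fraction("0.5")
                assert 1 <= c.metrics.c_gly <= 3
                assert Fraction("0.32") <= c.metrics.c_ilv_fraction <= Fraction("0.61")

    def test_matches_brute_force_on_random_instances(self, config):
        rng = np.random.default_rng(202)
        for _ in range(300):
            seq, scores = random_instance(rng)
            rec = ProteinRecord(id="R", sequence=seq)
            got = as_candidate_coords(scan(rec, profile(scores, "R"), config))
            want = [(a, b, c, d) for a, b, c, d in brute_scan(seq, scores)]
            assert got == want, (seq, scores)

    def test_matches_brute_force_under_nonstrict_threshold(self):
        cfg = FilterConfig(strict_greater=False)
        rng = np.random.default_rng(203)
        for _ in range(150):
            seq, scores = random_instance(rng)
            rec = ProteinRecord(id="R", sequence=seq)
            got = as_candidate_coords(scan(rec, profile(scores, "R"), cfg))
            assert got == brute_scan(seq, scores, strict=False)

    def test_shuffling_scores_within_stretches_is_invisible(self, config):
        rng = np.random.default_rng(7)
        for _ in range(100):
            seq, scores = random_instance(rng)
            rec = ProteinRecord(id="R", sequence=seq)
            base = as_candidate_coords(scan(rec, profile(scores, "R"), config))
            shuffled = list(scores)
            for s in find_stretches(profile(scores), config):
                block = shuffled[s.start - 1 : s.end]
                rng.shuffle(block)
                shuffled[s.start - 1 : s.end] = block
            assert as_candidate_coords(scan(rec, profile(shuffled, "R"), config)) == base


class TestFilterConfig:
    def test_defaults_encode_published_criteria(self, config):
        assert config.propensity_threshold == 1.06
        assert (config.min_stretch_len, config.max_stretch_len) == (5, 23)
        assert config.max_turn_len == 9
        assert (config.n_ilv_lo, config.n_ilv_hi) == (0.32, 0.50)
        assert (config.c_gly_lo, config.c_gly_hi) == (1, 3)
        assert (config.c_ilv_lo, config.c_ilv_hi) == (0.32, 0.61)
        assert config.aromatic_set == frozenset("FWY")

    def test_yaml_roundtrip(self, tmp_path, config):
        path = tmp_path / "cfg.yaml"
        cfg = FilterConfig(strict_greater=False, max_turn_len=7, aromatic_set=frozenset("FWYH"))
        cfg.to_yaml(path)
        assert FilterConfig.from_yaml(path) == cfg

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(min_stretch_len=10, max_stretch_len=5)
        with pytest.raises(ValueError):
            FilterConfig(n_ilv_lo=0.6, n_ilv_hi=0.3)
        with pytest.raises(ValueError):
            FilterConfig(c_gly_lo=4, c_gly_hi=2)
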