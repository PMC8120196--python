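from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipins.clip_screen import (
    ScreenConfig,
    SoftClip,
    corresponding_ref_segment,
    extract_softclips,
    local_match_score,
    screen_clip,
)
from clipins.io_alignment import ReferenceAccessor
from conftest import make_read
from oracles import brute_longest_common_substring

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestExtractSoftclips:
    def test_unclipped_read_yields_nothing(self):
        assert extract_softclips(make_read(cigar=[("M", 150)])) == []

    def test_head_clip_position_and_sequence(self):
        read = make_read(pos=1000, cigar=[("S", 30), ("M", 120)])
        (clip,) = extract_softclips(read)
        assert clip.side == "head"
        assert clip.ref_pos == 1000
        assert clip.clipped_seq == read.seq[:30]

    def test_tail_clip_boundary_is_alignment_end(self):
        read = make_read(pos=1000, cigar=[("M", 120), ("S", 30)])
        (clip,) = extract_softclips(read)
        assert clip.side == "tail"
        assert clip.ref_pos == 1120
        assert clip.clipped_seq == read.seq[-30:]

    def test_double_clip(self):
        read = make_read(cigar=[("S", 20), ("M", 110), ("S", 20)])
        clips = extract_softclips(read)
        assert [c.side for c in clips] == ["head", "tail"]

    def test_short_clips_dropped(self):
        read = make_read(cigar=[("S", 5), ("M", 145)])
        assert extract_softclips(read, min_clip_len=10) == []
        assert len(extract_softclips(read, min_clip_len=5)) == 1

    @pytest.mark.parametrize(
        "pos,mate_pos,is_read1,expected",
        [(1000, 2000, True, "left"), (2000, 1000, True, "right"), (1500, 1500, True, "left"), (1500, 1500, False, "right")],
    )
    def test_mate_role(self, pos, mate_pos, is_read1, expected):
        read = make_read(pos=pos, mate_pos=mate_pos, is_read1=is_read1, cigar=[("S", 20), ("M", 130)])
        (clip,) = extract_softclips(read)
        assert clip.mate_role == expected


class TestCorrespondingRefSegment:
    ref = ReferenceAccessor({"c": "".join(_rand_seq(np.random.default_rng(0), 200))})

    def _clip(self, side, ref_pos, n):
        return SoftClip("r", "c", side, ref_pos, "A" * n, "left")

    def test_head_uses_left_flank(self):
        seg = corresponding_ref_segment(self._clip("head", 100, 5), self.ref)
        assert seg == self.ref.fetch("c", 95, 100)

    def test_tail_uses_right_flank(self):
        seg = corresponding_ref_segment(self._clip("tail", 100, 5), self.ref)
        assert seg == self.ref.fetch("c", 100, 105)

    def test_truncated_at_contig_end(self):
        seg = corresponding_ref_segment(self._clip("tail", 190, 30), self.ref)
        assert seg == self.ref.fetch("c", 190, 200)
        assert len(seg) == 10


class TestLocalMatchScore:
    def test_identity_and_disjoint(self):
        assert local_match_score("ACGT", "ACGT") == 4
        assert local_match_score("AAAA", "CCCC") == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_match_score("", "ACGT")

    def test_ambiguity_never_matches(self):
        assert local_match_score("NNNN", "NNNN") == 0

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            s1 = _rand_seq(rng, int(rng.integers(5, 41)))
            s2 = _rand_seq(rng, int(rng.integers(5, 41)))
            assert local_match_score(s1, s2) == brute_longest_common_substring(s1, s2)

    @settings(deadline=None, derandomize=True)
    @given(dna, dna)
    def test_symmetric_and_bounded(self, s1, s2):
        score = local_match_score(s1, s2)
        assert score == local_match_score(s2, s1)
        assert 0 <= score <= min(len(s1), len(s2))
        assert local_match_score(s1, s1) == len(s1)

    def test_standard_sw_scoring_path(self):
        # full-length alignment, 5 matches and 1 mismatch under +1/-1/-1
        assert local_match_score("ACACAC", "ACGCAC", sw_mismatch=-1, sw_gap=-1) == 4
        # a gap buys back the frame shift: ACGT vs AGT aligns A-GT
        assert local_match_score("ACGT", "AGT", sw_mismatch=-1, sw_gap=-1) == 2


def _mk_clip(seq):
    return SoftClip("r", "c", "head", 100, seq, "left")


class TestScreenClip:
    cfg = ScreenConfig(m=0.5)

    def test_dissimilar_clip_kept(self):
        assert screen_clip(_mk_clip("ACGTACGTAC"), "TTTTTTTTTT", self.cfg)

    def test_identical_clip_discarded(self):
        assert not screen_clip(_mk_clip("ACGTACGTAC"), "ACGTACGTAC", self.cfg)

    def test_controlled_shared_run_straddles_threshold(self):
        # S_c over {A,C}, S_r over {G,T} except a spliced copy of a run of
        # S_c: the longest common substring is exactly that run.
        rng = np.random.default_rng(5)
        s_c = "".join(np.array(list("AC"))[rng.integers(0, 2, 20)])
        gt = "".join(np.array(list("GT"))[rng.integers(0, 2, 20)])
        for run_len, expect_keep in [(9, True), (11, False)]:
            run = s_c[3 : 3 + run_len]
            s_r = gt[:4] + run + gt[4 + run_len :]
            score = local_match_score(s_c, s_r)
            assert score == run_len
            assert screen_clip(_mk_clip(s_c), s_r, self.cfg) is expect_keep

    def test_raising_m_never_discards_kept_clips(self):
        rng = np.random.default_rng(9)
        clips = [_mk_clip(_rand_seq(rng, 20)) for _ in range(50)]
        refs = [_rand_seq(rng, 20) for _ in range(50)]
        kept_sets = []
        for m in (0.2, 0.5, 0.8):
            cfg = ScreenConfig(m=m)
            kept_sets.append({i for i, (c, r) in enumerate(zip(clips, refs)) if screen_clip(c, r, cfg)})
        assert kept_sets[0] <= kept_sets[1] <= kept_sets[2]

    def test_invert_flag_flips_decision(self):
        cfg = ScreenConfig(m=0.5, invert=True)
        assert screen_clip(_mk_clip("ACGTACGTAC"), "ACGTACGTAC", cfg)

    def test_empty_reference_segment_discards(self):
        assert not screen_clip(_mk_clip("ACGTACGTAC"), "", self.cfg)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(m=1.5)
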