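"""Soft-clip extraction and the clipped-sequence similarity screen.

A soft-clipped read end is the primary signature of an insertion breakpoint:
the clipped bases come from inserted sequence and therefore should NOT
resemble the reference continuation they would occupy if the read carried no
insertion.  Each clip's sequence ``S_c`` is scored against the corresponding
reference segment ``S_r`` (same length, on the clipped side) with a
Smith-Waterman local alignment; under the default scoring the optimum equals
the length of the longest common substring.  A clip is kept when

    max_score < len(S_c) * m

with mappability threshold ``m`` in [0, 1] (default 0.5): clips that look
like the local reference are alignment noise, clips that do not are insertion
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_alignment import AlignedRead, ReferenceAccessor

__all__ = [
    "SoftClip",
    "ScreenConfig",
    "extract_softclips",
    "corresponding_ref_segment",
    "local_match_score",
    "screen_clip",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SoftClip:
    """One clipped read end.

    ``ref_pos`` is the clip boundary: for a head clip the leftmost aligned
    base of the read, for a tail clip one past the rightmost aligned base.
    ``mate_role`` records which mate of the pair this read is by coordinate
    (left/right); together with ``side`` it determines the clip type used by
    the breakpoint caller.
    """

    read_name: str
    contig: str
    side: Literal["head", "tail"]
    ref_pos: int
    clipped_seq: str
    mate_role: Literal["left", "right"]
    clip_type: str | None = None


@dataclass
class ScreenConfig:
    """Parameters of the clipped-sequence screen.

    ``sw_mismatch``/``sw_gap`` of ``None`` select the longest-common-substring
    scoring (mismatch and gap effectively forbidden); numeric values give
    standard Smith-Waterman scoring for sensitivity analysis.
    """

    m: float = 0.5
    min_clip_len: int = 10
    sw_match: int = 1
    sw_mismatch: int | None = None
    sw_gap: int | None = None
    invert: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"mappability threshold m must be in [0, 1], got {self.m}")
        if self.min_clip_len < 1:
            raise ValueError("min_clip_len must be >= 1")


def extract_softclips(read: AlignedRead, min_clip_len: int = 10) -> list[SoftClip]:
    """Return the 0, 1 or 2 terminal soft-clips of a mapped read.

    Only ``S`` operations count (hard-clipped sequence is unavailable).  The
    mate role is left when this read's position precedes its mate's, right
    when it follows; a positional tie goes to read1 = left.
    """
    if not read.is_mapped or not read.cigar:
        return []
    if read.mate_pos is None or read.pos < read.mate_pos:
        role = "left"
    elif read.pos > read.mate_pos:
        role = "right"
    else:
        role = "left" if read.is_read1 else "right"
    clips: list[SoftClip] = []
    head_op, head_len = read.cigar[0]
    if head_op == "S" and head_len >= min_clip_len:
        clips.append(
            SoftClip(
                read_name=read.query_name,
                contig=read.contig,
                side="head",
                ref_pos=read.pos,
                clipped_seq=read.seq[:head_len],
                mate_role=role,
            )
        )
    tail_op, tail_len = read.cigar[-1]
    if tail_op == "S" and tail_len >= min_clip_len and len(read.cigar) > 1:
        clips.append(
            SoftClip(
                read_name=read.query_name,
                contig=read.contig,
                side="tail",
                ref_pos=read.reference_end,
                clipped_seq=read.seq[len(read.seq) - tail_len :],
                mate_role=role,
            )
        )
    return clips


def corresponding_ref_segment(clip: SoftClip, reference: ReferenceAccessor) -> str:
    """Reference segment the clipped bases would occupy absent an insertion.

    Head clip: the ``len(S_c)`` bases immediately left of the boundary; tail
    clip: immediately right.  Truncated at contig edges, so the result can be
    shorter than the clip.
    """
    n = len(clip.clipped_seq)
    contig_len = reference.length(clip.contig)
    if clip.side == "head":
        start = max(0, clip.ref_pos - n)
        end = max(0, min(clip.ref_pos, contig_len))
    else:
        start = min(clip.ref_pos, contig_len)
        end = min(clip.ref_pos + n, contig_len)
    if start >= end:
        return ""
    return reference.fetch(clip.contig, start, end)


def _longest_common_run(s1: str, s2: str) -> int:
    """Length of the longest common substring, via the diagonal DP.

    This equals the Smith-Waterman maximum with match=+1 and prohibitive
    mismatch/gap penalties.  Vectorised over one sequence per DP row.
    """
    a = np.array([_BASE_CODE.get(b, -1) for b in s1], dtype=np.int16)
    b = np.array([_BASE_CODE.get(c, -2) for c in s2], dtype=np.int16)
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    for i in range(len(a)):
        match = b == a[i]
        cur = np.zeros_like(prev)
        cur[0] = 1 if match[0] else 0
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def _smith_waterman(s1: str, s2: str, match: int, mismatch: int, gap: int) -> int:
    """Plain O(nm) Smith-Waterman maximum score (linear gap penalty)."""
    n, m = len(s1), len(s2)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        ci = s1[i - 1]
        row = H[i]
        prev_row = H[i - 1]
        for j in range(1, m + 1):
            cj = s2[j - 1]
            s = match if (ci == cj and ci in "ACGT") else mismatch
            v = max(0, prev_row[j - 1] + s, prev_row[j] + gap, row[j - 1] + gap)
            row[j] = v
            if v > best:
                best = v
    return best


def local_match_score(
    s1: str,
    s2: str,
    sw_match: int = 1,
    sw_mismatch: int | None = None,
    sw_gap: int | None = None,
) -> int:
    """Maximum local-alignment score between two sequences.

    With the default scoring (mismatch/gap = None, i.e. prohibitive) this is
    exactly the length of the longest run of consecutive matching bases — the
    longest common substring.  Ambiguity bases never match.
    """
    if not s1 or not s2:
        raise ValueError("local_match_score requires non-empty sequences")
    if sw_mismatch is None and sw_gap is None and sw_match == 1:
        return _longest_common_run(s1.upper(), s2.upper())
    forbid = -(max(len(s1), len(s2)) + 1)
    return _smith_waterman(
        s1.upper(),
        s2.upper(),
        sw_match,
        forbid if sw_mismatch is None else sw_mismatch,
        forbid if sw_gap is None else sw_gap,
    )


def screen_clip(clip: SoftClip, s_r: str, cfg: ScreenConfig) -> bool:
    """Keep a clip iff its similarity to the reference continuation is low.

    The effective clip length is ``min(len(S_c), len(S_r))`` so that segments
    truncated at a contig edge are screened at the truncated length.  With
    ``cfg.invert`` the decision is flipped (keep high-similarity clips).
    """
    if not s_r:
        return False
    score = local_match_score(
        clip.clipped_seq, s_r, cfg.sw_match, cfg.sw_mismatch, cfg.sw_gap
    )
    eff_len = min(len(clip.clipped_seq), len(s_r))
    keep = score < eff_len * cfg.m
    return (not keep) if cfg.invert else keep
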