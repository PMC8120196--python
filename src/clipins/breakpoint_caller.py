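"""Candidate breakpoint construction from screened soft-clips.

Clips are typed by which mate of the pair they sit on (Left/Right by
coordinate) and which read end is clipped (head -> L, tail -> R), giving the
four types LL, LR, RL, RR.  Clips within a small window are grouped into one
candidate breakpoint, and a candidate is evidence-supported when it has at
least one head-side clip type (LL or RL) and at least one tail-side clip type
(LR or RR):

    J = (LL or RL) and (LR or RR)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clip_screen import SoftClip

__all__ = [
    "CandidateBreakpoint",
    "classify_clip",
    "cluster_clips",
    "evidence_satisfied",
]

CLIP_TYPES = ("LL", "LR", "RL", "RR")


@dataclass
class CandidateBreakpoint:
    """A putative insertion site with its supporting clip set (PSD)."""

    contig: str
    position: int
    psd: list[SoftClip] = field(default_factory=list)
    evidence_ok: bool | None = None
    filter_ok: bool | None = None
    n_spanning: int | None = None
    n_oea: int | None = None

    def types_present(self) -> set[str]:
        """Distinct clip types in the PSD; one vote per (read name, type)."""
        return {c.clip_type for c in self.psd if c.clip_type is not None}

    def type_counts(self) -> dict[str, int]:
        seen: set[tuple[str, str]] = set()
        for c in self.psd:
            if c.clip_type is not None:
                seen.add((c.read_name, c.clip_type))
        out = {t: 0 for t in CLIP_TYPES}
        for _, t in seen:
            out[t] += 1
        return out


def classify_clip(clip: SoftClip) -> str:
    """Assign the two-letter clip type.

    First letter: left mate -> L, right mate -> R.  Second letter: head clip
    -> L, tail clip -> R.
    """
    first = "L" if clip.mate_role == "left" else "R"
    second = "L" if clip.side == "head" else "R"
    t = first + second
    clip.clip_type = t
    return t


def cluster_clips(clips: list[SoftClip], window: int = 10) -> list[CandidateBreakpoint]:
    """Group clips into candidate breakpoints by single-linkage within window.

    Clips must be sorted by (contig, ref_pos).  A new group starts whenever
    the gap to the previous clip exceeds ``window`` or the contig changes.
    The breakpoint position is the lower median of member positions, which is
    robust to one stray mis-clipped read.
    """
    out: list[CandidateBreakpoint] = []
    group: list[SoftClip] = []

    def flush() -> None:
        if not group:
            return
        positions = sorted(c.ref_pos for c in group)
        pos = positions[(len(positions) - 1) // 2]  # lower median
        out.append(CandidateBreakpoint(contig=group[0].contig, position=pos, psd=list(group)))

    for clip in clips:
        if group and (clip.contig != group[-1].contig or clip.ref_pos - group[-1].ref_pos > window):
            flush()
            group = []
        if group and clip.ref_pos < group[-1].ref_pos:
            raise ValueError("clips must be sorted by (contig, ref_pos)")
        group.append(clip)
    flush()
    return out


def evidence_satisfied(types: set[str]) -> bool:
    """Evidence predicate J on the clip types present at one candidate."""
    return bool(types & {"LL", "RL"}) and bool(types & {"LR", "RR"})
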