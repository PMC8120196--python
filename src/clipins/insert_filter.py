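"""Insert-size support filter for candidate breakpoints.

A true insertion perturbs the paired-read geometry around it: fragments
whose outer span straddles the site, and one-end-anchored (OEA) pairs whose
unmapped mate fell inside novel sequence.  Candidates are checked inside the
window [p - (mu + 3 sigma), p + (mu + 3 sigma)) and kept when the number of
spanning plus OEA pairs exceeds half the library coverage.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

from .breakpoint_caller import CandidateBreakpoint
from .io_alignment import AlignedRead, LibraryStats

__all__ = ["support_region", "count_support", "filter_breakpoint"]


def support_region(p: int, stats: LibraryStats) -> tuple[int, int]:
    """Half-open interval around p in which supporting pairs must align."""
    radius = int(round(stats.mu + 3 * stats.sigma))
    return max(0, p - radius), p + radius


def count_support(alignments: Iterable[AlignedRead], p: int) -> tuple[int, int]:
    """Count spanning pairs and OEA pairs around a breakpoint.

    A pair is *spanning* when both mates are mapped and the fragment's outer
    span straddles p (leftmost start < p <= rightmost end); *OEA* when exactly
    one mate is mapped.  Each pair contributes to one counter at most, with
    spanning taking priority.  The caller restricts ``alignments`` to the
    support region.
    """
    by_name: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in alignments:
        by_name[r.query_name].append(r)
    n_spanning = 0
    n_oea = 0
    for reads in by_name.values():
        mapped = [r for r in reads if r.is_mapped]
        both_mapped = bool(mapped) and all(r.mate_is_mapped for r in mapped)
        if both_mapped:
            if len(mapped) == 2:
                start = min(r.pos for r in mapped)
                end = max(r.reference_end for r in mapped)
            else:  # only one mate fell inside the window stream
                r = mapped[0]
                start = min(r.pos, r.mate_pos if r.mate_pos is not None else r.pos)
                end = max(r.reference_end, start + abs(r.template_len))
            if start < p <= end:
                n_spanning += 1
        elif mapped or any(r.mate_is_mapped for r in reads):
            n_oea += 1
    return n_spanning, n_oea


def filter_breakpoint(
    bp: CandidateBreakpoint,
    counts: tuple[int, int],
    stats: LibraryStats,
    min_support: int = 2,
) -> bool:
    """Keep a candidate iff spanning + OEA support strictly exceeds Cov / 2.

    ``min_support`` is an absolute floor preventing very low coverage
    libraries (Cov < 4) from passing a candidate on a single pair.
    """
    n_spanning, n_oea = counts
    total = n_spanning + n_oea
    keep = total > stats.cov / 2 and total >= min_support
    bp.n_spanning, bp.n_oea = n_spanning, n_oea
    bp.filter_ok = keep
    return keep
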