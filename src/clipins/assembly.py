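"""Local assembly of inserted sequence and contig placement.

For each confirmed breakpoint the abnormal reads (soft-clipped, one-end
anchored, unmapped-with-anchored-mate) around it are gathered and assembled
with a small de Bruijn assembler (k-mer graph, low-count k-mers dropped,
short tips clipped, unitigs emitted).  Each contig is then placed against the
reference window around the breakpoint with a two-flank alignment that allows
one long insertion gap; a CIGAR like ``132M186I130M`` yields the insertion
length (186) and the inserted bases (contig positions 133-318, 1-based).
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .breakpoint_caller import CandidateBreakpoint
from .genotyper import GenotypeCall
from .insert_filter import support_region
from .io_alignment import AlignedRead, LibraryStats, ReferenceAccessor

__all__ = [
    "AssemblyConfig",
    "InsertionCall",
    "Placement",
    "gather_reads",
    "assemble",
    "place_contig",
    "extract_insertion",
    "left_normalize_insertion",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AssemblyConfig:
    k: int = 31
    min_contig_len: int = 100
    min_kmer_count: int = 2
    assembler: str = "builtin"
    external_cmd: str | None = None  # template with {reads} and {out}
    min_flank: int = 20
    min_flank_identity: float = 0.9
    min_sv_len: int = 50

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 15 <= self.k <= 63:
            raise ValueError(f"k must be odd and in [15, 63], got {self.k}")


@dataclass
class InsertionCall:
    """Final insertion record emitted by the pipeline."""

    contig: str
    position: int
    genotype: GenotypeCall
    ins_len: int | None = None
    ins_seq: str | None = None
    n_spanning: int = 0
    n_oea: int = 0
    n_clips: int = 0

    def __post_init__(self) -> None:
        if self.ins_seq is not None and self.ins_len is not None:
            if len(self.ins_seq) != self.ins_len:
                raise ValueError("ins_seq length disagrees with ins_len")


@dataclass
class Placement:
    """A contig placed against the reference window around a breakpoint."""

    ref_start: int
    cigar: list[tuple[str, int]]
    contig: str  # contig sequence in placed orientation
    contig_start: int  # offset of the first aligned contig base
    strand: str = "+"
    score: int = 0
    flank_identity: float = 1.0


def gather_reads(
    alignments: Iterable[AlignedRead],
    bp: CandidateBreakpoint,
    stats: LibraryStats,
    min_clip_len: int = 5,
) -> list[AlignedRead]:
    """Abnormal reads around a breakpoint, deduplicated by (name, mate).

    The set is the union of soft-clipped reads in the support region, both
    mates of one-end-anchored pairs anchored there, and unmapped reads whose
    mapped mate lies in the region (unmapped reads are placed at their mate's
    coordinate, so they appear in the same window).
    """
    lo, hi = support_region(bp.position, stats)
    seen: set[tuple[str, bool]] = set()
    out: list[AlignedRead] = []
    for r in alignments:
        pos = r.pos
        end = r.reference_end if r.is_mapped else r.pos + 1
        if end <= lo or pos >= hi:
            continue
        keep = False
        if r.is_mapped and r.has_soft_clip(min_clip_len):
            keep = True
        if r.is_mapped and not r.mate_is_mapped:
            keep = True  # anchor of an OEA pair
        if not r.is_mapped and r.mate_is_mapped:
            keep = True  # novel-sequence mate of an OEA pair
        if keep:
            key = (r.query_name, r.is_read1)
            if key not in seen:
                seen.add(key)
                out.append(r)
    return out


# --- de Bruijn assembly -----------------------------------------------------


def _kmer_counts(seqs: Iterable[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return counts


def _unitigs(kmers: set[str], k: int) -> list[str]:
    def succ(x: str) -> list[str]:
        return [x[1:] + b for b in "ACGT" if x[1:] + b in kmers]

    def pred(x: str) -> list[str]:
        return [b + x[:-1] for b in "ACGT" if b + x[:-1] in kmers]

    visited: set[str] = set()
    contigs: list[str] = []

    def walk(start: str) -> str:
        path = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = succ(cur)
            if len(nxt) != 1:
                break
            nxt = nxt[0]
            if nxt in visited or len(pred(nxt)) != 1:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        return path[0] + "".join(p[-1] for p in path[1:])

    # unitig start nodes: no unique unambiguous incoming edge
    for x in sorted(kmers):
        if x in visited:
            continue
        ps = pred(x)
        if len(ps) != 1 or len(succ(ps[0])) != 1:
            contigs.append(walk(x))
    for x in sorted(kmers):  # leftover cycles
        if x not in visited:
            contigs.append(walk(x))
    return contigs


def _clip_tips(kmers: set[str], k: int) -> set[str]:
    """Remove dead-end unitigs of length <= 2k hanging off a junction."""
    def succ(x):
        return [x[1:] + b for b in "ACGT" if x[1:] + b in kmers]

    def pred(x):
        return [b + x[:-1] for b in "ACGT" if b + x[:-1] in kmers]

    removed = False
    for unitig in _unitigs(set(kmers), k):
        if len(unitig) > 2 * k:
            continue
        first, last = unitig[:k], unitig[len(unitig) - k :]
        dead_start = len(pred(first)) == 0
        dead_end = len(succ(last)) == 0
        junction_start = any(len(succ(p)) > 1 for p in pred(first))
        junction_end = any(len(pred(s)) > 1 for s in succ(last))
        if (dead_start and junction_end) or (dead_end and junction_start):
            for i in range(len(unitig) - k + 1):
                kmers.discard(unitig[i : i + k])
            removed = True
    return kmers


def assemble(reads: Iterable[AlignedRead | str], cfg: AssemblyConfig | None = None) -> list[str]:
    """Assemble read sequences into contigs of length >= min_contig_len.

    Builtin mode builds a de Bruijn graph on k-mers observed at least
    ``min_kmer_count`` times (sequencing errors produce singleton k-mers),
    clips short dead-end tips and emits unitigs.  External mode shells out to
    a Minia-compatible assembler command template.
    """
    cfg = cfg or AssemblyConfig()
    seqs = [r.seq if isinstance(r, AlignedRead) else r for r in reads]
    total = sum(len(s) for s in seqs)
    if total < 2 * cfg.k:
        raise ValueError(
            f"not enough sequence to assemble: {total} bases < 2k = {2 * cfg.k}"
        )
    if cfg.assembler == "external":
        return _assemble_external(seqs, cfg)
    counts = _kmer_counts(seqs, cfg.k)
    kmers = {km for km, c in counts.items() if c >= cfg.min_kmer_count}
    if not kmers:
        return []
    kmers = _clip_tips(kmers, cfg.k)
    contigs = _unitigs(kmers, cfg.k)
    return sorted(
        (c for c in contigs if len(c) >= cfg.min_contig_len), key=len, reverse=True
    )


def _assemble_external(seqs: Sequence[str], cfg: AssemblyConfig) -> list[str]:
    if not cfg.external_cmd:
        raise ValueError("external assembler selected but no command template given")
    with tempfile.TemporaryDirectory() as tmp:
        reads_fa = Path(tmp) / "reads.fa"
        out_fa = Path(tmp) / "contigs.fa"
        reads_fa.write_text("".join(f">r{i}\n{s}\n" for i, s in enumerate(seqs)))
        cmd = cfg.external_cmd.format(reads=reads_fa, out=out_fa)
        subprocess.run(shlex.split(cmd), check=True, capture_output=True)
        contigs = []
        seq: list[str] = []
        for line in out_fa.read_text().splitlines():
            if line.startswith(">"):
                if seq:
                    contigs.append("".join(seq))
                seq = []
            else:
                seq.append(line.strip())
        if seq:
            contigs.append("".join(seq))
    return sorted(
        (c for c in contigs if len(c) >= cfg.min_contig_len), key=len, reverse=True
    )


# --- placement --------------------------------------------------------------


def _encode(s: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([table.get(b, -1) for b in s.upper()], dtype=np.int16)


def _flank_dp(contig: str, window: str) -> tuple | None:
    """Best two-gapless-flank split of contig against window.

    Left flank: best local gapless alignment of a contig prefix ending at
    window offset j; right flank: contig suffix starting at the same offset.
    The contig bases between the two flanks form the insertion.  Returns
    (score, j, i1, i2, llen, rlen, lscore, rscore) or None.
    """
    c = _encode(contig)
    w = _encode(window)
    n, m = len(c), len(w)
    if n == 0 or m == 0:
        return None
    S = np.where(c[:, None] == w[None, :], 1, -1).astype(np.int32)
    S[c < 0, :] = -1  # ambiguity never matches

    Lsc = np.zeros((n + 1, m + 1), dtype=np.int32)
    Llen = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(n):
        ext = Lsc[i, :-1] + S[i, :]
        keep = ext > 0
        Lsc[i + 1, 1:] = np.where(keep, ext, 0)
        Llen[i + 1, 1:] = np.where(keep, Llen[i, :-1] + 1, 0)

    Rsc = np.zeros((n + 1, m + 1), dtype=np.int32)
    Rlen = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(n - 1, -1, -1):
        ext = Rsc[i + 1, 1:] + S[i, :]
        keep = ext > 0
        Rsc[i, :-1] = np.where(keep, ext, 0)
        Rlen[i, :-1] = np.where(keep, Rlen[i + 1, 1:] + 1, 0)

    bestL = Lsc.max(axis=0)
    argL = Lsc.argmax(axis=0)
    bestR = Rsc.max(axis=0)
    argR = Rsc.argmax(axis=0)
    totals = bestL + bestR
    cols = np.arange(m + 1)
    llen_at = Llen[argL, cols]
    rlen_at = Rlen[argR, cols]
    # among equal-score splits (e.g. anywhere along a pure-match diagonal)
    # prefer the most balanced one, so both flanks stay usable
    balance = np.minimum(llen_at, rlen_at)
    order = np.lexsort((-balance, -totals))
    for j in order:
        i1, i2 = int(argL[j]), int(argR[j])
        if i1 <= i2:
            return (
                int(totals[j]),
                int(j),
                i1,
                i2,
                int(Llen[i1, j]),
                int(Rlen[i2, j]),
                int(Lsc[i1, j]),
                int(Rsc[i2, j]),
            )
    return None


def place_contig(
    contig: str,
    reference: ReferenceAccessor,
    ref_contig: str,
    p: int,
    stats: LibraryStats,
    cfg: AssemblyConfig | None = None,
) -> Placement | None:
    """Place a contig in the window around p allowing one long insertion.

    Both flanks are aligned gaplessly (mismatches allowed) to the same
    reference offset; the skipped contig bases become a single I operation.
    Both orientations are tried (forward wins ties).  The placement is
    rejected when either flank is shorter than ``min_flank`` or its identity
    falls below ``min_flank_identity``.
    """
    cfg = cfg or AssemblyConfig()
    lo, hi = support_region(p, stats)
    hi = min(hi, reference.length(ref_contig))
    window = reference.fetch(ref_contig, lo, hi)
    best: Placement | None = None
    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        hit = _flank_dp(seq, window)
        if hit is None:
            continue
        score, j, i1, i2, llen, rlen, lsc, rsc = hit
        if llen < cfg.min_flank or rlen < cfg.min_flank:
            continue
        lid = ((lsc + llen) / 2) / llen if llen else 0.0
        rid = ((rsc + rlen) / 2) / rlen if rlen else 0.0
        if lid < cfg.min_flank_identity or rid < cfg.min_flank_identity:
            continue
        ins = i2 - i1
        cigar: list[tuple[str, int]] = [("M", llen)]
        if ins > 0:
            cigar.append(("I", ins))
            cigar.append(("M", rlen))
        else:
            cigar = [("M", llen + rlen)]
        placement = Placement(
            ref_start=lo + j - llen,
            cigar=cigar,
            contig=seq,
            contig_start=i1 - llen,
            strand=strand,
            score=score,
            flank_identity=min(lid, rid),
        )
        if best is None or placement.score > best.score:
            best = placement
    return best


def extract_insertion(
    placement: Placement, contig: str | None = None, min_sv_len: int = 50
) -> tuple[int, str, int] | None:
    """Pull the inserted sequence out of a placement.

    Requires exactly one I operation of length >= ``min_sv_len`` in the
    placement CIGAR; returns (ins_len, ins_seq, refined breakpoint position).
    The inserted bases are the contig bases spanned by the I operation, i.e.
    1-based positions [M1+1, M1+I] of the aligned part.
    """
    seq = placement.contig if contig is None else contig
    big = [(idx, n) for idx, (op, n) in enumerate(placement.cigar) if op == "I" and n >= min_sv_len]
    if len(big) != 1:
        return None
    idx, ins_len = big[0]
    offset = placement.contig_start
    ref_off = 0
    for op, n in placement.cigar[:idx]:
        if op in ("M", "=", "X"):
            offset += n
            ref_off += n
        elif op == "I":
            offset += n
        elif op == "D":
            ref_off += n
    ins_seq = seq[offset : offset + ins_len]
    refined = placement.ref_start + ref_off
    return ins_len, ins_seq, refined


def left_normalize_insertion(
    position: int, seq: str, reference: ReferenceAccessor, contig: str
) -> tuple[int, str]:
    """Shift an insertion to its leftmost equivalent placement.

    An insertion whose last base equals the reference base just before the
    breakpoint describes the same haplotype one base to the left (with the
    sequence rotated); repeating until that no longer holds gives the
    canonical left-aligned representation, so that equivalent calls compare
    equal.
    """
    while position > 0 and seq:
        prev = reference.fetch(contig, position - 1, position)
        if seq[-1] != prev:
            break
        seq = prev + seq[:-1]
        position -= 1
    return position, seq
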