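"""Synthetic diploid insertion datasets with analytically aligned reads.

The simulator builds a random reference contig, implants novel-sequence
insertions (homozygous on both haplotypes, heterozygous on one), and draws
paired-end fragments with Normal(mu, sigma) insert sizes.  Instead of
invoking an external aligner, each read is "aligned" through the exact
haplotype-to-reference coordinate map: reads wholly inside reference-derived
sequence become full-match records, reads straddling an insertion edge with a
sufficient reference anchor become soft-clipped records with the clip
boundary at the insertion point, and reads mostly inside novel sequence
become unmapped mates of one-end-anchored pairs.  This makes clip placement
and template lengths exact, so caller behaviour can be tested without any
external binary; an optional FASTQ export allows integration checks with a
real aligner.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pysam

from .io_alignment import AlignedRead, write_vcf

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimData",
    "make_genome",
    "implant_insertions",
    "simulate_aligned_pairs",
    "simulate_dataset",
    "write_sam",
    "write_fasta",
    "write_truth_vcf",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a standard short-read library: 150 bp reads, insert size
    Normal(500, 50), 0.1% substitution error.  Insertions are at least 50 bp
    (the conventional SV size floor) and are spaced at least two fragment
    windows apart so their evidence regions do not overlap.
    """

    genome_len: int = 500_000
    n_insertions: int = 50
    size_range: tuple[int, int] = (50, 300)
    zygosity_mix: float = 0.5  # fraction heterozygous
    coverage: float = 30.0
    read_len: int = 150
    mu: float = 500.0
    sigma: float = 50.0
    error_rate: float = 0.001
    min_anchor: int = 20
    seed: int = 0
    contig: str = "sim1"

    def __post_init__(self) -> None:
        if self.size_range[0] < 50:
            raise ValueError("insertions below the 50 bp SV floor are not simulated")
        if not 0.0 <= self.zygosity_mix <= 1.0:
            raise ValueError("zygosity_mix must be in [0, 1]")

    @property
    def spacing(self) -> int:
        return int(2 * (self.mu + 3 * self.sigma))


@dataclass
class TruthRecord:
    position: int  # 0-based, in original reference coordinates
    ins_len: int
    ins_seq: str
    genotype: Literal["hom", "het"]

    def __post_init__(self) -> None:
        if len(self.ins_seq) != self.ins_len:
            raise ValueError("ins_seq length disagrees with ins_len")

    @property
    def contig(self) -> str:  # for write_vcf compatibility
        return getattr(self, "_contig", "sim1")


@dataclass
class _Haplotype:
    """Haplotype sequence plus its coordinate map back to the reference."""

    seq: str
    # parallel arrays per segment, in haplotype order
    starts: list[int]  # hap start of each segment
    kinds: list[str]  # "ref" or "ins"
    ref_pos: list[int]  # ref start of segment ("ins": the insertion point)

    def segment_index(self, hap_pos: int) -> int:
        return bisect_right(self.starts, hap_pos) - 1


@dataclass
class SimData:
    reference: str
    contig: str
    reads: list[AlignedRead]
    truth: list[TruthRecord]
    config: SimConfig


def make_genome(length: int, seed: int | np.random.Generator) -> str:
    """Uniform i.i.d. ACGT sequence, reproducible from the seed."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10,000 bp")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def implant_insertions(
    reference: str, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[_Haplotype, _Haplotype, list[TruthRecord]]:
    """Place insertions on two haplotypes and return them with ground truth.

    Homozygous records modify both haplotypes; heterozygous records only
    haplotype A.  Truth positions are original-reference coordinates of the
    base immediately after the inserted sequence.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_insertions
    margin = cfg.spacing
    slack = len(reference) - 2 * margin - (n - 1) * cfg.spacing if n else 0
    if n and slack <= 0:
        raise ValueError(
            f"cannot place {n} insertions with spacing {cfg.spacing} "
            f"on a {len(reference)} bp reference"
        )
    offsets = np.sort(rng.integers(0, slack, size=n)) if n else np.array([], dtype=int)
    positions = [int(margin + off + i * cfg.spacing) for i, off in enumerate(offsets)]
    n_het = int(round(cfg.zygosity_mix * n))
    zygosity = np.array(["het"] * n_het + ["hom"] * (n - n_het))
    rng.shuffle(zygosity)
    truth = []
    for pos, z in zip(positions, zygosity):
        size = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
        seq = _random_seq(rng, size)
        # canonical (left-aligned) placement of an ambiguous insertion
        while pos > 0 and seq[-1] == reference[pos - 1]:
            seq = reference[pos - 1] + seq[:-1]
            pos -= 1
        truth.append(TruthRecord(pos, size, seq, str(z)))
        truth[-1]._contig = cfg.contig

    def build(records: list[TruthRecord]) -> _Haplotype:
        parts, starts, kinds, refp = [], [], [], []
        cursor_ref = 0
        cursor_hap = 0
        for t in records:
            if t.position > cursor_ref:
                seg = reference[cursor_ref : t.position]
                parts.append(seg)
                starts.append(cursor_hap)
                kinds.append("ref")
                refp.append(cursor_ref)
                cursor_hap += len(seg)
            parts.append(t.ins_seq)
            starts.append(cursor_hap)
            kinds.append("ins")
            refp.append(t.position)
            cursor_hap += t.ins_len
            cursor_ref = t.position
        if cursor_ref < len(reference):
            parts.append(reference[cursor_ref:])
            starts.append(cursor_hap)
            kinds.append("ref")
            refp.append(cursor_ref)
        return _Haplotype("".join(parts), starts, kinds, refp)

    hap_a = build(truth)
    hap_b = build([t for t in truth if t.genotype == "hom"])
    return hap_a, hap_b, truth


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    arr = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        cur = arr[pos]
        alts = [b for b in "ACGT" if b != cur]
        arr[pos] = alts[rng.integers(0, 3)]
    return "".join(arr)


def _map_read(hap: _Haplotype, s: int, read_len: int, min_anchor: int):
    """Analytic alignment of haplotype interval [s, s + read_len).

    Returns (is_mapped, pos, cigar).  Reads fully in a reference segment map
    with a full-M CIGAR; reads straddling an insertion edge with an anchor of
    at least ``min_anchor`` reference bases are soft-clipped on the longer
    anchor's far side; reads without a sufficient anchor are unmapped.
    """
    e = s + read_len
    i0 = hap.segment_index(s)
    i1 = hap.segment_index(e - 1)
    if i0 == i1 and hap.kinds[i0] == "ref":
        pos = hap.ref_pos[i0] + (s - hap.starts[i0])
        return True, pos, [("M", read_len)]
    # length of the leading / trailing reference run
    left_run = 0
    if hap.kinds[i0] == "ref":
        left_run = min(e, hap.starts[i0 + 1]) - s
    right_run = 0
    if hap.kinds[i1] == "ref":
        right_run = e - max(s, hap.starts[i1])
    if max(left_run, right_run) < min_anchor:
        return False, -1, []
    if left_run >= right_run:
        pos = hap.ref_pos[i0] + (s - hap.starts[i0])
        cigar = [("M", left_run)]
        if read_len - left_run:
            cigar.append(("S", read_len - left_run))
        return True, pos, cigar
    pos = hap.ref_pos[i1] + max(0, s - hap.starts[i1])
    cigar = []
    if read_len - right_run:
        cigar.append(("S", read_len - right_run))
    cigar.append(("M", right_run))
    return True, pos, cigar


def simulate_aligned_pairs(
    haplotypes: tuple[_Haplotype, _Haplotype],
    reference: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Draw paired-end fragments and emit analytically aligned records.

    Fragments are uniform over each haplotype (half the total from each, so a
    heterozygous site sees a 50/50 haplotype mix); fragment length is
    Normal(mu, sigma) clamped to at least one read length; per-base
    substitution errors at ``error_rate``.  Sequences are stored in
    genome-forward orientation as in SAM.  Records come back coordinate
    sorted, fully unmapped pairs last.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    reads: list[AlignedRead] = []
    frag_id = 0
    for hap in haplotypes:
        n_frags = int(round(cfg.coverage * len(hap.seq) / (4 * cfg.read_len)))
        lengths = np.maximum(
            rng.normal(cfg.mu, cfg.sigma, size=n_frags).round().astype(int),
            cfg.read_len + 10,
        )
        starts = rng.integers(0, np.maximum(1, len(hap.seq) - lengths), size=n_frags)
        for s, L in zip(starts.tolist(), lengths.tolist()):
            name = f"frag{frag_id:07d}"
            frag_id += 1
            s2 = s + L - cfg.read_len
            m1, p1, c1 = _map_read(hap, s, cfg.read_len, cfg.min_anchor)
            m2, p2, c2 = _map_read(hap, s2, cfg.read_len, cfg.min_anchor)
            seq1 = _apply_errors(hap.seq[s : s + cfg.read_len], rng, cfg.error_rate)
            seq2 = _apply_errors(hap.seq[s2 : s2 + cfg.read_len], rng, cfg.error_rate)
            r1 = AlignedRead(name, m1, cfg.contig if m1 or m2 else None, p1, c1, seq1,
                             is_reverse=False, is_read1=True)
            r2 = AlignedRead(name, m2, cfg.contig if m1 or m2 else None, p2, c2, seq2,
                             is_reverse=True, is_read1=False)
            _finalise_pair(r1, r2)
            reads.extend((r1, r2))
    mapped = [r for r in reads if r.pos >= 0]
    orphans = [r for r in reads if r.pos < 0]
    mapped.sort(key=lambda r: r.pos)
    return mapped + orphans


def _ref_end(read: AlignedRead) -> int:
    return read.reference_end


def _finalise_pair(r1: AlignedRead, r2: AlignedRead) -> None:
    r1.mate_is_mapped = r2.is_mapped
    r2.mate_is_mapped = r1.is_mapped
    if r1.is_mapped and r2.is_mapped:
        r1.mate_pos, r2.mate_pos = r2.pos, r1.pos
        left, right = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
        span = max(_ref_end(left), _ref_end(right)) - left.pos
        left.template_len = span
        right.template_len = -span
    elif r1.is_mapped or r2.is_mapped:
        anchor, floater = (r1, r2) if r1.is_mapped else (r2, r1)
        floater.pos = anchor.pos  # unmapped mate placed at the anchor
        floater.mate_pos = anchor.pos
        anchor.mate_pos = anchor.pos
        anchor.template_len = 0
        floater.template_len = 0
    else:
        r1.pos = r2.pos = -1
        r1.mate_pos = r2.mate_pos = None


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Full simulation: genome, implanted insertions, aligned read pairs."""
    rng = np.random.default_rng(cfg.seed)
    reference = make_genome(cfg.genome_len, rng)
    hap_a, hap_b, truth = implant_insertions(reference, cfg, rng)
    reads = simulate_aligned_pairs((hap_a, hap_b), reference, cfg, rng)
    return SimData(reference=reference, contig=cfg.contig, reads=reads, truth=truth, config=cfg)


# --- writers ----------------------------------------------------------------


def write_fasta(data: SimData, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{data.contig}\n")
        for i in range(0, len(data.reference), 80):
            fh.write(data.reference[i : i + 80] + "\n")


def write_sam(data: SimData, path: str | Path) -> None:
    """Write the simulated records as a coordinate-sorted SAM file."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": data.contig, "LN": len(data.reference)}],
        }
    )
    ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in data.reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.query_name
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            a.flag = (
                0x1
                | (0x40 if r.is_read1 else 0x80)
                | (0x4 if not r.is_mapped else 0)
                | (0x8 if not r.mate_is_mapped else 0)
                | (0x10 if r.is_reverse and r.is_mapped else 0)
                | (0x20 if r.mate_is_mapped and r.is_read1 else 0)
            )
            if r.pos >= 0:
                a.reference_id = 0
                a.reference_start = r.pos
            else:
                a.reference_id = -1
            if r.is_mapped:
                a.cigartuples = [(ops[op], n) for op, n in r.cigar]
                a.mapping_quality = 60
            if r.mate_pos is not None:
                a.next_reference_id = 0
                a.next_reference_start = r.mate_pos
            else:
                a.next_reference_id = -1
            a.template_length = r.template_len
            out.write(a)


def write_truth_vcf(data: SimData, path: str | Path) -> None:
    write_vcf(data.truth, {data.contig: len(data.reference)}, path, sample="TRUTH")


def write_fastq(data: SimData, prefix: str | Path) -> tuple[Path, Path]:
    """Export read pairs as FASTQ (read2 in sequencing orientation)."""
    from .assembly import revcomp

    p1 = Path(f"{prefix}_1.fastq")
    p2 = Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        pairs: dict[str, dict[bool, AlignedRead]] = {}
        for r in data.reads:
            pairs.setdefault(r.query_name, {})[r.is_read1] = r
        for name in sorted(pairs):
            duo = pairs[name]
            if True not in duo or False not in duo:
                continue
            r1, r2 = duo[True], duo[False]
            f1.write(f"@{name}/1\n{r1.seq}\n+\n{'I' * len(r1.seq)}\n")
            f2.write(f"@{name}/2\n{revcomp(r2.seq)}\n+\n{'I' * len(r2.seq)}\n")
    return p1, p2
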