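"""Alignment and reference I/O, library statistics, and VCF output.

All coordinates inside the package are 0-based half-open; the only place a
1-based coordinate appears is the POS column written by :func:`write_vcf`.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

__all__ = [
    "AlignedRead",
    "LibraryStats",
    "ReferenceAccessor",
    "read_alignments",
    "fetch_reference",
    "estimate_library_stats",
    "write_vcf",
    "read_vcf_calls",
]

# CIGAR operations that consume query sequence / reference, respectively.
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MD=XN")


@dataclass
class AlignedRead:
    """One paired-end alignment record (mapped or unmapped).

    ``pos`` is the 0-based leftmost reference coordinate of the alignment;
    ``template_len`` is the signed observed insert size (outer fragment span),
    positive on the leftmost mate of a pair.  Unmapped reads carry the mate's
    position when the mate is mapped (standard placement convention), so they
    remain retrievable from a coordinate-sorted stream.
    """

    query_name: str
    is_mapped: bool
    contig: str | None
    pos: int
    cigar: list[tuple[str, int]]
    seq: str
    is_reverse: bool = False
    mate_is_mapped: bool = False
    mate_pos: int | None = None
    template_len: int = 0
    mapq: int = 0
    is_read1: bool = True

    @property
    def query_length(self) -> int:
        return len(self.seq)

    @property
    def reference_length(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned segment."""
        return self.pos + self.reference_length

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    def has_soft_clip(self, min_len: int = 1) -> bool:
        if not self.cigar:
            return False
        head = self.cigar[0]
        tail = self.cigar[-1]
        return (head[0] == "S" and head[1] >= min_len) or (
            tail[0] == "S" and tail[1] >= min_len
        )


@dataclass
class LibraryStats:
    """Sequencing-library summary: insert-size mean/SD, depth, read length."""

    mu: float
    sigma: float
    cov: float
    read_len: int

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"insert-size mean must be positive, got {self.mu}")
        if self.sigma < 0:
            raise ValueError(f"insert-size SD must be non-negative, got {self.sigma}")
        if self.cov <= 0:
            raise ValueError(f"coverage must be positive, got {self.cov}")


class ReferenceAccessor:
    """Random access to reference sequence from a FASTA file or dict.

    Wraps either an on-disk (indexed) FASTA via pyfaidx or an in-memory
    ``{contig: sequence}`` mapping behind the same ``fetch`` interface.
    """

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {name: seq.upper() for name, seq in source.items()}

    def contigs(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def length(self, contig: str) -> int:
        if self._dict is not None:
            return len(self._seq(contig))
        return len(self._fasta[contig])

    def _seq(self, contig: str) -> str:
        if self._dict is not None:
            if contig not in self._dict:
                raise KeyError(f"unknown contig {contig!r}")
            return self._dict[contig]
        if contig not in self._fasta:
            raise KeyError(f"unknown contig {contig!r}")
        return None  # pragma: no cover - dict path only

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Uppercase sequence for [start, end); bounds are checked."""
        n = self.length(contig)
        if start < 0 or end < start or end > n:
            raise ValueError(
                f"reference slice [{start}, {end}) out of range for "
                f"{contig!r} (length {n})"
            )
        if start == end:
            return ""
        if self._dict is not None:
            return self._dict[contig][start:end]
        return str(self._fasta[contig][start:end]).upper()


def fetch_reference(fasta: str | Path | ReferenceAccessor, contig: str, start: int, end: int) -> str:
    """Fetch reference sequence [start, end) (0-based half-open), uppercase."""
    acc = fasta if isinstance(fasta, ReferenceAccessor) else ReferenceAccessor(fasta)
    return acc.fetch(contig, start, end)


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = []
    if rec.cigartuples:
        ops = "MIDNSHP=X"
        cigar = [(ops[op], n) for op, n in rec.cigartuples]
    return AlignedRead(
        query_name=rec.query_name,
        is_mapped=not rec.is_unmapped,
        contig=rec.reference_name if not rec.is_unmapped else (rec.next_reference_name if not rec.mate_is_unmapped else None),
        pos=rec.reference_start if not rec.is_unmapped else (rec.next_reference_start if not rec.mate_is_unmapped else -1),
        cigar=cigar,
        seq=rec.query_sequence or "",
        is_reverse=rec.is_reverse,
        mate_is_mapped=rec.is_paired and not rec.mate_is_unmapped,
        mate_pos=rec.next_reference_start if (rec.is_paired and not rec.mate_is_unmapped) else None,
        template_len=rec.template_length,
        mapq=rec.mapping_quality,
        is_read1=rec.is_read1 or not rec.is_paired,
    )


def read_alignments(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> Iterator[AlignedRead]:
    """Stream records from a coordinate-sorted SAM/BAM in position order.

    ``region`` is (contig, start, end), 0-based half-open; only mapped reads
    overlapping the window (or unmapped mates placed inside it) are yielded.
    Raises on a missing file or on the first out-of-order record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    mode = "rb" if path.suffix == ".bam" else "r"
    last: dict[str, int] = {}
    seen_contigs: list[str] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped and rec.mate_is_unmapped:
                # orphan pairs sort to the end; no coordinate to check
                yield_rec = region is None
                if yield_rec:
                    yield _from_pysam(rec)
                continue
            contig = rec.reference_name if not rec.is_unmapped else rec.next_reference_name
            pos = rec.reference_start if not rec.is_unmapped else rec.next_reference_start
            if contig in last and pos < last[contig]:
                raise ValueError(
                    f"input is not coordinate-sorted: record {rec.query_name!r} at "
                    f"{contig}:{pos} follows position {last[contig]}"
                )
            if contig not in last:
                seen_contigs.append(contig)
            last[contig] = pos
            if region is not None:
                rcontig, rstart, rend = region
                if contig != rcontig:
                    continue
                end = (rec.reference_end if not rec.is_unmapped else pos + 1) or pos + 1
                if end <= rstart or pos >= rend:
                    continue
            yield _from_pysam(rec)


def estimate_library_stats(
    alignments: Iterable[AlignedRead],
    genome_len: int,
    trim_frac: float = 0.05,
) -> LibraryStats:
    """Estimate insert-size mean/SD, coverage and read length from alignments.

    The insert-size mean is a symmetric trimmed mean of |template length| over
    proper pairs (both mates mapped, 0 < |tlen| < 10 * read length); the SD is
    the scaled median absolute deviation (1.4826 * MAD), which is consistent
    for the standard deviation at the normal and robust to chimeric pairs.
    Coverage is mapped bases divided by genome length.
    """
    tlens: list[int] = []
    n_mapped = 0
    read_lens: list[int] = []
    for r in alignments:
        if r.is_mapped:
            n_mapped += 1
            read_lens.append(r.query_length)
        if r.is_mapped and r.mate_is_mapped and r.template_len > 0:
            tlens.append(r.template_len)
    if len(tlens) < 100:
        raise ValueError(
            f"cannot estimate library: need >= 100 proper pairs, found {len(tlens)}"
        )
    read_len = int(statistics.median(read_lens))
    arr = np.sort(np.abs(np.asarray(tlens, dtype=float)))
    arr = arr[(arr > 0) & (arr < 10 * read_len)]
    k = int(len(arr) * trim_frac)
    trimmed = arr[k : len(arr) - k] if k > 0 else arr
    mu = float(np.mean(trimmed))
    mad = float(np.median(np.abs(arr - np.median(arr))))
    sigma = 1.4826 * mad
    cov = n_mapped * read_len / genome_len
    return LibraryStats(mu=mu, sigma=sigma, cov=cov, read_len=read_len)


def write_vcf(calls: Sequence, reference, path: str | Path, sample: str = "SAMPLE") -> None:
    """Write insertion calls as a VCF 4.2 file.

    ``reference`` is a :class:`ReferenceAccessor` (used for contig lengths and
    the anchor base) or a ``{contig: length}`` mapping.  Calls must be sorted
    by (contig, position).  POS is the 1-based coordinate of the breakpoint
    base (internal 0-based position + 1); the anchor REF base is the reference
    base at the breakpoint, and ALT is anchor + inserted sequence when the
    sequence was assembled, else the symbolic ``<INS>``.
    """
    ordered = sorted(calls, key=lambda c: (c.contig, c.position))
    for a, b in zip(calls, ordered):
        if (a.contig, a.position) != (b.contig, b.position):
            raise ValueError("calls must be sorted by (contig, position)")
    if isinstance(reference, ReferenceAccessor):
        contig_lens = {c: reference.length(c) for c in reference.contigs()}
        accessor = reference
    else:
        contig_lens = dict(reference)
        accessor = None
    lines = [
        "##fileformat=VCFv4.2",
        "##source=clipins",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of inserted sequence">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##ALT=<ID=INS,Description="Insertion of novel sequence">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for name, length in contig_lens.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for i, call in enumerate(ordered):
        pos1 = call.position + 1
        if accessor is not None:
            ref_base = accessor.fetch(call.contig, call.position, call.position + 1) or "N"
        else:
            ref_base = "N"
        ins_seq = getattr(call, "ins_seq", None)
        ins_len = getattr(call, "ins_len", None)
        if ins_seq:
            alt = ref_base + ins_seq
            svlen = len(ins_seq)
        else:
            alt = "<INS>"
            svlen = ins_len if ins_len is not None else 0
        gt = "1/1" if _is_homozygous(call) else "0/1"
        info = f"SVTYPE=INS;SVLEN={svlen};END={pos1}"
        lines.append(
            f"{call.contig}\t{pos1}\tINS{i + 1}\t{ref_base}\t{alt}\t.\tPASS\t{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _is_homozygous(call) -> bool:
    gt = getattr(call, "genotype", None)
    label = getattr(gt, "genotype", gt)
    return str(label) in ("homozygous", "hom", "1/1")


def read_vcf_calls(path: str | Path) -> list[dict]:
    """Parse an insertion VCF back into plain records (0-based positions)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "<INS>"
            seq = None if alt.startswith("<") else alt[1:]
            sample = rec.samples[0] if rec.samples else None
            gt = None
            if sample is not None and sample.get("GT") is not None:
                alleles = sample["GT"]
                gt = "homozygous" if tuple(alleles) == (1, 1) else "heterozygous"
            out.append(
                {
                    "contig": rec.contig,
                    "position": rec.pos - 1,
                    "svlen": rec.info.get("SVLEN"),
                    "seq": seq,
                    "genotype": gt,
                }
            )
    return out
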