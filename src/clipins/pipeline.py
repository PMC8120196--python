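"""End-to-end insertion calling: screen -> cluster -> filter -> genotype -> assemble.

The pipeline consumes a coordinate-sorted alignment stream plus the reference
and produces insertion calls with genotypes and, where assembly succeeds,
the inserted sequence.  Every candidate breakpoint is recorded in a
diagnostics table together with the stage that rejected it.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path

from . import assembly as asm
from .assembly import AssemblyConfig, InsertionCall
from .breakpoint_caller import (
    CandidateBreakpoint,
    classify_clip,
    cluster_clips,
    evidence_satisfied,
)
from .clip_screen import (
    ScreenConfig,
    corresponding_ref_segment,
    extract_softclips,
    screen_clip,
)
from .genotyper import GenotypeConfig, call_genotype, collect_pairs
from .insert_filter import count_support, filter_breakpoint, support_region
from .io_alignment import (
    AlignedRead,
    LibraryStats,
    ReferenceAccessor,
    estimate_library_stats,
    read_alignments,
    write_vcf,
)

__all__ = ["CallerConfig", "call_insertions", "run_call", "run_simulate", "run_evaluate"]


@dataclass
class CallerConfig:
    """All tunables of the calling pipeline, with field-standard defaults."""

    min_mapq: int = 0
    window: int = 10
    min_support: int = 2
    skip_assembly: bool = False
    cov_override: float | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)


class _ReadIndex:
    """Coordinate index over in-memory reads for window queries."""

    def __init__(self, reads: list[AlignedRead]):
        located = [r for r in reads if r.pos >= 0 and r.contig is not None]
        located.sort(key=lambda r: (r.contig, r.pos))
        self._by_contig: dict[str, list[AlignedRead]] = {}
        for r in located:
            self._by_contig.setdefault(r.contig, []).append(r)
        self._pos: dict[str, list[int]] = {
            c: [r.pos for r in rs] for c, rs in self._by_contig.items()
        }
        self._max_span = max(
            (r.reference_length if r.is_mapped else 1 for r in located), default=1
        )

    def window(self, contig: str, lo: int, hi: int) -> list[AlignedRead]:
        rs = self._by_contig.get(contig, [])
        if not rs:
            return []
        start = bisect_left(self._pos[contig], lo - self._max_span)
        out = []
        for r in rs[start:]:
            if r.pos >= hi:
                break
            end = r.reference_end if r.is_mapped else r.pos + 1
            if end > lo:
                out.append(r)
        return out


def call_insertions(
    reads: list[AlignedRead],
    reference: ReferenceAccessor,
    cfg: CallerConfig | None = None,
    stats: LibraryStats | None = None,
) -> tuple[list[InsertionCall], list[dict], LibraryStats]:
    """Run the full caller on in-memory records.

    Returns (calls, diagnostics rows, library stats).  Each diagnostics row
    describes one candidate breakpoint and, for rejected candidates, the
    reason: too-few complementary clip types (``failed_evidence``) or
    insufficient spanning/OEA support (``failed_support``).
    """
    cfg = cfg or CallerConfig()
    genome_len = sum(reference.length(c) for c in reference.contigs())
    if stats is None:
        stats = estimate_library_stats(reads, genome_len)
    if cfg.cov_override is not None:
        stats = LibraryStats(stats.mu, stats.sigma, cfg.cov_override, stats.read_len)

    # stage 1: soft-clip extraction + similarity screen
    kept = []
    for r in reads:
        if not r.is_mapped or r.mapq < cfg.min_mapq:
            continue
        for clip in extract_softclips(r, cfg.screen.min_clip_len):
            s_r = corresponding_ref_segment(clip, reference)
            if s_r and screen_clip(clip, s_r, cfg.screen):
                classify_clip(clip)
                kept.append(clip)
    kept.sort(key=lambda c: (c.contig, c.ref_pos))

    # stage 2: candidate breakpoints + evidence predicate
    candidates = cluster_clips(kept, cfg.window)
    index = _ReadIndex(reads)
    calls: list[InsertionCall] = []
    diagnostics: list[dict] = []
    for bp in candidates:
        types = bp.types_present()
        bp.evidence_ok = evidence_satisfied(types)
        row = {
            "contig": bp.contig,
            "position": bp.position,
            "n_clips": len({(c.read_name, c.clip_type) for c in bp.psd}),
            "types": ",".join(sorted(types)),
            "evidence_ok": bp.evidence_ok,
            "n_spanning": "",
            "n_oea": "",
            "filter_ok": "",
            "reason": "",
        }
        if not bp.evidence_ok:
            row["reason"] = "failed_evidence"
            diagnostics.append(row)
            continue

        # stage 3: insert-size support filter
        lo, hi = support_region(bp.position, stats)
        region_reads = index.window(bp.contig, lo, hi)
        counts = count_support(region_reads, bp.position)
        keep = filter_breakpoint(bp, counts, stats, cfg.min_support)
        row["n_spanning"], row["n_oea"] = counts
        row["filter_ok"] = keep
        if not keep:
            row["reason"] = "failed_support"
            diagnostics.append(row)
            continue
        diagnostics.append(row)

        # stage 4: genotype from spanning-pair insert sizes
        pairs = collect_pairs(region_reads, bp.position, stats)
        gt = call_genotype(pairs, cfg.genotype)

        call = InsertionCall(
            contig=bp.contig,
            position=bp.position,
            genotype=gt,
            n_spanning=counts[0],
            n_oea=counts[1],
            n_clips=row["n_clips"],
        )

        # stage 5: local assembly of the inserted sequence
        if not cfg.skip_assembly:
            _assemble_call(call, bp, region_reads, reference, stats, cfg.assembly)
        calls.append(call)

    calls.sort(key=lambda c: (c.contig, c.position))
    return calls, diagnostics, stats


def _assemble_call(
    call: InsertionCall,
    bp: CandidateBreakpoint,
    region_reads: list[AlignedRead],
    reference: ReferenceAccessor,
    stats: LibraryStats,
    acfg: AssemblyConfig,
) -> None:
    gathered = asm.gather_reads(region_reads, bp, stats)
    if not gathered:
        return
    try:
        contigs = asm.assemble(gathered, acfg)
    except ValueError:
        return
    best: tuple[int, str, int] | None = None
    for contig in contigs:
        placement = asm.place_contig(
            contig, reference, bp.contig, bp.position, stats, acfg
        )
        if placement is None:
            continue
        hit = asm.extract_insertion(placement, min_sv_len=acfg.min_sv_len)
        if hit is None:
            continue
        if best is None or hit[0] > best[0]:
            best = hit
    if best is not None:
        ins_len, ins_seq, refined = best
        refined, ins_seq = asm.left_normalize_insertion(
            refined, ins_seq, reference, bp.contig
        )
        call.ins_len = ins_len
        call.ins_seq = ins_seq
        call.position = refined


def run_call(
    bam: str | Path,
    ref: str | Path,
    out_vcf: str | Path,
    cfg: CallerConfig | None = None,
    diagnostics_tsv: str | Path | None = None,
) -> list[InsertionCall]:
    """File-level entry point: SAM/BAM + FASTA in, VCF (+ diagnostics TSV) out."""
    reads = list(read_alignments(bam))
    reference = ReferenceAccessor(ref)
    calls, diagnostics, _ = call_insertions(reads, reference, cfg)
    write_vcf(calls, reference, out_vcf)
    if diagnostics_tsv is not None:
        _write_diagnostics(diagnostics, diagnostics_tsv)
    return calls


def _write_diagnostics(rows: list[dict], path: str | Path) -> None:
    cols = [
        "contig",
        "position",
        "n_clips",
        "types",
        "evidence_ok",
        "n_spanning",
        "n_oea",
        "filter_ok",
        "reason",
    ]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def run_simulate(cfg, out_prefix: str | Path):
    """Simulate a dataset and write SAM + reference FASTA + truth VCF."""
    from .simulate import simulate_dataset, write_fasta, write_sam, write_truth_vcf

    data = simulate_dataset(cfg)
    prefix = str(out_prefix)
    write_sam(data, prefix + ".sam")
    write_fasta(data, prefix + ".fasta")
    write_truth_vcf(data, prefix + ".truth.vcf")
    return data


def run_evaluate(calls_vcf, truth_vcf, tol: int = 10, out_tsv=None) -> dict:
    from .evaluate import evaluate_vcfs

    return evaluate_vcfs(calls_vcf, truth_vcf, tol=tol, out_tsv=out_tsv)


def benchmark_simulation(sim_cfg, caller_cfg: CallerConfig | None = None, tol: int = 10) -> dict:
    """Simulate -> call -> score in memory; the standard self-test loop.

    Returns position metrics (percent scale), genotype accuracy on true
    positives, and assembly accuracy (fraction of assembled true positives
    with length within +/-5 bp, and with the exact inserted sequence).
    """
    from .evaluate import match_calls, precision_recall_f
    from .simulate import simulate_dataset

    data = simulate_dataset(sim_cfg)
    reference = ReferenceAccessor({data.contig: data.reference})
    calls, _, _ = call_insertions(data.reads, reference, caller_cfg)
    counts = match_calls(
        [c.position for c in calls], [t.position for t in data.truth], tol
    )
    pr, rc, f = precision_recall_f(counts)
    canon = {"hom": "homozygous", "het": "heterozygous"}
    gt_ok = n_tp = len_ok = seq_ok = assembled = 0
    for c in calls:
        near = [t for t in data.truth if abs(t.position - c.position) <= tol]
        if not near:
            continue
        t = near[0]
        n_tp += 1
        gt_ok += canon[t.genotype] == c.genotype.genotype
        if c.ins_len is not None:
            assembled += 1
            len_ok += abs(c.ins_len - t.ins_len) <= 5
            seq_ok += c.ins_seq == t.ins_seq
    return {
        "n_calls": len(calls),
        "n_truth": len(data.truth),
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "precision": pr,
        "recall": rc,
        "f_score": f,
        "genotype_accuracy": gt_ok / n_tp if n_tp else float("nan"),
        "n_assembled_tp": assembled,
        "len_within_5_frac": len_ok / assembled if assembled else float("nan"),
        "exact_seq_frac": seq_ok / assembled if assembled else float("nan"),
    }
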