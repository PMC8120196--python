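"""Benchmarking of insertion calls against ground truth.

A called breakpoint counts as a true positive when it lies within a small
tolerance (default 10 bp) of an unmatched truth breakpoint; matching is
greedy nearest-first and one-to-one, so two calls near one truth record yield
one TP and one FP.  Precision, recall and F-score are reported on the
percentage scale, F being the harmonic mean of the other two.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "EvalCounts",
    "match_calls",
    "precision_recall_f",
    "evaluate_vcfs",
    "genotype_concordance",
]


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def match_calls(
    calls: Sequence[int], truth: Sequence[int], tol: int = 10
) -> EvalCounts:
    """One-to-one greedy matching of call positions to truth positions.

    Candidate pairs within ``tol`` are taken nearest-first (ties to the
    leftmost call, then leftmost truth); every matched pair is a TP,
    leftover calls are FP and leftover truths FN.  Positions must belong to
    one contig; run per contig for multi-contig data.
    """
    calls = sorted(calls)
    truth = sorted(truth)
    pairs = [
        (abs(c - t), c, ci, ti)
        for ci, c in enumerate(calls)
        for ti, t in enumerate(truth)
        if abs(c - t) <= tol
    ]
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        tp += 1
    return EvalCounts(tp=tp, fp=len(calls) - tp, fn=len(truth) - tp)


def precision_recall_f(counts: EvalCounts) -> tuple[float, float, float]:
    """(precision, recall, F-score) in percent.

    An undefined metric (no calls, or no truth) is reported as 0.
    """
    pr = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    rc = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    return pr, rc, f


def genotype_concordance(
    calls: Sequence[tuple[int, str]],
    truth: Sequence[tuple[int, str]],
    tol: int = 10,
) -> tuple[int, int]:
    """(# genotype-concordant TPs, # TPs) under the same matching rule."""
    call_pos = [p for p, _ in calls]
    truth_pos = [p for p, _ in truth]
    pairs = [
        (abs(c - t), c, ci, ti)
        for ci, c in enumerate(call_pos)
        for ti, t in enumerate(truth_pos)
        if abs(c - t) <= tol
    ]
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    concordant = 0
    total = 0
    canon = {"hom": "homozygous", "het": "heterozygous"}
    for _, _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        total += 1
        g_call = canon.get(calls[ci][1], calls[ci][1])
        g_truth = canon.get(truth[ti][1], truth[ti][1])
        if g_call == g_truth:
            concordant += 1
    return concordant, total


def evaluate_vcfs(
    calls_vcf: str | Path,
    truth_vcf: str | Path,
    tol: int = 10,
    out_tsv: str | Path | None = None,
    size_bins: Sequence[tuple[int, int]] = ((50, 300), (301, 600), (601, 1000), (1001, 1500)),
) -> dict:
    """Score a call VCF against a truth VCF; optionally write a metrics TSV."""
    from .io_alignment import read_vcf_calls

    calls = read_vcf_calls(calls_vcf)
    truth = read_vcf_calls(truth_vcf)
    contigs = sorted({r["contig"] for r in truth} | {r["contig"] for r in calls})
    total = EvalCounts()
    for contig in contigs:
        c = [r["position"] for r in calls if r["contig"] == contig]
        t = [r["position"] for r in truth if r["contig"] == contig]
        part = match_calls(c, t, tol)
        total = EvalCounts(total.tp + part.tp, total.fp + part.fp, total.fn + part.fn)
    pr, rc, f = precision_recall_f(total)
    conc, n_tp = genotype_concordance(
        [(r["position"], r["genotype"]) for r in calls if r["genotype"]],
        [(r["position"], r["genotype"]) for r in truth if r["genotype"]],
        tol,
    )
    result = {
        "tp": total.tp,
        "fp": total.fp,
        "fn": total.fn,
        "precision": pr,
        "recall": rc,
        "f_score": f,
        "genotype_concordant": conc,
        "genotype_total": n_tp,
    }
    if out_tsv is not None:
        rows = ["bin\ttp\tfp\tfn\tprecision\trecall\tf_score"]
        rows.append(
            f"all\t{total.tp}\t{total.fp}\t{total.fn}\t{pr:.3f}\t{rc:.3f}\t{f:.3f}"
        )
        for lo, hi in size_bins:
            t_bin = [r["position"] for r in truth if r["svlen"] and lo <= r["svlen"] <= hi]
            if not t_bin:
                continue
            c_all = [r["position"] for r in calls]
            part = match_calls(c_all, t_bin, tol)
            # FP is not size-attributable; report bin recall only
            rcb = 100.0 * part.tp / (part.tp + part.fn) if part.tp + part.fn else 0.0
            rows.append(f"{lo}-{hi}\t{part.tp}\t.\t{part.fn}\t.\t{rcb:.3f}\t.")
        Path(out_tsv).write_text("\n".join(rows) + "\n")
    return result
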