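"""Genotyping of insertion breakpoints from spanning-pair insert sizes.

A fragment whose mates map on either side of an insertion loses the inserted
bases from its apparent insert size, so its observed template length shifts
down by roughly the insertion length.  At a homozygous site every spanning
fragment crosses the insertion and the insert sizes form a single shifted
mode; at a heterozygous site fragments from the unmodified haplotype keep the
library mode, giving two modes.  Density clustering (DBSCAN, eps = 50 bp,
min_samples = 2 by default) on the insert sizes counts the modes: two or more
clusters -> heterozygous, at most one -> homozygous.  The opposite mapping
(one cluster -> heterozygous) is kept behind ``rule='literal'`` for
comparison.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .insert_filter import support_region
from .io_alignment import AlignedRead, LibraryStats

__all__ = [
    "SpanningPair",
    "GenotypeConfig",
    "GenotypeCall",
    "collect_pairs",
    "density_cluster",
    "call_genotype",
]


@dataclass(frozen=True)
class SpanningPair:
    """One both-mapped pair spanning a breakpoint: mate positions and insert size."""

    p_l: int
    p_r: int
    i: int

    def __post_init__(self) -> None:
        if self.p_l > self.p_r:
            raise ValueError("left mate position must not exceed right mate position")
        if self.i <= 0:
            raise ValueError("insert size must be positive")


@dataclass
class GenotypeConfig:
    eps: float = 50.0
    min_samples: int = 2
    feature_space: Literal["insert_size_only", "full_triple"] = "insert_size_only"
    rule: Literal["two_cluster_het", "literal"] = "two_cluster_het"

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class GenotypeCall:
    genotype: Literal["homozygous", "heterozygous"]
    n_clusters: int
    n_noise: int
    low_confidence: bool = False


def collect_pairs(
    alignments: Iterable[AlignedRead], p: int, stats: LibraryStats
) -> list[SpanningPair]:
    """Spanning pairs around p, one per both-mapped pair whose fragment straddles it.

    ``alignments`` should already be restricted to the support region; the
    region bound is re-checked here so callers can pass a wider stream.
    Pairs with a soft-clipped member are excluded: a clip truncates the
    apparent outer span at the clip boundary, so such pairs measure clip
    placement rather than fragment geometry and would smear the insert-size
    modes the genotype call depends on.
    """
    lo, hi = support_region(p, stats)
    by_name: dict[str, list[AlignedRead]] = defaultdict(list)
    skip: set[str] = set()
    for r in alignments:
        if r.is_mapped and r.has_soft_clip():
            skip.add(r.query_name)
        if r.is_mapped and r.mate_is_mapped and lo <= r.pos < hi:
            by_name[r.query_name].append(r)
    for name in skip:
        by_name.pop(name, None)
    out: list[SpanningPair] = []
    for reads in by_name.values():
        r = reads[0]
        if r.template_len == 0:
            continue
        positions = {x.pos for x in reads}
        if r.mate_pos is not None:
            positions.add(r.mate_pos)
        p_l, p_r = min(positions), max(positions)
        i = abs(r.template_len)
        end = max(max(x.reference_end for x in reads), p_l + i)
        if p_l < p <= end:
            out.append(SpanningPair(p_l=p_l, p_r=p_r, i=i))
    return out


def density_cluster(points: Sequence[Sequence[float]] | np.ndarray, cfg: GenotypeConfig) -> np.ndarray:
    """DBSCAN labels (cluster id per point, -1 = noise), deterministic.

    Standard DBSCAN semantics with Euclidean distance: a core point has at
    least ``min_samples`` points (itself included) within ``eps``; clusters
    are connected components of core points plus their border points.
    """
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return np.empty(0, dtype=int)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    labels = DBSCAN(eps=cfg.eps, min_samples=cfg.min_samples).fit(arr).labels_
    return _canonical_labels(arr, labels)


def _canonical_labels(arr: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Renumber clusters by their minimum point (lexicographic), so labels are
    independent of input order."""
    ids = sorted(set(labels) - {-1}, key=lambda k: tuple(arr[labels == k].min(axis=0)))
    remap = {old: new for new, old in enumerate(ids)}
    remap[-1] = -1
    return np.array([remap[v] for v in labels], dtype=int)


def call_genotype(pairs: Sequence[SpanningPair], cfg: GenotypeConfig | None = None) -> GenotypeCall:
    """Genotype a breakpoint from its spanning pairs.

    Fewer than ``min_samples`` pairs cannot form any cluster; the site is
    reported homozygous with a low-confidence flag (no normal-insert-size
    mode was observed, consistent with both haplotypes carrying the event).
    """
    cfg = cfg or GenotypeConfig()
    if len(pairs) < cfg.min_samples:
        return GenotypeCall("homozygous", n_clusters=0, n_noise=len(pairs), low_confidence=True)
    if cfg.feature_space == "full_triple":
        points = np.array([[q.p_l, q.p_r, q.i] for q in pairs], dtype=float)
    else:
        points = np.array([[q.i] for q in pairs], dtype=float)
    labels = density_cluster(points, cfg)
    n_clusters = len(set(labels.tolist()) - {-1})
    n_noise = int(np.sum(labels == -1))
    if cfg.rule == "literal":
        gt = "heterozygous" if n_clusters == 1 else "homozygous"
    else:
        gt = "heterozygous" if n_clusters >= 2 else "homozygous"
    return GenotypeCall(gt, n_clusters=n_clusters, n_noise=n_noise)
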