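"""Gene-level and genome-level coverage summaries.

Per-gene **Coverage** is the number of reads overlapping the gene, **Depth**
the maximum per-base pileup over the gene's span, and **Focus** an index in
[0, 1] of how concentrated the overlaps are: 1 when every read shares a
common region, 0 when the reads are spread along the gene with no two
overlapping.  The endpoints fix Focus only partially; this package uses
(depth - 1) / (coverage - 1), which reproduces both endpoints and grows
monotonically with overlap concentration.  A single-read gene gets Focus 1
by convention (a singleton trivially shares its own region); set
``singleton_focus=None`` for NaN instead.

Genome-level summaries: a fixed-window histogram of read starts (40 kb
windows by default), three-way Venn counts of the gene sets recovered by
the Sec / SRP / TAT libraries, the statistical fold coverage of a library,
and the 1/6 chance expectation for frame matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synth import Gene

__all__ = [
    "GeneMetrics",
    "WindowHistogram",
    "VennCounts",
    "gene_metrics",
    "window_histogram",
    "venn_overlap",
    "fold_coverage",
    "chance_genic_fraction",
    "genes_identified",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneMetrics:
    gene_id: str
    coverage: int
    depth: int
    focus: float


def gene_metrics(
    hits: Sequence[Interval],
    gene: Gene,
    singleton_focus: float | None = 1.0,
) -> GeneMetrics:
    """Coverage / Depth / Focus for one gene from read intervals.

    ``hits`` are 0-based half-open read intervals on the same genome;
    strand is irrelevant for pileup.  Focus = (depth - 1) / (coverage - 1)
    for coverage >= 2; NaN for coverage 0; ``singleton_focus`` for
    coverage 1.
    """
    span = gene.length
    pile = np.zeros(span + 1, dtype=np.int64)
    coverage = 0
    for s, e in hits:
        a, b = max(s, gene.start), min(e, gene.end)
        if b <= a:
            continue
        coverage += 1
        pile[a - gene.start] += 1
        pile[b - gene.start] -= 1
    depth = int(np.cumsum(pile[:-1]).max()) if coverage else 0
    if coverage == 0:
        focus = math.nan
    elif coverage == 1:
        focus = math.nan if singleton_focus is None else float(singleton_focus)
    else:
        focus = (depth - 1) / (coverage - 1)
    return GeneMetrics(gene.gene_id, coverage, depth, focus)


@dataclass(frozen=True)
class WindowHistogram:
    window_size: int
    counts: tuple[int, ...]

    @property
    def n_reads(self) -> int:
        return sum(self.counts)


def window_histogram(
    hits: Sequence[Interval],
    genome_length: int,
    window_size: int = 40_000,
    by: str = "start",
) -> WindowHistogram:
    """Histogram of reads along the genome in fixed windows.

    Each read falls in window floor(anchor / window_size), where the anchor
    is its start coordinate (default) or midpoint (``by='midpoint'``);
    counts conserve the number of reads.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if by not in ("start", "midpoint"):
        raise ValueError("by must be 'start' or 'midpoint'")
    n_windows = math.ceil(genome_length / window_size)
    if hits:
        anchors = np.array(
            [s if by == "start" else (s + e) // 2 for s, e in hits], dtype=np.int64
        )
        counts = np.bincount(anchors // window_size, minlength=n_windows)
    else:
        counts = np.zeros(n_windows, dtype=np.int64)
    return WindowHistogram(window_size, tuple(int(c) for c in counts))


@dataclass(frozen=True)
class VennCounts:
    """Region cardinalities of a three-set (Sec/SRP/TAT) partition."""

    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def union_total(self) -> int:
        return (self.only_a + self.only_b + self.only_c
                + self.ab_only + self.ac_only + self.bc_only + self.abc)


def venn_overlap(a: Iterable[str], b: Iterable[str], c: Iterable[str]) -> VennCounts:
    """Exact three-set Venn region counts over gene-id sets."""
    a, b, c = set(a), set(b), set(c)
    return VennCounts(
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(a & b & c),
    )


def fold_coverage(n_clones: float, mean_insert: float, genome_length: float) -> float:
    """Statistical fold coverage: clones x mean insert length / genome size."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return n_clones * mean_insert / genome_length


def chance_genic_fraction() -> float:
    """Chance that a random cloned fragment reads a gene it overlaps in
    frame: one of 2 strands x 3 frame offsets, i.e. 1/6 (~17%)."""
    return 1.0 / 6.0


def genes_identified(
    hits_by_library: Mapping[str, Sequence[Interval]],
    genes: Sequence[Gene],
) -> dict[str, set[str]]:
    """Gene ids hit by >= 1 read, per library plus the pooled ``'union'``.

    A gene counts as identified iff at least one mapped read overlaps its
    interval, regardless of read class.
    """
    genes = sorted(genes, key=lambda g: g.start)
    starts = np.array([g.start for g in genes], dtype=np.int64)
    ends = np.array([g.end for g in genes], dtype=np.int64)
    out: dict[str, set[str]] = {}
    union: set[str] = set()
    for lib, hits in hits_by_library.items():
        found: set[str] = set()
        for s, e in hits:
            lo = int(np.searchsorted(ends, s, side="right"))
            hi = int(np.searchsorted(starts, e, side="left"))
            for g in genes[lo:hi]:
                found.add(g.gene_id)
        out[lib] = found
        union |= found
    out["union"] = union
    return out
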