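"""Perfect-match read mapping and genic / non-genic ORF classification.

Sequencing errors make frame assignment ambiguous, so the analysable subset
is the "perfect sequences": reads that match the reference exactly over
their full length, fixing the precise start, end and strand of the cloned
insert.  Each perfect read is then classified by the fusion-frame rule and
by comparison with the gene annotation:

* ``non_orf`` — the read's frame-0 translation (in its cloned orientation)
  hits a stop codon or breaks the lactamase frame;
* ``genic_orf`` — the read is a stop-free fusion ORF and its cloned frame
  and strand coincide with an annotated gene it overlaps;
* ``nongenic_orf`` — stop-free, but in a frame (or on a strand, or in a
  region) that matches no gene;
* ``unmapped`` — no exact hit on either strand.

Reads are assumed to be reported in vector orientation, so the cloned frame
is frame 0 of the read as given.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .fragmentation import Fragment
from .selection import is_fusion_orf
from .seq import revcomp
from .synth import Gene, Genome

__all__ = [
    "MappedRead",
    "ReadClass",
    "ClassifiedRead",
    "ClassificationReport",
    "exact_map",
    "perfect_match_filter",
    "classify_read",
    "classify_reads",
    "classification_report",
    "frame_matches_gene",
    "frame_match_fraction",
]


class ReadClass(str, Enum):
    GENIC_ORF = "genic_orf"
    NONGENIC_ORF = "nongenic_orf"
    NON_ORF = "non_orf"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class MappedRead:
    """An exact-match alignment: the genome slice (reverse-complemented for
    '-') equals the read over its full length."""

    read_id: str
    start: int
    end: int
    strand: str
    n_hits: int = 1


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    start: int | None
    end: int | None
    strand: str | None
    read_class: ReadClass
    gene_id: str | None
    n_hits: int
    multimapped: bool = False


def exact_map(read: str, genome: Genome, min_length: int = 20) -> list[MappedRead]:
    """All loci where the read matches the genome exactly, on either strand.

    A '+' hit means the read equals ``genome[start:end]``; a '-' hit means
    the read equals its reverse complement.  Returns an empty list for an
    unmapped read.  Overlapping occurrences are all reported.
    """
    if len(read) < min_length:
        raise ValueError(f"read shorter than the {min_length} nt minimum")
    hits: list[tuple[int, int, str]] = []
    for strand, query in (("+", read), ("-", revcomp(read))):
        pos = genome.sequence.find(query)
        while pos != -1:
            hits.append((pos, pos + len(read), strand))
            pos = genome.sequence.find(query, pos + 1)
    hits.sort()
    n = len(hits)
    return [MappedRead("", s, e, st, n) for s, e, st in hits]


def perfect_match_filter(
    reads: Sequence[tuple[str, str]], genome: Genome, min_length: int = 20
) -> list[tuple[str, str]]:
    """Keep only reads with at least one exact hit; order preserved."""
    return [
        (rid, seq)
        for rid, seq in reads
        if len(seq) >= min_length and exact_map(seq, genome, min_length)
    ]


def _overlapping_genes(genes: Sequence[Gene], start: int, end: int) -> list[Gene]:
    """Genes (sorted, non-overlapping) intersecting [start, end)."""
    starts = [g.start for g in genes]
    i = max(0, bisect_right(starts, start) - 1)
    out = []
    for g in genes[i:]:
        if g.start >= end:
            break
        if g.end > start:
            out.append(g)
    return out


def frame_matches_gene(start: int, end: int, strand: str, gene: Gene) -> bool:
    """Does a cloned interval read in the gene's natural frame and strand?

    The cloned frame is anchored at the interval's first coding base: for
    '+' genes that base must sit at a codon start, (start - gene.start)
    mod 3 = 0; for '-' genes the anchor runs from the gene's right edge,
    (gene.end - end) mod 3 = 0.
    """
    if strand != gene.strand:
        return False
    if gene.strand == "+":
        return (start - gene.start) % 3 == 0
    return (gene.end - end) % 3 == 0


def _in_frame_codon_overlap(start: int, end: int, gene: Gene) -> int:
    """Number of complete gene-frame codons inside the overlap."""
    a, b = max(start, gene.start), min(end, gene.end)
    if b <= a:
        return 0
    if gene.strand == "+":
        c0 = gene.start + 3 * math.ceil((a - gene.start) / 3)
        return max(0, (b - c0) // 3)
    e0 = gene.end - 3 * math.ceil((gene.end - b) / 3)
    return max(0, (e0 - a) // 3)


def classify_read(
    hit: MappedRead,
    genes: Sequence[Gene],
    genome: Genome,
    amber_suppression: bool = False,
    min_overlap_codons: int = 1,
) -> tuple[ReadClass, str | None]:
    """Classify one exact hit; returns (class, gene_id or None).

    ``genes`` must be sorted by start and pairwise non-overlapping (the
    bacterial single-CDS gene model).  A genic call requires strand and
    frame agreement with an overlapping gene plus at least
    ``min_overlap_codons`` complete in-frame codons shared with it; when
    several genes qualify the one with the largest overlap is reported.
    """
    seq = genome.sequence[hit.start : hit.end]
    insert = seq if hit.strand == "+" else revcomp(seq)
    if not is_fusion_orf(insert, amber_suppression):
        return ReadClass.NON_ORF, None
    best: tuple[int, str] | None = None
    for g in _overlapping_genes(genes, hit.start, hit.end):
        if not frame_matches_gene(hit.start, hit.end, hit.strand, g):
            continue
        if _in_frame_codon_overlap(hit.start, hit.end, g) < min_overlap_codons:
            continue
        ov = min(hit.end, g.end) - max(hit.start, g.start)
        if best is None or ov > best[0]:
            best = (ov, g.gene_id)
    if best is not None:
        return ReadClass.GENIC_ORF, best[1]
    return ReadClass.NONGENIC_ORF, None


_PRIORITY = {ReadClass.GENIC_ORF: 2, ReadClass.NONGENIC_ORF: 1, ReadClass.NON_ORF: 0}


def classify_reads(
    reads: Sequence[tuple[str, str]],
    genome: Genome,
    genes: Sequence[Gene],
    amber_suppression: bool = False,
    min_overlap_codons: int = 1,
    min_length: int = 20,
) -> list[ClassifiedRead]:
    """Map and classify a batch of reads.

    Reads without an exact hit are reported ``unmapped``.  Multi-hit reads
    are classified by the hit with the highest class priority (genic over
    non-genic ORF) and flagged ``multimapped``.
    """
    genes = sorted(genes, key=lambda g: g.start)
    out: list[ClassifiedRead] = []
    for rid, seq in reads:
        if len(seq) < min_length:
            out.append(ClassifiedRead(rid, None, None, None, ReadClass.UNMAPPED, None, 0))
            continue
        hits = exact_map(seq, genome, min_length)
        if not hits:
            out.append(ClassifiedRead(rid, None, None, None, ReadClass.UNMAPPED, None, 0))
            continue
        best = None
        for h in hits:
            cls, gid = classify_read(h, genes, genome, amber_suppression, min_overlap_codons)
            cand = (_PRIORITY[cls], h, cls, gid)
            if best is None or cand[0] > best[0]:
                best = cand
        _, h, cls, gid = best
        out.append(
            ClassifiedRead(rid, h.start, h.end, h.strand, cls, gid, len(hits),
                           multimapped=len(hits) > 1)
        )
    return out


@dataclass(frozen=True)
class ClassificationReport:
    """Headline fractions over a perfect-match read set.

    ``genic_fraction`` factorises exactly as ``orf_fraction *
    genic_given_orf`` (both computed over mapped reads); fractions are NaN
    when their denominator is zero.
    """

    n_total: int
    n_mapped: int
    n_orf: int
    n_genic: int
    orf_fraction: float
    genic_given_orf: float
    genic_fraction: float


def classification_report(classes: Iterable[ReadClass]) -> ClassificationReport:
    """Summarise read classes into the headline fractions."""
    classes = list(classes)
    n_total = len(classes)
    n_mapped = sum(c is not ReadClass.UNMAPPED for c in classes)
    n_genic = sum(c is ReadClass.GENIC_ORF for c in classes)
    n_orf = n_genic + sum(c is ReadClass.NONGENIC_ORF for c in classes)
    orf_fraction = n_orf / n_mapped if n_mapped else math.nan
    genic_given_orf = n_genic / n_orf if n_orf else math.nan
    genic_fraction = n_genic / n_mapped if n_mapped else math.nan
    return ClassificationReport(
        n_total, n_mapped, n_orf, n_genic, orf_fraction, genic_given_orf, genic_fraction
    )


def frame_match_fraction(
    fragments: Sequence[Fragment], genes: Sequence[Gene]
) -> tuple[int, int]:
    """(matching, overlapping) counts for the chance frame-match estimate.

    A fragment overlapping at least one gene is scored against its
    corresponding gene — the overlapping gene with the largest overlap —
    and counts as matching iff its cloned strand and frame coincide with
    that gene's.  No ORF or survival filtering is applied, so with uniform
    random fragments the match fraction has expectation exactly 1/6 (one of
    2 strands x 3 frame offsets).
    """
    genes = sorted(genes, key=lambda g: g.start)
    n_overlap = n_match = 0
    for f in fragments:
        cands = _overlapping_genes(genes, f.start, f.end)
        if not cands:
            continue
        n_overlap += 1
        g = max(cands, key=lambda g: min(f.end, g.end) - max(f.start, g.start))
        if frame_matches_gene(f.start, f.end, f.cloned_strand, g):
            n_match += 1
    return n_match, n_overlap
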