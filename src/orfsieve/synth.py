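"""Synthetic annotated genomes, folding qualities, and sequencing errors.

This module stands in for the wet-lab inputs of the ORF-filtering workflow:
an intronless bacterial genome with annotated protein-coding genes, the
folding behaviour of the encoded polypeptide fragments, and the error
profile of pyrosequencing-style reads.  Everything is deterministic given a
seed so the downstream stages are testable without any external data.

Genes are embedded as runs of random sense codons terminated by a stop
codon, on either strand, placed uniformly without overlap; intergenic
sequence is composition-random at the requested GC content.  No codon-usage
table is applied: the analysis downstream is driven by reading-frame and
stop-codon statistics, not by codon biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import SENSE_CODONS, STOP_CODONS, codons, require_dna, revcomp

__all__ = [
    "Genome",
    "Gene",
    "GenomeSpec",
    "FoldingQualityModel",
    "ErrorModel",
    "generate_genome",
    "assign_folding_quality",
    "simulate_sequencing_errors",
]

_STOPS = tuple(sorted(STOP_CODONS))


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence restricted to the ACGT alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        require_dna(self.sequence, f"genome {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Gene:
    """An annotated single-CDS coding interval, 0-based half-open.

    The coding strand carries a stop-free reading frame anchored at
    ``start`` for '+' genes and at ``end`` (reading leftwards) for '-'
    genes; the terminal codon is a stop codon.
    """

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval "
                             f"[{self.start}, {self.end})")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: length not a multiple of 3")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def coding_sequence(self, genome: Genome) -> str:
        """The gene's sequence read 5'->3' on its coding strand."""
        s = genome.sequence[self.start : self.end]
        return s if self.strand == "+" else revcomp(s)


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic genome; see :func:`generate_genome`."""

    genome_length: int = 100_000
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (300, 3000)
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")
        if lo < 6 or hi < lo:
            raise ValueError("gene_length_range must satisfy 6 <= min <= max")
        if self.n_genes * lo > self.genome_length:
            raise ValueError(
                "infeasible packing: n_genes x min gene length exceeds genome_length"
            )


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    # S/W symmetric: G and C each at gc/2, A and T each at (1-gc)/2.
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _gene_coding_sequence(length: int, rng: np.random.Generator) -> str:
    n_codons = length // 3 - 1
    body = rng.choice(len(SENSE_CODONS), size=n_codons)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "".join(SENSE_CODONS[i] for i in body) + stop


def generate_genome(spec: GenomeSpec) -> tuple[Genome, list[Gene]]:
    """Generate a synthetic annotated genome.

    Gene lengths are drawn uniformly over the multiples of 3 inside
    ``gene_length_range``; each gene is a run of random sense codons plus a
    terminal stop, so every gene is stop-free by construction.  Genes are
    placed uniformly without overlap (free sequence is split into random
    intergenic gaps) and assigned to either strand with equal probability.

    Returns the genome and its genes sorted by start coordinate.

    Raises
    ------
    ValueError
        If the requested genes cannot be packed into the genome.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    lo3, hi3 = -(-lo // 3), hi // 3  # ceil, floor
    # Resample until the drawn lengths pack (deterministic given the seed);
    # give up only when packing is genuinely impossible at these settings.
    for _ in range(1000):
        lengths = 3 * rng.integers(lo3, hi3 + 1, size=spec.n_genes)
        free = spec.genome_length - int(lengths.sum())
        if free >= 0:
            break
    else:
        raise ValueError(
            "infeasible packing: genes cannot be placed without overlap "
            f"(n_genes={spec.n_genes}, range={spec.gene_length_range}, "
            f"genome_length={spec.genome_length})"
        )

    # Split the free sequence into n_genes + 1 random gaps (uniform composition).
    cuts = np.sort(rng.integers(0, free + 1, size=spec.n_genes))
    gaps = np.diff(np.concatenate(([0], cuts, [free])))

    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i in range(spec.n_genes):
        gap = int(gaps[i])
        parts.append(_random_dna(gap, spec.gc_content, rng).tobytes().decode())
        pos += gap
        length = int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _gene_coding_sequence(length, rng)
        parts.append(cds if strand == "+" else revcomp(cds))
        genes.append(Gene(f"gene_{i + 1:04d}", pos, pos + length, strand))
        pos += length
    parts.append(_random_dna(int(gaps[-1]), spec.gc_content, rng).tobytes().decode())

    genome = Genome("synthetic", "".join(parts))
    assert genome.length == spec.genome_length
    return genome, genes


@dataclass(frozen=True)
class FoldingQualityModel:
    """Class-conditional folding quality as Beta draws on [0, 1].

    Fragments of real genes encode polypeptides that evolved to fold, so
    genic inserts draw from a Beta skewed high (default Beta(5, 2), mean
    5/7) and spurious stop-free frames from its mirror (Beta(2, 5), mean
    2/7); the genic distribution stochastically dominates the non-genic one.
    """

    genic_shape: tuple[float, float] = (5.0, 2.0)
    nongenic_shape: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        for a, b in (self.genic_shape, self.nongenic_shape):
            if a <= 0 or b <= 0:
                raise ValueError("Beta shape parameters must be positive")


def assign_folding_quality(
    read_class: str,
    params: FoldingQualityModel | None = None,
    size: int | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Draw folding qualities in [0, 1] for ``'genic'`` or ``'nongenic'`` inserts.

    Returns a scalar when ``size`` is None, else an array of length ``size``.
    """
    params = params or FoldingQualityModel()
    if read_class in ("genic", "genic_orf"):
        a, b = params.genic_shape
    elif read_class in ("nongenic", "nongenic_orf"):
        a, b = params.nongenic_shape
    else:
        raise ValueError(f"unknown read class {read_class!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = rng.beta(a, b, size=size)
    return float(out) if size is None else out


@dataclass(frozen=True)
class ErrorModel:
    """A 454-style read error model.

    substitution_rate
        Per-base substitution probability.
    homopolymer_indel_rate
        Per-run indel probability scale; a homopolymer run of length L >=
        ``min_run_length`` suffers a one-base insertion or deletion with
        probability min(1, rate * L), increasing in run length as is
        characteristic of pyrosequencing flow miscalls.
    """

    substitution_rate: float = 1e-3
    homopolymer_indel_rate: float = 5e-3
    min_run_length: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.homopolymer_indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("error rates must lie in [0, 1]")
        if self.min_run_length < 2:
            raise ValueError("min_run_length must be >= 2")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i


def _homopolymer_runs(s: str):
    """Yield (start, length) for maximal single-base runs."""
    i, n = 0, len(s)
    while i < n:
        j = i + 1
        while j < n and s[j] == s[i]:
            j += 1
        yield i, j - i
        i = j


def simulate_sequencing_errors(
    read: str,
    model: ErrorModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Return a mutated copy of ``read`` under the error model.

    Substitutions are applied per base, then homopolymer indels per run.
    With all rates zero the read is returned unchanged.
    """
    model = model or ErrorModel()
    require_dna(read, "read")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(model.seed if rng is None else rng)

    out = read
    p = model.substitution_rate
    if p > 0:
        arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
        hit = np.flatnonzero(rng.random(arr.size) < p)
        if hit.size:
            cur = _BASE_INDEX[arr[hit]]
            arr[hit] = _BASES[(cur + 1 + rng.integers(0, 3, size=hit.size)) % 4]
            out = arr.tobytes().decode()

    rate = model.homopolymer_indel_rate
    if rate > 0:
        pieces: list[str] = []
        for start, length in _homopolymer_runs(out):
            run = out[start : start + length]
            if length >= model.min_run_length and rng.random() < min(1.0, rate * length):
                run = run[:-1] if rng.random() < 0.5 else run + run[0]
            pieces.append(run)
        out = "".join(pieces)
    return out


def validate_gene(gene: Gene, genome: Genome, terminal_stop: bool = True) -> None:
    """Assert the full gene invariants against a genome; raises on violation."""
    if gene.end > genome.length:
        raise ValueError(f"gene {gene.gene_id} extends past the genome end")
    cds = gene.coding_sequence(genome)
    cods = list(codons(cds))
    if any(c in STOP_CODONS for c in cods[:-1]):
        raise ValueError(f"gene {gene.gene_id}: internal stop codon")
    if terminal_stop and cods[-1] not in STOP_CODONS:
        raise ValueError(f"gene {gene.gene_id}: terminal codon is not a stop")
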