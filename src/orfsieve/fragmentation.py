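"""Random fragmentation and blunt-end cloning in random orientation.

Emulates nebulisation of genomic DNA into 200-800 bp fragments and their
blunt-end ligation into the filtering vector: fragment positions are
uniform over the genome, lengths follow a configurable law (truncated
normal by default, matching the ~400 bp average observed for cloned
inserts), and the cloned orientation is a fair coin since blunt cloning has
no directional preference.  Fragments are drawn independently with
replacement — the physical library's diversity is vastly larger than any
simulated draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .seq import revcomp
from .synth import Genome

__all__ = ["Fragment", "LengthDistribution", "draw_fragments", "insert_sequence"]


@dataclass(frozen=True)
class Fragment:
    """A cloned genomic interval, 0-based half-open.

    ``cloned_strand`` is the genome strand whose 5'->3' reading equals the
    insert as it sits in the vector: '+' inserts read the plus-strand
    slice, '-' inserts its reverse complement.
    """

    genome_id: str
    start: int
    end: int
    cloned_strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")
        if self.cloned_strand not in ("+", "-"):
            raise ValueError("cloned_strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LengthDistribution:
    """Insert length law: uniform or truncated normal on [min, max] nt."""

    min: int = 200
    max: int = 800
    mean: float = 400.0
    shape: str = "truncated-normal"
    sd: float = 120.0

    def __post_init__(self) -> None:
        if self.min <= 0:
            raise ValueError("min length must be positive")
        if not (self.min <= self.mean <= self.max):
            raise ValueError("length law requires min <= mean <= max")
        if self.shape not in ("uniform", "truncated-normal"):
            raise ValueError("shape must be 'uniform' or 'truncated-normal'")
        if self.shape == "truncated-normal" and self.sd <= 0:
            raise ValueError("sd must be positive for truncated-normal")

    def _loc(self) -> float:
        # Solve for the location whose truncated mean equals the requested
        # mean; with asymmetric bounds the raw loc would bias the average.
        def shifted_mean(loc: float) -> float:
            a, b = (self.min - loc) / self.sd, (self.max - loc) / self.sd
            return stats.truncnorm.mean(a, b, loc=loc, scale=self.sd) - self.mean

        if self.min == self.max:
            return float(self.mean)
        return optimize.brentq(shifted_mean, self.min - 5 * self.sd,
                               self.max + 5 * self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.shape == "uniform":
            return rng.integers(self.min, self.max + 1, size=n)
        loc = self._loc()
        a, b = (self.min - loc) / self.sd, (self.max - loc) / self.sd
        draws = stats.truncnorm.rvs(a, b, loc=loc, scale=self.sd, size=n,
                                    random_state=rng)
        return np.clip(np.rint(draws).astype(np.int64), self.min, self.max)


def draw_fragments(
    genome: Genome,
    n: int,
    dist: LengthDistribution | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Fragment]:
    """Draw ``n`` independent fragments from the genome.

    Start positions are uniform over the valid range for each drawn length;
    cloned orientation is an independent fair coin.
    """
    dist = dist or LengthDistribution()
    if n < 1:
        raise ValueError("n must be >= 1")
    if dist.max > genome.length:
        raise ValueError(
            f"maximum fragment length {dist.max} exceeds genome length {genome.length}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lengths = dist.sample(n, rng)
    starts = rng.integers(0, genome.length - lengths + 1)
    strands = rng.random(n) < 0.5
    return [
        Fragment(genome.id, int(s), int(s + l), "+" if plus else "-")
        for s, l, plus in zip(starts, lengths, strands)
    ]


def insert_sequence(fragment: Fragment, genome: Genome) -> str:
    """The insert as cloned: plus-strand slice, or its reverse complement."""
    if fragment.end > genome.length:
        raise ValueError(
            f"fragment [{fragment.start}, {fragment.end}) out of bounds for "
            f"genome of length {genome.length}"
        )
    s = genome.sequence[fragment.start : fragment.end]
    return s if fragment.cloned_strand == "+" else revcomp(s)
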