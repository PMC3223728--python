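"""In-silico beta-lactamase ORF filtering and ampicillin selection.

A cloned fragment sits between a secretion leader (Sec, SRP or TAT) and the
mature beta-lactamase gene; the fusion is functional only if the insert
keeps both partners in frame (length divisible by 3) and contains no
in-frame stop codon.  Among such fusion ORFs, clones encoding well-folding
polypeptides tolerate more ampicillin: each clone gets a minimal inhibitory
concentration (MIC) that rises linearly with its folding quality, and
survival at a given ampicillin concentration is logistic in the log2 ratio
of MIC to concentration.  The quantitative survival model is an explicit
parameterised stand-in — the underlying experiment reports survival curves,
not per-clone MICs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .fragmentation import Fragment
from .seq import NON_AMBER_STOPS, STOP_CODONS, codons, require_dna

__all__ = [
    "Clone",
    "SelectionParams",
    "Library",
    "is_fusion_orf",
    "clone_mic",
    "survival_probability",
    "select_library",
]

LEADERS = ("Sec", "SRP", "TAT")


def is_fusion_orf(insert: str, amber_suppression: bool = False) -> bool:
    """Does the insert keep leader and lactamase fused in a stop-free frame?

    True iff the insert length is divisible by 3 and no frame-0 codon is a
    stop codon; with amber suppression the TAG codon is read through (the
    host's supE suppressor inserts glutamine) and only TAA/TGA disqualify.
    The insert is read in frame 0 from its first base: the vector junction
    contributes no frame offset.
    """
    require_dna(insert, "insert")
    if len(insert) % 3 != 0:
        return False
    stops = NON_AMBER_STOPS if amber_suppression else STOP_CODONS
    return all(c not in stops for c in codons(insert))


@dataclass(frozen=True)
class Clone:
    """A library member: a cloned fragment with its phenotype inputs."""

    fragment: Fragment
    insert: str
    leader: str
    folding_quality: float
    fusion_orf: bool

    def __post_init__(self) -> None:
        if self.leader not in LEADERS:
            raise ValueError(f"leader must be one of {LEADERS}")
        if not (0.0 <= self.folding_quality <= 1.0):
            raise ValueError("folding_quality must lie in [0, 1]")


@dataclass(frozen=True)
class SelectionParams:
    """Survival-model parameters, concentrations in ug/mL.

    Non-ORF clones sit at ``mic_nonorf`` (background resistance only);
    fusion-ORF clones interpolate from ``mic_base`` (quality 0) to
    ``mic_max`` (quality 1).  ``logistic_slope`` sets how sharply survival
    falls per doubling of ampicillin past the MIC.  Defaults put a library
    of random genomic fragments in a ~1% survival regime at the stringent
    end of the 0.25-100 ug/mL series.
    """

    mic_nonorf: float = 0.25
    mic_base: float = 0.5
    mic_max: float = 150.0
    logistic_slope: float = 2.0
    amber_suppression: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.mic_nonorf <= self.mic_base < self.mic_max):
            raise ValueError("require 0 < mic_nonorf <= mic_base < mic_max")
        if self.logistic_slope <= 0:
            raise ValueError("logistic_slope must be positive")


@dataclass(frozen=True)
class Library:
    """All clones carrying one leader."""

    leader: str
    clones: tuple[Clone, ...]

    def __post_init__(self) -> None:
        if any(c.leader != self.leader for c in self.clones):
            raise ValueError("all clones in a library must share its leader")

    def __len__(self) -> int:
        return len(self.clones)


def clone_mic(clone: Clone, params: SelectionParams) -> float:
    """The clone's minimal inhibitory concentration in ug/mL."""
    if not clone.fusion_orf:
        return params.mic_nonorf
    return params.mic_base + (params.mic_max - params.mic_base) * clone.folding_quality


def survival_probability(clone: Clone, amp: float, params: SelectionParams) -> float:
    """P(colony survives) on ampicillin ``amp`` ug/mL.

    At amp = 0 (chloramphenicol-only plates) every clone survives; otherwise
    survival is logistic in log2(MIC) - log2(amp), crossing 1/2 at the MIC
    and non-increasing in amp.
    """
    if amp < 0:
        raise ValueError("ampicillin concentration must be non-negative")
    if amp == 0:
        return 1.0
    mic = clone_mic(clone, params)
    return float(expit(params.logistic_slope * (np.log2(mic) - np.log2(amp))))


def select_library(
    library: Library,
    amp: float,
    params: SelectionParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[Library, float]:
    """Plate the library on ampicillin; return (survivors, survival rate).

    Each clone is retained independently with its survival probability;
    the rate is survivors / total.
    """
    params = params or SelectionParams()
    if len(library) == 0:
        raise ValueError("library is empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    probs = np.array([survival_probability(c, amp, params) for c in library.clones])
    keep = rng.random(len(probs)) < probs
    survivors = tuple(c for c, k in zip(library.clones, keep) if k)
    return replace(library, clones=survivors), float(keep.mean())


def survival_sweep(
    library: Library,
    concentrations: Sequence[float],
    params: SelectionParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[float, float]]:
    """Survival rate at each ampicillin concentration (independent platings)."""
    params = params or SelectionParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for amp in concentrations:
        _, rate = select_library(library, amp, params, rng)
        out.append((float(amp), rate))
    return out
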