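"""Small nucleotide-sequence helpers shared across the pipeline.

Only plain ACGT strings are handled; anything else is rejected at the
boundaries so downstream codon arithmetic can stay branch-free.
"""

from __future__ import annotations

from itertools import product

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: Stop codons that terminate translation when amber (TAG) suppression is on.
NON_AMBER_STOPS = frozenset({"TAA", "TGA"})
SENSE_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def is_dna(s: str) -> bool:
    return bool(s) and set(s) <= _ALPHABET


def require_dna(s: str, what: str = "sequence") -> None:
    if not s:
        raise ValueError(f"{what} is empty")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)!r}")


def revcomp(s: str) -> str:
    """Reverse complement of an ACGT string."""
    return s.translate(_COMPLEMENT)[::-1]


def codons(s: str):
    """Iterate frame-0 codons; a trailing partial codon is not yielded."""
    for i in range(0, len(s) - 2, 3):
        yield s[i : i + 3]
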