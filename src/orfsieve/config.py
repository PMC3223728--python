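"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, replace

import yaml

from .fragmentation import LengthDistribution
from .selection import LEADERS, SelectionParams
from .synth import ErrorModel, FoldingQualityModel, GenomeSpec

__all__ = ["RunConfig", "load_config", "config_hash"]

#: The ampicillin series used on the plates, in ug/mL (0 = chloramphenicol only).
DEFAULT_CONCENTRATIONS = (0.0, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    n_clones: int = 20_000
    length: LengthDistribution = field(default_factory=LengthDistribution)
    selection: SelectionParams = field(default_factory=SelectionParams)
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    target_survival: float = 0.01
    errors: ErrorModel = field(default_factory=ErrorModel)
    folding: FoldingQualityModel = field(default_factory=FoldingQualityModel)
    leaders: tuple[str, ...] = LEADERS
    min_overlap_codons: int = 1
    min_read_length: int = 20
    window_size: int = 40_000

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if list(self.concentrations) != sorted(self.concentrations):
            raise ValueError("concentrations must be sorted ascending")
        if not (0 < self.target_survival <= 1):
            raise ValueError("target_survival must lie in (0, 1]")
        unknown = set(self.leaders) - set(LEADERS)
        if unknown:
            raise ValueError(f"unknown leaders: {sorted(unknown)}")
        if (self.genome_fasta is None) != (self.genes_gff3 is None):
            raise ValueError("genome_fasta and genes_gff3 must be given together")


def _build(cls, block: dict, **extra):
    return cls(**{**block, **extra})


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load a RunConfig from YAML; missing keys take their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    genome_block = dict(raw.get("genome", {}))
    genome_fasta = genome_block.pop("fasta", None)
    genes_gff3 = genome_block.pop("gff3", None)
    if "gene_length_range" in genome_block:
        genome_block["gene_length_range"] = tuple(genome_block["gene_length_range"])
    frag = dict(raw.get("fragmentation", {}))
    n_clones = int(frag.pop("n_clones", RunConfig.n_clones))
    length = _build(LengthDistribution, frag.pop("length", {}))
    sel = dict(raw.get("selection", {}))
    concentrations = tuple(float(c) for c in sel.pop("concentrations",
                                                    DEFAULT_CONCENTRATIONS))
    target = float(sel.pop("target_survival", RunConfig.target_survival))
    fold = dict(raw.get("folding", {}))
    for k in ("genic_shape", "nongenic_shape"):
        if k in fold:
            fold[k] = tuple(fold[k])
    cls_block = dict(raw.get("classification", {}))
    met_block = dict(raw.get("metrics", {}))
    return RunConfig(
        seed=seed,
        genome_fasta=genome_fasta,
        genes_gff3=genes_gff3,
        genome=_build(GenomeSpec, genome_block, seed=seed),
        n_clones=n_clones,
        length=length,
        selection=_build(SelectionParams, sel),
        concentrations=concentrations,
        target_survival=target,
        errors=_build(ErrorModel, dict(raw.get("errors", {}))),
        folding=_build(FoldingQualityModel, fold),
        leaders=tuple(raw.get("leaders", LEADERS)),
        min_overlap_codons=int(cls_block.get("min_overlap_codons", 1)),
        min_read_length=int(cls_block.get("min_read_length", 20)),
        window_size=int(met_block.get("window_size", 40_000)),
    )


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, for the run manifest."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
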