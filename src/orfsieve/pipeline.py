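"""End-to-end orchestration: synth -> fragment -> select -> sequence -> classify -> metrics.

One seed drives every stochastic stage through spawned generator streams,
so re-running an identical configuration reproduces identical artifacts
byte for byte.  The sequencing point is chosen from the ampicillin sweep as
the lowest concentration whose survival rate falls at or below the target
(default 1%) — the "filter to ~1% survival" rule — or the most stringent
concentration if none reaches it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import io as osio
from .classification import (ClassifiedRead, MappedRead, ReadClass, classification_report,
                             classify_read, classify_reads)
from .config import RunConfig, config_hash
from .fragmentation import Fragment, draw_fragments, insert_sequence
from .metrics import gene_metrics, genes_identified, venn_overlap, window_histogram
from .selection import Clone, Library, is_fusion_orf, select_library, survival_sweep
from .synth import (Gene, Genome, assign_folding_quality, generate_genome,
                    simulate_sequencing_errors)

__all__ = ["assemble_clones", "build_library", "choose_sequencing_concentration",
           "run_pipeline"]


def _get_inputs(config: RunConfig) -> tuple[Genome, list[Gene]]:
    if config.genome_fasta is not None:
        genome = osio.read_genome(config.genome_fasta)
        genes = osio.read_gff3(config.genes_gff3)
        return genome, genes
    return generate_genome(config.genome)


def assemble_clones(
    genome: Genome,
    genes: list[Gene],
    fragments: list[Fragment],
    leader: str,
    config: RunConfig,
    rng: np.random.Generator,
) -> Library:
    """Turn fragments into one leader's clone library.

    Folding quality is class-conditional: fusion-ORF clones whose cloned
    frame matches an overlapping gene draw from the genic Beta, all other
    clones from the non-genic one (for non-ORF clones the value is inert —
    their MIC ignores folding).
    """
    genes = sorted(genes, key=lambda g: g.start)
    clones = []
    for frag in fragments:
        insert = insert_sequence(frag, genome)
        orf = is_fusion_orf(insert, config.selection.amber_suppression)
        cls = ReadClass.NONGENIC_ORF
        if orf:
            hit = MappedRead("", frag.start, frag.end, frag.cloned_strand)
            cls, _ = classify_read(hit, genes, genome,
                                   config.selection.amber_suppression,
                                   config.min_overlap_codons)
        label = "genic" if cls is ReadClass.GENIC_ORF else "nongenic"
        quality = assign_folding_quality(label, config.folding, rng=rng)
        clones.append(Clone(frag, insert, leader, quality, orf))
    return Library(leader, tuple(clones))


def build_library(
    genome: Genome,
    genes: list[Gene],
    leader: str,
    config: RunConfig,
    rng: np.random.Generator,
) -> Library:
    """Fragment the genome and assemble one leader's clone library."""
    fragments = draw_fragments(genome, config.n_clones, config.length, rng)
    return assemble_clones(genome, genes, fragments, leader, config, rng)


def choose_sequencing_concentration(
    sweep: list[tuple[float, float]], target: float
) -> float:
    """Lowest concentration with survival <= target, else the highest."""
    for amp, rate in sweep:
        if rate <= target:
            return amp
    return sweep[-1][0]


def _classified_frame(rows: list[ClassifiedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in rows],
            "start": [r.start if r.start is not None else -1 for r in rows],
            "end": [r.end if r.end is not None else -1 for r in rows],
            "strand": [r.strand or "." for r in rows],
            "class": [r.read_class.value for r in rows],
            "gene_id": [r.gene_id or "." for r in rows],
            "n_hits": [r.n_hits for r in rows],
        }
    )


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Run every stage and write the artifact directory; returns the summary.

    Artifacts: genome FASTA + GFF3, per-leader fragment BED, survival TSV,
    survivor reads FASTA, per-read classification TSV, pooled per-gene
    metrics TSV, window histogram TSV, Venn JSON, summary JSON and a
    manifest recording the configuration hash and seed.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    genome, genes = _get_inputs(config)
    genes = sorted(genes, key=lambda g: g.start)
    osio.write_fasta([(genome.id, genome.sequence)], os.path.join(outdir, "genome.fasta"))
    osio.write_gff3(genes, genome, os.path.join(outdir, "genes.gff3"))

    streams = np.random.SeedSequence(config.seed).spawn(len(config.leaders))
    survival_rows = []
    summary: dict = {
        "seed": config.seed,
        "genome_length": genome.length,
        "n_genes": len(genes),
        "libraries": {},
    }
    hits_by_library: dict[str, list[tuple[int, int]]] = {}
    genes_by_library: dict[str, set[str]] = {}
    all_hits: list[tuple[int, int]] = []

    for leader, stream in zip(config.leaders, streams):
        rng = np.random.default_rng(stream)
        library = build_library(genome, genes, leader, config, rng)
        osio.write_fragments_bed(
            [c.fragment for c in library.clones],
            os.path.join(outdir, f"fragments_{leader}.bed"),
        )

        sweep = survival_sweep(library, config.concentrations, config.selection, rng)
        survival_rows += [(leader, amp, rate) for amp, rate in sweep]
        seq_amp = choose_sequencing_concentration(sweep, config.target_survival)
        survivors, rate = select_library(library, seq_amp, config.selection, rng)

        reads = [
            (f"{leader}_read_{i + 1}",
             simulate_sequencing_errors(c.insert, config.errors, rng))
            for i, c in enumerate(survivors.clones)
        ]
        osio.write_fasta(reads, os.path.join(outdir, f"reads_{leader}.fasta"))

        classified = classify_reads(reads, genome, genes,
                                    config.selection.amber_suppression,
                                    config.min_overlap_codons,
                                    config.min_read_length)
        _classified_frame(classified).to_csv(
            os.path.join(outdir, f"classified_{leader}.tsv"), sep="\t", index=False
        )
        hits = [(r.start, r.end) for r in classified
                if r.read_class is not ReadClass.UNMAPPED]
        hits_by_library[leader] = hits
        all_hits += hits
        report = classification_report([r.read_class for r in classified])
        summary["libraries"][leader] = {
            "n_clones": len(library),
            "sequencing_concentration": seq_amp,
            "survival_rate_at_sequencing": rate,
            "total_reads": report.n_total,
            "mapped_reads": report.n_mapped,
            "orf_fraction": report.orf_fraction,
            "genic_given_orf": report.genic_given_orf,
            "genic_fraction": report.genic_fraction,
        }

    pd.DataFrame(survival_rows, columns=["leader", "concentration", "survival_rate"]) \
        .to_csv(os.path.join(outdir, "survival.tsv"), sep="\t", index=False)

    ident = genes_identified(hits_by_library, genes)
    genes_by_library = {k: v for k, v in ident.items() if k != "union"}
    for leader in config.leaders:
        summary["libraries"][leader]["genes_identified"] = len(ident[leader])
    summary["genes_identified_union"] = len(ident["union"])
    summary["genes_identified_fraction"] = (
        len(ident["union"]) / len(genes) if genes else math.nan
    )

    rows = [asdict(gene_metrics(all_hits, g)) for g in genes]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "gene_metrics.tsv"),
                              sep="\t", index=False)

    hist = window_histogram(all_hits, genome.length, config.window_size)
    pd.DataFrame({"window": range(len(hist.counts)), "count": hist.counts}) \
        .to_csv(os.path.join(outdir, "window_histogram.tsv"), sep="\t", index=False)

    if len(config.leaders) == 3:
        a, b, c = (genes_by_library[l] for l in config.leaders)
        venn = venn_overlap(a, b, c)
        with open(os.path.join(outdir, "venn.json"), "w") as fh:
            json.dump({"libraries": list(config.leaders), **asdict(venn),
                       "union_total": venn.union_total}, fh, indent=2, sort_keys=True)

    manifest = {"config_hash": config_hash(config), "seed": config.seed}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
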