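"""Reading and writing the pipeline's on-disk formats.

FASTA for genomes, inserts and reads; GFF3 for gene annotation (type
``gene``, ``ID=<gene_id>``; coordinates converted between the package's
0-based half-open intervals and GFF's 1-based inclusive ones); BED for
fragments (0-based half-open, strand column = cloned orientation).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragmentation import Fragment
from .synth import Gene, Genome

__all__ = [
    "write_fasta",
    "read_genome",
    "read_reads",
    "write_gff3",
    "read_gff3",
    "write_fragments_bed",
    "read_fragments_bed",
]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_genome(path: str | os.PathLike) -> Genome:
    """Read the first record of a FASTA file as the genome."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return Genome(rec.id, str(rec.seq).upper())


def read_reads(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_gff3(genes: Sequence[Gene], genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in sorted(genes, key=lambda g: g.start):
            fh.write(
                f"{genome.id}\torfsieve\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    """Read ``gene`` features from GFF3, back to 0-based half-open."""
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    genes = [
        Gene(f.id, f.start - 1, f.end, f.strand)
        for f in db.features_of_type("gene", order_by="start")
    ]
    return sorted(genes, key=lambda g: g.start)


def write_fragments_bed(fragments: Sequence[Fragment], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "chrom": [f.genome_id for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "name": [f"frag_{i + 1}" for i in range(len(fragments))],
            "score": 0,
            "strand": [f.cloned_strand for f in fragments],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | os.PathLike) -> list[Fragment]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        Fragment(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]
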