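"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA parsing is delegated to Biopython; GFF3 parsing to gffutils.  All
writers are deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

from .genome import AnnotatedGenome, GeneModel

FASTA_WIDTH = 60
FASTQ_QUALITY_CHAR = "I"  # Sanger Q40 placeholder


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: dict[str, str], width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- FASTQ

def write_fastq(path: str, reads: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{FASTQ_QUALITY_CHAR * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


# ---------------------------------------------------------------- GFF3

def write_gff3(path: str, genome: AnnotatedGenome, source: str = "syntloss") -> None:
    """Write gene/mRNA/exon/CDS features; 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in genome.sequences:
            fh.write(f"##sequence-region {name} 1 {len(genome.sequences[name])}\n")
        for scaf in genome.sequences:
            for g in genome.genes_on(scaf):
                gid, mid = g.gene_id, f"{g.gene_id}.t1"
                row = [scaf, source, "gene", str(g.start + 1), str(g.end), ".", g.strand, "."]
                fh.write("\t".join(row + [f"ID={gid}"]) + "\n")
                row[2] = "mRNA"
                fh.write("\t".join(row + [f"ID={mid};Parent={gid}"]) + "\n")
                phase = 0
                for i, (es, ee) in enumerate(g.exons, start=1):
                    for ftype, attrs in (
                        ("exon", f"ID={mid}.exon{i};Parent={mid}"),
                        ("CDS", f"ID={mid}.cds{i};Parent={mid}"),
                    ):
                        ph = str(phase) if ftype == "CDS" else "."
                        fh.write(
                            "\t".join(
                                [scaf, source, ftype, str(es + 1), str(ee), ".", g.strand, ph, attrs]
                            )
                            + "\n"
                        )
                    phase = (3 - ((ee - es) - phase) % 3) % 3


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene models (gene + CDS children) from a GFF3 file."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for cds in db.children(feat, featuretype="CDS", order_by="start"):
            exons.append((cds.start - 1, cds.end))
        if not exons:
            for ex in db.children(feat, featuretype="exon", order_by="start"):
                exons.append((ex.start - 1, ex.end))
        genes.append(
            GeneModel(
                gene_id=feat.id,
                scaffold=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or "+",
                exons=exons,
            )
        )
    return genes


def read_genome(
    fasta_path: str,
    gff3_path: str | None = None,
    protein_fasta_path: str | None = None,
    unanchored_prefix: str = "scaffold_un_",
) -> AnnotatedGenome:
    """Assemble an :class:`AnnotatedGenome` from its on-disk parts."""
    seqs = read_fasta(fasta_path)
    genes = read_gff3(gff3_path) if gff3_path else []
    if protein_fasta_path:
        prots = read_fasta(protein_fasta_path)
        for g in genes:
            g.protein = prots.get(g.gene_id)
    return AnnotatedGenome(sequences=seqs, genes=genes, unanchored_prefix=unanchored_prefix)


# ---------------------------------------------------------------- TSV

def write_tsv(path: str, rows: Sequence[Sequence], header: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def read_tsv(path: str) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        return header, list(r)


def read_depth_bed(path: str) -> dict[str, "list[tuple[int, int, float]]"]:
    """Read a BED-like depth track: scaffold, start, end, depth (0-based half-open)."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            scaf, start, end, depth = line.split()[:4]
            track.setdefault(scaf, []).append((int(start), int(end), float(depth)))
    return track
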