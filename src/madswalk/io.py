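"""Reading and writing the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; GFF3 is read with gffutils and written as
plain GFF3 lines (gene > mRNA > exon/CDS, 1-based inclusive coordinates).
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioRecord

from .records import GeneModel, SequenceRecord


def read_fasta(path: str | os.PathLike, alphabet: str = "dna") -> list[SequenceRecord]:
    return [
        SequenceRecord(r.id, str(r.seq).upper(), alphabet)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    bio = [BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[SequenceRecord]:
    return [
        SequenceRecord(r.id, str(r.seq).upper(), "dna")
        for r in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(
    records: Iterable[SequenceRecord], path: str | os.PathLike, quality_char: str = "?"
) -> None:
    # constant placeholder qualities: downstream stages ignore quality strings
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            attrs = f"ID={g.gene_id}"
            if g.reason:
                attrs += f";note={g.reason}"
            fh.write(
                f"{g.scaffold_id}\tmadswalk\tgene\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.scaffold_id}\tmadswalk\tmRNA\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            order = g.exons if g.strand == "+" else g.exons[::-1]
            phases = {}
            consumed = 0
            for s, e in order:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold_id}\tmadswalk\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}.t1\n"
                )
                fh.write(
                    f"{g.scaffold_id}\tmadswalk\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t{phases[(s, e)]}\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Load gene models (gene + CDS intervals) from a GFF3 file."""
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []  # header-only file: a valid empty annotation
    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbfn = tmp.name
    try:
        db = gffutils.create_db(
            str(path), dbfn=dbfn, force=True, keep_order=True, merge_strategy="error"
        )
        genes = []
        for gene in db.features_of_type("gene"):
            exons = []
            for mrna in db.children(gene, featuretype="mRNA"):
                for cds in db.children(mrna, featuretype="CDS"):
                    exons.append((cds.start - 1, cds.end))
            note = gene.attributes.get("note", [None])[0]
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    scaffold_id=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    reason=note,
                )
            )
        return genes
    finally:
        if os.path.exists(dbfn):
            os.unlink(dbfn)
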