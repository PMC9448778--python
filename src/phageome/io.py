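"""FASTA and annotation-table I/O.

FASTA goes through Bio.SeqIO (wrapped at 60 columns on output). Gene
annotations travel as TSV with one row per gene: contig_id, gene_id, start,
end, strand, protein_seq plus the boolean evidence flags and best-hit family
used by the discovery criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLAG_COLUMNS = [
    "viral_hallmark",
    "plasmid_hallmark",
    "bacterial_marker",
    "rRNA",
    "viral_db_hit",
    "plasmid_db_hit",
    "temperate_marker",
]

GENE_COLUMNS = ["contig_id", "gene_id", "start", "end", "strand", "protein_seq"] + FLAG_COLUMNS + ["besthit_family"]


@dataclass
class GeneAnnotation:
    """One predicted gene: 1-based inclusive coordinates plus evidence flags."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    protein_seq: str = ""
    viral_hallmark: bool = False
    plasmid_hallmark: bool = False
    bacterial_marker: bool = False
    rRNA: bool = False
    viral_db_hit: bool = False
    plasmid_db_hit: bool = False
    temperate_marker: bool = False
    besthit_family: Optional[str] = None

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"{self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class ContigRecord:
    """An assembled contig with its gene annotations and contig-level evidence."""

    id: str
    seq: str
    genes: List[GeneAnnotation] = field(default_factory=list)
    kmer_p: Optional[float] = None
    sample_id: str = "sample"

    def __post_init__(self):
        for g in self.genes:
            if g.end > len(self.seq):
                raise ValueError(f"{self.id}: gene {g.gene_id} exceeds contig bounds")

    def __len__(self) -> int:
        return len(self.seq)

    def gene_seq(self, gene: GeneAnnotation) -> str:
        return self.seq[gene.start - 1 : gene.end]


def write_fasta(records, path) -> None:
    """records: iterable of (id, seq) pairs or objects with .id/.seq."""
    seqs = []
    for rec in records:
        rid, seq = (rec.id, rec.seq) if hasattr(rec, "id") else rec
        seqs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path):
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def genes_to_frame(contigs) -> pd.DataFrame:
    rows = []
    for contig in contigs:
        for g in contig.genes:
            rows.append(
                {
                    "contig_id": contig.id,
                    "gene_id": g.gene_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "protein_seq": g.protein_seq,
                    **{flag: int(getattr(g, flag)) for flag in FLAG_COLUMNS},
                    "besthit_family": g.besthit_family if g.besthit_family is not None else "",
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def frame_to_genes(frame: pd.DataFrame) -> dict:
    """TSV/DataFrame -> {contig_id: [GeneAnnotation, ...]}."""
    out: dict = {}
    for row in frame.itertuples(index=False):
        family = getattr(row, "besthit_family", "")
        if family != family or family == "":  # NaN or empty
            family = None
        gene = GeneAnnotation(
            gene_id=row.gene_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            protein_seq=row.protein_seq if isinstance(row.protein_seq, str) else "",
            **{flag: bool(int(getattr(row, flag))) for flag in FLAG_COLUMNS},
            besthit_family=family,
        )
        out.setdefault(row.contig_id, []).append(gene)
    return out


def write_gene_table(contigs, path) -> None:
    genes_to_frame(contigs).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> dict:
    return frame_to_genes(pd.read_csv(path, sep="\t", keep_default_na=False))
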