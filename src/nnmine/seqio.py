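"""Readers and writers for the on-disk formats the pipeline exchanges.

FASTA goes through Bio.SeqIO, GFF3 through gffutils, tabular formats
through pandas, graphs through networkx GraphML.  The TSV gene-table
dialect is a six-column file (gene_id, contig, start, end, strand, family,
optional product) with 1-based inclusive coordinates, the same convention
as GFF3.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd
from Bio import SeqIO

from .records import GeneRecord, GenomeTable, ProteinRecord

if TYPE_CHECKING:  # pragma: no cover
    from .ssn import SimilarityGraph

logger = logging.getLogger("nnmine")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "write_graphml",
    "read_graphml",
    "write_edge_list",
]

GENE_TABLE_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "family", "product"]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA.

    Order is preserved; sequences are uppercased; ids must be unique and
    records non-empty, otherwise a ValueError names the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def _gene_table_from_tsv(path: Path, genome_id: str) -> GenomeTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    if "product" not in df.columns:
        df["product"] = ""
    genes = [
        GeneRecord(
            gene_id=row.gene_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            family=row.family,
            product="" if pd.isna(row.product) else str(row.product),
        )
        for row in df.itertuples()
    ]
    return GenomeTable(genome_id, genes)


def _gene_table_from_gff3(path: Path, genome_id: str, family_attr: str,
                          feature_type: str) -> GenomeTable:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type):
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"{path}: feature {feat.id!r} has unsupported strand {feat.strand!r}"
            )
        family = feat.attributes.get(family_attr, [""])[0]
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                family=family,
                product=product,
            )
        )
    return GenomeTable(genome_id, genes)


def read_gene_table(
    path: str | Path,
    dialect: str = "tsv",
    genome_id: str | None = None,
    family_attr: str = "gene_family",
    feature_type: str = "gene",
) -> GenomeTable:
    """Read a genome's gene table from GFF3 or the TSV dialect.

    Genes come back sorted by (contig, start).  ``family_attr`` names the
    GFF3 attribute key holding the family label.
    """
    p = Path(path)
    gid = genome_id if genome_id is not None else p.stem
    if dialect == "tsv":
        return _gene_table_from_tsv(p, gid)
    if dialect == "gff3":
        return _gene_table_from_gff3(p, gid, family_attr, feature_type)
    raise ValueError(f"unknown gene-table dialect {dialect!r}")


def write_gene_table(gt: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# nnmine gene table; coordinates 1-based inclusive\n")
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in gt.genes:
            fh.write(
                f"{g.gene_id}\t{g.contig}\t{g.start}\t{g.end}\t{g.strand}"
                f"\t{g.family}\t{g.product}\n"
            )


def write_graphml(graph: "SimilarityGraph", path: str | Path) -> None:
    """Write a similarity graph to GraphML; attributes survive round-trip."""
    import networkx as nx

    g = graph.g.copy()
    g.graph["evalue_threshold"] = graph.threshold
    g.graph["scheme"] = graph.scheme_name
    nx.write_graphml(g, str(path), infer_numeric_types=False)


def read_graphml(path: str | Path) -> "SimilarityGraph":
    import networkx as nx

    from .ssn import SimilarityGraph

    g = nx.read_graphml(str(path))
    threshold = float(g.graph.pop("evalue_threshold"))
    scheme = str(g.graph.pop("scheme", "BLOSUM62"))
    return SimilarityGraph(g=g, threshold=threshold, scheme_name=scheme)


def write_edge_list(graph: "SimilarityGraph", path: str | Path) -> None:
    """Plain TSV edge list: query, subject, score, evalue, identity_pct."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tevalue\tidentity_pct\n")
        for u, v, data in sorted(graph.g.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data['score']}\t{data['evalue']:.6g}"
                f"\t{data['identity_pct']:.4f}\n"
            )
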