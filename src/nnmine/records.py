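"""Core domain types shared across the pipeline.

Coordinates are 1-based and inclusive throughout (GFF3 convention).
Neighborhood analysis counts distance in *genes*, not base pairs; bp
coordinates are carried for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "GeneRecord",
    "GenomeTable",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: the node unit of the similarity network.

    The sequence is uppercased on construction; a trailing stop ``*`` is
    stripped; any character outside the 20 amino acids plus ``X`` is
    rejected.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id {self.id!r} is empty or contains whitespace")
        seq = self.sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = sorted(set(seq) - _ALLOWED)
        if bad:
            raise ValueError(
                f"protein {self.id!r} has illegal characters {''.join(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """One gene on a contig, labeled with a family tag.

    Family labels are the unit of homology in neighborhood analysis;
    they are supplied by the input annotation or produced upstream by the
    SSN / fingerprint modules.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: coordinates are 1-based")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class GenomeTable:
    """Ordered gene table for one genome.

    Genes are kept sorted by (contig, start); (contig, gene_id) pairs are
    unique.
    """

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig, g.start))
        seen: set[tuple[str, str]] = set()
        for g in self.genes:
            key = (g.contig, g.gene_id)
            if key in seen:
                raise ValueError(
                    f"genome {self.genome_id!r}: duplicate gene "
                    f"{g.gene_id!r} on contig {g.contig!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def contigs(self) -> list[str]:
        out: list[str] = []
        for g in self.genes:
            if not out or out[-1] != g.contig:
                out.append(g.contig)
        return out

    def genes_on_contig(self, contig: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.contig == contig]

    def families_on_contig(self, contig: str) -> list[str]:
        return [g.family for g in self.genes if g.contig == contig]

    def add(self, gene: GeneRecord) -> None:
        """Insert a gene, restoring sort order and uniqueness checks."""
        self.genes.append(gene)
        self.__post_init__()

    def translated(self, contig: str, offset_bp: int) -> "GenomeTable":
        """Shift all genes on one contig by a constant bp offset (reporting aid)."""
        genes = [
            replace(g, start=g.start + offset_bp, end=g.end + offset_bp)
            if g.contig == contig
            else g
            for g in self.genes
        ]
        return GenomeTable(self.genome_id, genes)
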