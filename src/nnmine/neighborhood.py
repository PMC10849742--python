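"""Genomic-neighborhood analysis: windows around anchor genes, gene-family
co-occurrence, content-based BGC classes, and conserved synteny blocks.

Distance is counted in genes, not base pairs (the natural unit when
reasoning about "consecutive genes" in a cluster); bp coordinates are
carried for reporting.  Homology between genes is family-label equality —
labels arrive with the input annotation or from the SSN / fingerprint
stages upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .records import GeneRecord, GenomeTable

__all__ = [
    "Neighborhood",
    "NeighborhoodProfile",
    "BgcClassAssignment",
    "ConservedBlock",
    "extract_neighborhoods",
    "cooccurrence",
    "profile",
    "classify_bgc_types",
    "conserved_block",
    "neighborhoods_to_frame",
]


@dataclass(frozen=True)
class Neighborhood:
    """An anchor gene and its flanking genes (anchor +/- window on one contig).

    Members are listed 5'->3' relative to the anchor's strand, so
    reverse-strand anchors yield layouts comparable with forward ones.
    """

    genome_id: str
    anchor: GeneRecord
    members: tuple[GeneRecord, ...]

    @property
    def families(self) -> list[str]:
        return [g.family for g in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Binary family-presence vector (plus counts) for one neighborhood."""

    genome_id: str
    anchor_gene_id: str
    universe: tuple[str, ...]  # family labels + trailing "other" bucket
    presence: np.ndarray
    counts: np.ndarray

    @property
    def present_families(self) -> frozenset[str]:
        return frozenset(
            fam for fam, p in zip(self.universe, self.presence) if p
        )


@dataclass
class BgcClassAssignment:
    """Single-linkage classes of neighborhoods by shared gene content."""

    assignment: dict[int, int]  # profile index -> class index
    class_members: list[list[int]] = field(default_factory=list)
    consensus_families: list[frozenset[str]] = field(default_factory=list)
    organisms_per_class: list[int] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_members)

    @property
    def n_organisms(self) -> int:
        return sum(self.organisms_per_class)


def extract_neighborhoods(
    gt: GenomeTable, anchor_family: str, window_genes: int
) -> list[Neighborhood]:
    """One neighborhood per gene of ``anchor_family``: the anchor plus up to
    ``window_genes`` genes on each side of it on the same contig,
    truncated at contig ends.  An absent anchor family yields an empty
    list."""
    if window_genes < 0:
        raise ValueError("window_genes must be >= 0")
    out: list[Neighborhood] = []
    for contig in gt.contigs:
        genes = gt.genes_on_contig(contig)
        for idx, g in enumerate(genes):
            if g.family != anchor_family:
                continue
            lo = max(0, idx - window_genes)
            hi = min(len(genes), idx + window_genes + 1)
            members = tuple(genes[lo:hi])
            if g.strand == "-":
                members = tuple(reversed(members))
            out.append(Neighborhood(genome_id=gt.genome_id, anchor=g, members=members))
    return out


def cooccurrence(
    genomes: Sequence[GenomeTable],
    family_a: str,
    family_b: str,
    window_genes: int,
) -> tuple[int, list[tuple[str, str, str]]]:
    """Count family_a genes with at least one family_b gene within
    ``window_genes`` genes on the same contig.

    Counting is per family_a gene (two nearby b-genes still count once), so
    swapping the arguments may give a different count.  Returns the count
    and the witnessing (genome_id, a_gene_id, nearest b_gene_id) triples in
    deterministic order.
    """
    count = 0
    witnesses: list[tuple[str, str, str]] = []
    for gt in genomes:
        for contig in gt.contigs:
            genes = gt.genes_on_contig(contig)
            b_positions = [i for i, g in enumerate(genes) if g.family == family_b]
            if not b_positions:
                continue
            for idx, g in enumerate(genes):
                if g.family != family_a:
                    continue
                near = [j for j in b_positions if abs(j - idx) <= window_genes and j != idx]
                if near:
                    nearest = min(near, key=lambda j: (abs(j - idx), j))
                    count += 1
                    witnesses.append((gt.genome_id, g.gene_id, genes[nearest].gene_id))
    return count, witnesses


def profile(
    nbhd: Neighborhood, family_universe: Sequence[str]
) -> NeighborhoodProfile:
    """Family presence/count vector over a fixed, ordered family universe.

    Families outside the universe are bucketed into a trailing "other"
    slot so every profile in a run is indexed identically.
    """
    universe = tuple(family_universe) + ("other",)
    index = {fam: i for i, fam in enumerate(family_universe)}
    counts = np.zeros(len(universe), dtype=np.int64)
    for fam in nbhd.families:
        counts[index.get(fam, len(universe) - 1)] += 1
    return NeighborhoodProfile(
        genome_id=nbhd.genome_id,
        anchor_gene_id=nbhd.anchor.gene_id,
        universe=universe,
        presence=(counts > 0).astype(np.int8),
        counts=counts,
    )


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0  # two empty profiles are indistinguishable
    return float(np.logical_and(a, b).sum() / union)


def classify_bgc_types(
    profiles: Sequence[NeighborhoodProfile], jaccard_cut: float = 0.5
) -> BgcClassAssignment:
    """Group neighborhoods into BGC classes by shared gene content.

    Pairwise Jaccard similarity on presence vectors; single-linkage at
    ``jaccard_cut`` (connected components of the >=cut similarity graph).
    Class indices are ordered by decreasing size, ties by smallest member
    index.  The consensus family set of a class holds the families present
    in a majority (>= half) of its members; the organism count is the
    number of distinct source genomes.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if not 0.0 <= jaccard_cut <= 1.0:
        raise ValueError("jaccard_cut must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(range(len(profiles)))
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            if _jaccard(profiles[i].presence, profiles[j].presence) >= jaccard_cut:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    assignment: dict[int, int] = {}
    consensus: list[frozenset[str]] = []
    organisms: list[int] = []
    for ci, comp in enumerate(comps):
        for idx in comp:
            assignment[idx] = ci
        universe = profiles[comp[0]].universe
        stack = np.stack([profiles[idx].presence for idx in comp])
        freq = stack.mean(axis=0)
        consensus.append(
            frozenset(
                fam
                for fam, f in zip(universe, freq)
                if f >= 0.5 and fam != "other"
            )
        )
        organisms.append(len({profiles[idx].genome_id for idx in comp}))
    return BgcClassAssignment(
        assignment=assignment,
        class_members=comps,
        consensus_families=consensus,
        organisms_per_class=organisms,
    )


@dataclass(frozen=True)
class ConservedBlock:
    """Longest run of consecutive genes shared, in order, by two genomes."""

    length: int
    contig_a: str | None = None
    start_index_a: int | None = None  # gene-order index on contig_a
    contig_b: str | None = None
    start_index_b: int | None = None
    reversed_in_b: bool = False
    families: tuple[str, ...] = ()


def _longest_common_run(fa: list[str], fb: list[str]) -> tuple[int, int, int]:
    """Longest common contiguous substring of two label lists.

    Returns (length, start_a, start_b); among maxima the leftmost start in
    ``fa`` wins, then the leftmost in ``fb``.
    """
    la, lb = len(fa), len(fb)
    best = (0, 0, 0)
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        cur = [0] * (lb + 1)
        for j in range(1, lb + 1):
            if fa[i - 1] == fb[j - 1]:
                run = prev[j - 1] + 1
                cur[j] = run
                cand = (run, i - run, j - run)
                if run > best[0] or (
                    run == best[0]
                    and (cand[1], cand[2]) < (best[1], best[2])
                    and run > 0
                ):
                    best = cand
        prev = cur
    return best


def conserved_block(gt_a: GenomeTable, gt_b: GenomeTable) -> ConservedBlock:
    """Longest run of consecutive genes in ``gt_a`` whose family labels
    appear, in order, as consecutive genes in ``gt_b``.

    Both orientations of each ``gt_b`` contig are tested, so a block that
    was inverted wholesale in one genome still counts.  Ties break to the
    leftmost start in ``gt_a``, preferring the forward orientation.
    """
    best = ConservedBlock(length=0)
    for ca in gt_a.contigs:
        fa = gt_a.families_on_contig(ca)
        for cb in gt_b.contigs:
            fb = gt_b.families_on_contig(cb)
            for rev in (False, True):
                labels_b = fb[::-1] if rev else fb
                length, sa, sb = _longest_common_run(fa, labels_b)
                if length == 0:
                    continue
                sb_orig = len(fb) - sb - length if rev else sb
                cand = ConservedBlock(
                    length=length,
                    contig_a=ca,
                    start_index_a=sa,
                    contig_b=cb,
                    start_index_b=sb_orig,
                    reversed_in_b=rev,
                    families=tuple(fa[sa : sa + length]),
                )
                key = (-cand.length, cand.contig_a, cand.start_index_a, cand.reversed_in_b)
                best_key = (
                    -best.length,
                    best.contig_a or "",
                    best.start_index_a or 0,
                    best.reversed_in_b,
                )
                if best.length == 0 or key < best_key:
                    best = cand
    return best


def neighborhoods_to_frame(neighborhoods: Sequence[Neighborhood]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": n.genome_id,
            "anchor_gene_id": n.anchor.gene_id,
            "contig": n.anchor.contig,
            "position": i,
            "gene_id": g.gene_id,
            "family": g.family,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for n in neighborhoods
        for i, g in enumerate(n.members)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "anchor_gene_id", "contig", "position",
            "gene_id", "family", "start", "end", "strand",
        ],
    )
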