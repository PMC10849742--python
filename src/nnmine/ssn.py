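"""Sequence similarity network (SSN) construction and clustering.

An SSN connects protein pairs whose all-vs-all local-alignment e-value
passes a stringent threshold; connected components of the resulting graph
approximate isofunctional groups.  Clustering is deliberately just
connected components (the convention of EFI-EST-style visual analysis) —
no community detection — and every ordering rule is deterministic so that
cluster indices are stable across runs.

Edge filtering is done on the log e-value, so thresholds far below the
double-precision underflow limit (e.g. 1e-110 against near-identical
sequences) behave exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import pandas as pd

from .align import ScoringScheme, align_local, local_score, log_evalue
from .records import ProteinRecord

__all__ = [
    "SimilarityGraph",
    "ClusterAssignment",
    "DeduplicationResult",
    "deduplicate",
    "pairwise_evalues",
    "build_ssn",
    "components",
    "threshold_sweep",
]


@dataclass
class SimilarityGraph:
    """Weighted undirected graph over protein ids.

    Node attributes: ``length`` and ``description``.  Edge attributes:
    ``score``, ``evalue``, ``identity_pct``.  The e-value threshold the
    graph was built with travels with it.
    """

    g: nx.Graph
    threshold: float
    scheme_name: str = "BLOSUM62"

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()


@dataclass
class ClusterAssignment:
    """Deterministic component labelling of a similarity graph.

    Cluster indices start at 0 and are ordered by decreasing size, ties
    broken by the lexicographically smallest member id.
    """

    assignment: dict[str, int]
    sizes: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def is_singleton(self, node_id: str) -> bool:
        return self.sizes[self.assignment[node_id]] == 1

    def members(self, cluster: int) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == cluster)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": nid,
                "cluster": c,
                "cluster_size": self.sizes[c],
                "is_singleton": self.sizes[c] == 1,
            }
            for nid, c in sorted(self.assignment.items(), key=lambda kv: (kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["id", "cluster", "cluster_size", "is_singleton"])


class DeduplicationResult(NamedTuple):
    records: list[ProteinRecord]
    members: dict[str, list[str]]  # surviving id -> all ids with that sequence


def deduplicate(seqs: list[ProteinRecord]) -> DeduplicationResult:
    """Collapse exact-duplicate sequences, keeping the first id seen.

    Input order is preserved for the survivors; the membership map records
    every id that carried each surviving sequence.
    """
    by_seq: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    survivors: list[ProteinRecord] = []
    for rec in seqs:
        keeper = by_seq.get(rec.sequence)
        if keeper is None:
            by_seq[rec.sequence] = rec.id
            members[rec.id] = [rec.id]
            survivors.append(rec)
        else:
            members[keeper].append(rec.id)
    return DeduplicationResult(survivors, members)


def pairwise_evalues(
    seqs: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    max_length_ratio: float | None = None,
) -> pd.DataFrame:
    """All-vs-all Smith–Waterman scores and log e-values.

    Exact (no heuristic prefilter) — intended for desk-scale sets of at
    most a few hundred sequences.  ``max_length_ratio``, when given, skips
    pairs whose length ratio exceeds it (off by default).
    """
    scheme = scheme or ScoringScheme.load()
    enc = [scheme.encode(s.sequence) for s in seqs]
    rows = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            la, lb = len(seqs[i]), len(seqs[j])
            if max_length_ratio is not None:
                ratio = max(la, lb) / min(la, lb)
                if ratio > max_length_ratio:
                    continue
            score = local_score(enc[i], enc[j], scheme)
            rows.append(
                {
                    "id_a": seqs[i].id,
                    "id_b": seqs[j].id,
                    "score": score,
                    "log_evalue": log_evalue(max(score, 0), la, lb, scheme),
                }
            )
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "score", "log_evalue"])
    df["evalue"] = [max(math.exp(v), 5e-324) if v > -745 else 5e-324
                    for v in df["log_evalue"]]
    return df


def build_ssn(
    seqs: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    threshold: float = 1e-110,
    pair_table: pd.DataFrame | None = None,
) -> SimilarityGraph:
    """Build the SSN: one node per sequence, an edge per pair with
    e-value <= ``threshold``.

    ``pair_table`` may carry a precomputed :func:`pairwise_evalues` result
    so threshold variations do not redo the alignments.
    """
    if len(seqs) < 2:
        raise ValueError("an SSN needs at least two sequences")
    if not (threshold > 0):
        raise ValueError("e-value threshold must be positive")
    scheme = scheme or ScoringScheme.load()
    if pair_table is None:
        pair_table = pairwise_evalues(seqs, scheme)
    by_id = {s.id: s for s in seqs}
    g = nx.Graph()
    for s in seqs:
        g.add_node(s.id, length=len(s), description=s.description)
    log_cut = math.log(threshold)
    kept = pair_table[pair_table["log_evalue"] <= log_cut]
    for row in kept.itertuples():
        aln = align_local(by_id[row.id_a], by_id[row.id_b], scheme)
        g.add_edge(
            row.id_a,
            row.id_b,
            score=int(row.score),
            evalue=float(row.evalue),
            identity_pct=float(aln.identity_pct),
        )
    return SimilarityGraph(g=g, threshold=threshold, scheme_name=scheme.name)


def components(graph: SimilarityGraph) -> ClusterAssignment:
    """Connected components with deterministic numbering.

    Components are sorted by decreasing size, then by smallest member id;
    isolated nodes become singleton clusters.
    """
    comps = [sorted(c) for c in nx.connected_components(graph.g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    assignment: dict[str, int] = {}
    sizes: list[int] = []
    for idx, comp in enumerate(comps):
        sizes.append(len(comp))
        for node in comp:
            assignment[node] = idx
    return ClusterAssignment(assignment=assignment, sizes=sizes)


def threshold_sweep(
    seqs: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    thresholds: list[float] | None = None,
    pair_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summarise network structure across ascending e-value thresholds.

    Alignments are computed once; each row reports (threshold, n_edges,
    n_clusters, max_cluster_size).  Edge count is monotone nondecreasing
    in the threshold.
    """
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    scheme = scheme or ScoringScheme.load()
    if pair_table is None:
        pair_table = pairwise_evalues(seqs, scheme)
    ids = [s.id for s in seqs]
    rows = []
    for t in thresholds:
        log_cut = math.log(t)
        kept = pair_table[pair_table["log_evalue"] <= log_cut]
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(zip(kept["id_a"], kept["id_b"]))
        comp_sizes = [len(c) for c in nx.connected_components(g)]
        rows.append(
            {
                "threshold": t,
                "n_edges": int(len(kept)),
                "n_clusters": len(comp_sizes),
                "max_cluster_size": max(comp_sizes) if comp_sizes else 0,
            }
        )
    return pd.DataFrame(rows)
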