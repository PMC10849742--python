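"""Active-site residue-fingerprint classification of enzyme domains.

A fingerprint is a reference protein plus annotated positions: for the
SznF-type N-nitrosating enzymes these are the seven iron-binding residues
of the heme-oxygenase-like diiron (HDO) domain and the three histidines of
the cupin domain.  Each homolog is globally aligned to the reference, the
annotated positions are mapped through the alignment, and a domain is
called active when enough of its expected residues are conserved.  A
homolog that keeps the cupin triad but has lost the HDO iron ligands is
the signature pattern that flags N-nitrosation-only chemistry.

Position mapping uses pairwise global alignment to the reference rather
than a progressive multiple alignment: it is deterministic and sufficient
for site mapping.  A star-MSA (all pairwise alignments stacked on the
reference's coordinates) is available for conservation displays.

The shipped default definition deliberately has no positions filled in:
the reference's annotated residue numbers must come from the primary
literature for the reference protein, not from this package.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import ScoringScheme, align_global
from .records import ProteinRecord

__all__ = [
    "FingerprintSite",
    "FingerprintDefinition",
    "MappedSite",
    "SiteCall",
    "FingerprintResult",
    "ClusterFingerprintSummary",
    "DEFAULT_DOMAIN_CUTOFFS",
    "map_positions",
    "score_fingerprint",
    "classify",
    "evaluate_protein",
    "cluster_summary",
    "star_msa",
    "results_to_frame",
]

# Default active-call cutoffs: the cupin triad must be fully retained
# (3/3 histidines); the HDO domain tolerates partial loss (>= 5 of 7).
DEFAULT_DOMAIN_CUTOFFS: dict[str, float] = {"HDO": 5.0 / 7.0, "cupin": 1.0}

# Optional conservative-substitution groups (off unless requested).
CONSERVATIVE_GROUPS: dict[str, str] = {"D": "DE", "E": "DE", "H": "H"}


@dataclass(frozen=True)
class FingerprintSite:
    ref_position: int  # 1-based index into the reference sequence
    expected: frozenset[str]
    domain: str

    def __post_init__(self) -> None:
        if self.ref_position < 1:
            raise ValueError("site positions are 1-based")
        if not self.expected:
            raise ValueError(f"site {self.ref_position}: empty expected-residue set")
        object.__setattr__(self, "expected", frozenset(self.expected))


@dataclass(frozen=True)
class FingerprintDefinition:
    reference: ProteinRecord
    sites: tuple[FingerprintSite, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.sites:
            raise ValueError("a fingerprint needs at least one site")
        per_domain: dict[str, list[int]] = {}
        for s in self.sites:
            if s.ref_position > len(self.reference):
                raise ValueError(
                    f"site position {s.ref_position} beyond reference length "
                    f"{len(self.reference)}"
                )
            per_domain.setdefault(s.domain, []).append(s.ref_position)
        for dom, positions in per_domain.items():
            if sorted(positions) != positions or len(set(positions)) != len(positions):
                raise ValueError(f"domain {dom!r}: positions must be strictly increasing")

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for s in self.sites:
            if s.domain not in seen:
                seen.append(s.domain)
        return seen

    def domain_sites(self, domain: str) -> list[FingerprintSite]:
        return [s for s in self.sites if s.domain == domain]

    @classmethod
    def from_reference(
        cls,
        reference: ProteinRecord,
        positions: Mapping[str, Sequence[int]],
        conservative: bool = False,
    ) -> "FingerprintDefinition":
        """Build a definition whose expected set at each site is the
        reference residue (optionally widened to its conservative group)."""
        sites = []
        for domain, pos_list in positions.items():
            for p in pos_list:
                ref_res = reference.sequence[p - 1]
                expected = CONSERVATIVE_GROUPS.get(ref_res, ref_res) if conservative else ref_res
                sites.append(FingerprintSite(p, frozenset(expected), domain))
        return cls(reference=reference, sites=tuple(sites))

    def to_json(self, path: str | Path, reference_fasta: str) -> None:
        doc = {
            "reference_fasta": reference_fasta,
            "reference_id": self.reference.id,
            "sites": [
                {
                    "ref_position": s.ref_position,
                    "expected": sorted(s.expected),
                    "domain": s.domain,
                }
                for s in self.sites
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FingerprintDefinition":
        from .seqio import read_fasta

        doc = json.loads(Path(path).read_text())
        fasta = Path(path).parent / doc["reference_fasta"]
        refs = {r.id: r for r in read_fasta(fasta)}
        reference = refs[doc["reference_id"]]
        sites = tuple(
            FingerprintSite(
                ref_position=s["ref_position"],
                expected=frozenset(s["expected"]),
                domain=s["domain"],
            )
            for s in doc["sites"]
        )
        return cls(reference=reference, sites=sites)


@dataclass(frozen=True)
class MappedSite:
    ref_position: int
    query_position: int | None  # None when the site aligns to a gap
    observed: str | None
    domain: str


@dataclass(frozen=True)
class SiteCall:
    ref_position: int
    observed: str | None
    match: bool
    domain: str


@dataclass(frozen=True)
class FingerprintResult:
    protein_id: str
    site_calls: tuple[SiteCall, ...]
    match_fraction: dict[str, float]
    status: dict[str, str] | None = None  # "active" / "inactive" after classify


def map_positions(
    query: ProteinRecord,
    fp: FingerprintDefinition,
    scheme: ScoringScheme | None = None,
) -> list[MappedSite]:
    """Map each annotated reference position into the query through the
    global-alignment traceback.

    A reference site aligned against a gap maps to (None, None).  Query
    positions are 1-based.
    """
    aln = align_global(fp.reference, query, scheme)
    ref_to_query: dict[int, tuple[int | None, str | None]] = {}
    ri = qi = 0
    for rc, qc in zip(aln.aligned_query, aln.aligned_subject):
        if rc != "-":
            ri += 1
        if qc != "-":
            qi += 1
        if rc != "-":
            ref_to_query[ri] = (qi, qc) if qc != "-" else (None, None)
    return [
        MappedSite(
            ref_position=s.ref_position,
            query_position=ref_to_query[s.ref_position][0],
            observed=ref_to_query[s.ref_position][1],
            domain=s.domain,
        )
        for s in fp.sites
    ]


def score_fingerprint(
    mapped: list[MappedSite], fp: FingerprintDefinition, protein_id: str
) -> FingerprintResult:
    """Per-site match calls and per-domain match fractions.

    A gap at a site counts as a mismatch: a missing ligand cannot bind
    metal.
    """
    expected = {(s.domain, s.ref_position): s.expected for s in fp.sites}
    calls = tuple(
        SiteCall(
            ref_position=m.ref_position,
            observed=m.observed,
            match=m.observed is not None
            and m.observed in expected[(m.domain, m.ref_position)],
            domain=m.domain,
        )
        for m in mapped
    )
    fractions: dict[str, float] = {}
    for dom in fp.domains:
        dom_calls = [c for c in calls if c.domain == dom]
        fractions[dom] = sum(c.match for c in dom_calls) / len(dom_calls)
    return FingerprintResult(
        protein_id=protein_id, site_calls=calls, match_fraction=fractions
    )


def classify(
    result: FingerprintResult,
    match_min: float | Mapping[str, float] | None = None,
) -> FingerprintResult:
    """Call each domain active or inactive.

    A domain is active iff its match fraction is >= the cutoff (inclusive
    at the boundary).  ``match_min`` may be a single fraction or a
    per-domain mapping; unspecified domains fall back to
    :data:`DEFAULT_DOMAIN_CUTOFFS`, then to 1.0.
    """
    if match_min is None:
        cutoffs: Mapping[str, float] = DEFAULT_DOMAIN_CUTOFFS
    elif isinstance(match_min, Mapping):
        cutoffs = {**DEFAULT_DOMAIN_CUTOFFS, **match_min}
    else:
        if not 0.0 <= match_min <= 1.0:
            raise ValueError("match_min must lie in [0, 1]")
        cutoffs = {dom: match_min for dom in result.match_fraction}
    status = {}
    for dom, frac in result.match_fraction.items():
        cut = cutoffs.get(dom, DEFAULT_DOMAIN_CUTOFFS.get(dom, 1.0))
        if not 0.0 <= cut <= 1.0:
            raise ValueError(f"cutoff for domain {dom!r} must lie in [0, 1]")
        status[dom] = "active" if frac >= cut else "inactive"
    return replace(result, status=status)


def evaluate_protein(
    query: ProteinRecord,
    fp: FingerprintDefinition,
    scheme: ScoringScheme | None = None,
    match_min: float | Mapping[str, float] | None = None,
) -> FingerprintResult:
    """Map, score and classify one homolog in a single call."""
    mapped = map_positions(query, fp, scheme)
    return classify(score_fingerprint(mapped, fp, query.id), match_min)


@dataclass(frozen=True)
class ClusterFingerprintSummary:
    n_members: int
    mean_match_fraction: dict[str, float]
    status_counts: dict[str, Counter]  # domain -> Counter({"active": .., "inactive": ..})
    site_frequencies: dict[tuple[str, int], float]  # (domain, ref_position) -> match freq


def cluster_summary(results: Sequence[FingerprintResult]) -> ClusterFingerprintSummary:
    """Aggregate fingerprint results over one SSN cluster."""
    if not results:
        raise ValueError("cannot summarise an empty cluster")
    domains = list(results[0].match_fraction)
    mean_fraction = {
        dom: sum(r.match_fraction[dom] for r in results) / len(results)
        for dom in domains
    }
    status_counts: dict[str, Counter] = {dom: Counter() for dom in domains}
    for r in results:
        if r.status is None:
            raise ValueError("results must be classified before summarising")
        for dom in domains:
            status_counts[dom][r.status[dom]] += 1
    site_freq: dict[tuple[str, int], float] = {}
    for call in results[0].site_calls:
        key = (call.domain, call.ref_position)
        matched = sum(
            1
            for r in results
            for c in r.site_calls
            if c.domain == call.domain and c.ref_position == call.ref_position and c.match
        )
        site_freq[key] = matched / len(results)
    return ClusterFingerprintSummary(
        n_members=len(results),
        mean_match_fraction=mean_fraction,
        status_counts=status_counts,
        site_frequencies=site_freq,
    )


def star_msa(
    queries: Sequence[ProteinRecord],
    fp: FingerprintDefinition,
    scheme: ScoringScheme | None = None,
) -> dict[str, str]:
    """Stack pairwise alignments on reference coordinates (star alignment).

    Query residues inserted relative to the reference are dropped, so every
    output row has the reference's length — adequate for site-conservation
    displays, not a substitute for a true progressive MSA.
    """
    ref = fp.reference
    out: dict[str, str] = {ref.id: ref.sequence}
    for q in queries:
        aln = align_global(ref, q, scheme)
        row = [
            qc
            for rc, qc in zip(aln.aligned_query, aln.aligned_subject)
            if rc != "-"
        ]
        out[q.id] = "".join(row)
    return out


def results_to_frame(results: Sequence[FingerprintResult]) -> pd.DataFrame:
    """Long-form results table: one row per (protein, domain)."""
    rows = []
    for r in results:
        for dom, frac in r.match_fraction.items():
            calls = ";".join(
                f"{c.ref_position}:{c.observed or '-'}:{'1' if c.match else '0'}"
                for c in r.site_calls
                if c.domain == dom
            )
            rows.append(
                {
                    "id": r.protein_id,
                    "domain": dom,
                    "match_fraction": frac,
                    "status": (r.status or {}).get(dom, ""),
                    "site_calls": calls,
                }
            )
    return pd.DataFrame(rows, columns=["id", "domain", "match_fraction", "status", "site_calls"])
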