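"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of (specification, seed): identical
inputs give identical outputs, and each returns a machine-readable truth
record alongside the data so downstream checks read planted truth instead
of re-deriving expectations from the pipeline under test.

The generators emulate the statistical structure of a mining campaign —
protein families with controlled within/between-family identity and
controlled conservation at designated metal-binding positions; genomes as
ordered gene tables with planted co-occurring families, neighborhood-class
templates and conserved synteny blocks; isotopologue spectra as a
natural-abundance envelope mixed with a label-shifted copy — not realistic
sequence evolution (no indels, no rate heterogeneity, no operon/GC
structure).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import AMINO_ACIDS, GeneRecord, GenomeTable, ProteinRecord

__all__ = [
    "FamilySpec",
    "ContigPlan",
    "PlantedGene",
    "PlantedRun",
    "GenomePlan",
    "random_reference",
    "gen_protein_family",
    "gen_genomes",
    "gen_isotopologue",
    "make_fingerprint_spec",
    "make_cooccurrence_plans",
    "make_block_plans",
    "make_bgc_class_plans",
    "write_truth",
    "DEFAULT_ENVELOPE",
]

# Natural-abundance isotopologue envelope of a mid-size (~C30) organic
# metabolite: M+0 dominant, M+1 from 13C, small M+2/M+3 tail.  Normalised.
DEFAULT_ENVELOPE = np.array([1.0, 0.33, 0.08, 0.015])
DEFAULT_ENVELOPE = DEFAULT_ENVELOPE / DEFAULT_ENVELOPE.sum()


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# protein families

def random_reference(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform reference sequence over the 20 amino acids."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one protein family derived from a reference sequence.

    ``frozen_sites`` are kept at the reference residue in every member;
    ``randomized_sites`` are redrawn uniformly from the 19 non-reference
    residues; everything else mutates i.i.d. at ``mutation_rate``.
    Positions are 1-based.
    """

    family_id: str
    reference: str
    n_members: int
    frozen_sites: tuple[int, ...] = ()
    randomized_sites: tuple[int, ...] = ()
    mutation_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        frozen, rand = set(self.frozen_sites), set(self.randomized_sites)
        if frozen & rand:
            raise ValueError("frozen and randomized site sets must be disjoint")
        for p in frozen | rand:
            if not 1 <= p <= len(self.reference):
                raise ValueError(f"site {p} outside reference length {len(self.reference)}")
        if self.mutation_rate > 0.5:
            warnings.warn(
                f"family {self.family_id!r}: mutation rate {self.mutation_rate} > 0.5; "
                "members may not cluster together",
                stacklevel=2,
            )


def _mutate(residue: str, rng: np.random.Generator) -> str:
    alternatives = AMINO_ACIDS.replace(residue, "")
    return alternatives[rng.integers(len(alternatives))]


def gen_protein_family(
    spec: FamilySpec, seed: int
) -> tuple[list[ProteinRecord], dict]:
    """Generate family members plus a truth table of every designated
    site's residue per member."""
    rng = np.random.default_rng(seed)
    frozen = set(spec.frozen_sites)
    randomized = set(spec.randomized_sites)
    designated = sorted(frozen | randomized)
    records: list[ProteinRecord] = []
    site_table: dict[str, dict[str, str]] = {}
    for k in range(spec.n_members):
        member_id = f"{spec.family_id}_{k:03d}"
        seq = list(spec.reference)
        for pos0, ref_res in enumerate(spec.reference):
            pos = pos0 + 1
            if pos in frozen:
                continue
            if pos in randomized:
                seq[pos0] = _mutate(ref_res, rng)
            elif rng.random() < spec.mutation_rate:
                seq[pos0] = _mutate(ref_res, rng)
        seq_str = "".join(seq)
        records.append(
            ProteinRecord(id=member_id, sequence=seq_str,
                          description=f"synthetic member of {spec.family_id}")
        )
        site_table[member_id] = {str(p): seq_str[p - 1] for p in designated}
    truth = {
        "family_id": spec.family_id,
        "reference": spec.reference,
        "mutation_rate": spec.mutation_rate,
        "frozen_sites": sorted(frozen),
        "randomized_sites": sorted(randomized),
        "site_residues": site_table,
    }
    return records, truth


def make_fingerprint_spec(
    family_id: str,
    reference: str,
    site_positions: dict[str, Sequence[int]],
    active_domains: Sequence[str],
    n_members: int,
    mutation_rate: float = 0.2,
) -> FamilySpec:
    """FamilySpec for one conservation pattern: sites of active domains are
    frozen, sites of inactive domains are randomized away from the
    reference residue."""
    frozen: list[int] = []
    randomized: list[int] = []
    for domain, positions in site_positions.items():
        (frozen if domain in active_domains else randomized).extend(positions)
    return FamilySpec(
        family_id=family_id,
        reference=reference,
        n_members=n_members,
        frozen_sites=tuple(sorted(frozen)),
        randomized_sites=tuple(sorted(randomized)),
        mutation_rate=mutation_rate,
    )


# ---------------------------------------------------------------------------
# genomes

@dataclass(frozen=True)
class ContigPlan:
    contig_id: str
    n_genes: int


@dataclass(frozen=True)
class PlantedGene:
    contig_id: str
    index: int  # gene-order index on the contig, 0-based
    family: str


@dataclass(frozen=True)
class PlantedRun:
    """A run of consecutive planted families (neighborhood template or
    synteny block)."""

    contig_id: str
    start_index: int
    families: tuple[str, ...]
    reversed: bool = False
    label: str = ""  # e.g. a neighborhood-class label

    @property
    def placed_families(self) -> tuple[str, ...]:
        return tuple(reversed(self.families)) if self.reversed else self.families


@dataclass
class GenomePlan:
    genome_id: str
    contigs: list[ContigPlan]
    genes: list[PlantedGene] = field(default_factory=list)
    runs: list[PlantedRun] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = {c.contig_id: c.n_genes for c in self.contigs}
        taken: dict[tuple[str, int], str] = {}

        def claim(contig: str, idx: int, fam: str) -> None:
            if contig not in sizes:
                raise ValueError(f"plan {self.genome_id}: unknown contig {contig!r}")
            if not 0 <= idx < sizes[contig]:
                raise ValueError(
                    f"plan {self.genome_id}: gene index {idx} overflows contig "
                    f"{contig!r} ({sizes[contig]} genes)"
                )
            if (contig, idx) in taken:
                raise ValueError(
                    f"plan {self.genome_id}: position {contig}:{idx} planted twice"
                )
            taken[(contig, idx)] = fam

        for g in self.genes:
            claim(g.contig_id, g.index, g.family)
        for r in self.runs:
            for off, fam in enumerate(r.placed_families):
                claim(r.contig_id, r.start_index + off, fam)


def gen_genomes(
    plans: Sequence[GenomePlan],
    family_alphabet: Sequence[str],
    seed: int,
) -> tuple[list[GenomeTable], dict]:
    """Materialise genome tables from plans; filler genes draw families
    uniformly from ``family_alphabet`` (which must not contain planted
    family labels if planted counts are to be exact)."""
    rng = np.random.default_rng(seed)
    alphabet = list(family_alphabet)
    if not alphabet:
        raise ValueError("family_alphabet must be non-empty")
    gene_len, spacing = 1000, 1500
    tables: list[GenomeTable] = []
    truth: dict = {"genomes": {}}
    for plan in plans:
        planted: dict[tuple[str, int], str] = {}
        for g in plan.genes:
            planted[(g.contig_id, g.index)] = g.family
        for r in plan.runs:
            for off, fam in enumerate(r.placed_families):
                planted[(r.contig_id, r.start_index + off)] = fam
        genes: list[GeneRecord] = []
        for contig in plan.contigs:
            for i in range(contig.n_genes):
                fam = planted.get((contig.contig_id, i))
                is_planted = fam is not None
                if fam is None:
                    fam = alphabet[rng.integers(len(alphabet))]
                start = 1 + i * spacing
                genes.append(
                    GeneRecord(
                        gene_id=f"{contig.contig_id}_g{i:04d}",
                        contig=contig.contig_id,
                        start=start,
                        end=start + gene_len - 1,
                        strand="+" if rng.random() < 0.5 else "-",
                        family=fam,
                        product="planted" if is_planted else "filler",
                    )
                )
        tables.append(GenomeTable(plan.genome_id, genes))
        truth["genomes"][plan.genome_id] = {
            "planted_genes": [
                {"contig": g.contig_id, "index": g.index, "family": g.family}
                for g in plan.genes
            ],
            "planted_runs": [
                {
                    "contig": r.contig_id,
                    "start_index": r.start_index,
                    "families": list(r.families),
                    "reversed": r.reversed,
                    "label": r.label,
                }
                for r in plan.runs
            ],
        }
    return tables, truth


# --- plan builders for the three planted-genome studies --------------------

def make_cooccurrence_plans(
    n_pairs: int = 107,
    n_lone_a: int = 40,
    n_genomes: int = 250,
    family_a: str = "chmN_like",
    family_b: str = "sznF_like_hdo_inactive",
    contig_genes: int = 25,
    max_offset: int = 5,
    seed: int = 0,
) -> tuple[list[GenomePlan], dict]:
    """Plans planting exactly ``n_pairs`` co-localized a/b pairs plus
    ``n_lone_a`` a-genes with no b anywhere near (each feature on its own
    contig, so the planted count is the exact truth for any window
    >= ``max_offset``)."""
    rng = np.random.default_rng(seed)
    features: list[str] = ["pair"] * n_pairs + ["lone_a"] * n_lone_a
    plans: list[GenomePlan] = []
    fi = 0
    for gi in range(n_genomes):
        remaining, genomes_left = len(features) - fi, n_genomes - gi
        n_here = (remaining + genomes_left - 1) // genomes_left  # ceil spread
        my = features[fi : fi + n_here]
        fi += n_here
        contigs = []
        genes: list[PlantedGene] = []
        for ci, kind in enumerate(my):
            cid = f"g{gi:03d}_c{ci}"
            contigs.append(ContigPlan(cid, contig_genes))
            pos = int(rng.integers(max_offset, contig_genes - max_offset))
            genes.append(PlantedGene(cid, pos, family_a))
            if kind == "pair":
                offset = int(rng.integers(1, max_offset + 1))
                side = 1 if rng.random() < 0.5 else -1
                genes.append(PlantedGene(cid, pos + side * offset, family_b))
        if not my:  # background genome: pure filler
            contigs.append(ContigPlan(f"g{gi:03d}_c0", contig_genes))
        plans.append(GenomePlan(f"genome{gi:03d}", contigs, genes=genes))
    truth = {
        "n_pairs": n_pairs,
        "n_lone_a": n_lone_a,
        "family_a": family_a,
        "family_b": family_b,
        "max_offset": max_offset,
    }
    return plans, truth


def make_block_plans(
    block_len: int = 17,
    flank_genes: int = 30,
    reversed_in_b: bool = True,
    seed: int = 0,
) -> tuple[list[GenomePlan], dict]:
    """Two genomes sharing one conserved run of ``block_len`` gene families,
    embedded in unrelated flanks (disjoint filler alphabets guarantee the
    planted block is the unique common run); genome B may carry it
    inverted."""
    block = tuple(f"blk{i:02d}" for i in range(block_len))
    n = flank_genes + block_len + flank_genes
    plan_a = GenomePlan(
        "genomeA",
        [ContigPlan("A_c0", n)],
        runs=[PlantedRun("A_c0", flank_genes, block)],
    )
    plan_b = GenomePlan(
        "genomeB",
        [ContigPlan("B_c0", n)],
        runs=[PlantedRun("B_c0", flank_genes, block, reversed=reversed_in_b)],
    )
    truth = {
        "block_families": list(block),
        "block_len": block_len,
        "reversed_in_b": reversed_in_b,
        "start_index_a": flank_genes,
        "start_index_b": flank_genes,
    }
    return [plan_a, plan_b], truth


def make_bgc_class_plans(
    class_sizes: Sequence[int] = (40, 30, 17, 10),
    n_specific: int = 8,
    core_families: Sequence[str] = ("nhpG", "nhpH", "nhpI", "nhpJ"),
    anchor_family: str = "nhpG",
    flank_genes: int = 4,
    flips_per_neighborhood: int = 1,
    seed: int = 0,
) -> tuple[list[GenomePlan], dict]:
    """One genome (organism) per neighborhood, drawn from planted BGC-class
    templates that share a core (the N-hydroxypyrrole-forming gene set)
    and differ in ``n_specific`` class-specific families; each neighborhood
    has ``flips_per_neighborhood`` non-anchor families replaced by a unique
    noise label."""
    rng = np.random.default_rng(seed)
    templates = [
        tuple(core_families) + tuple(f"cls{c}_fam{i:02d}" for i in range(n_specific))
        for c in range(len(class_sizes))
    ]
    plans: list[GenomePlan] = []
    labels: list[str] = []
    noise_counter = 0
    org = 0
    for c, size in enumerate(class_sizes):
        for _ in range(size):
            fams = list(templates[c])
            flippable = [i for i, f in enumerate(fams) if f != anchor_family]
            for i in rng.choice(flippable, size=flips_per_neighborhood, replace=False):
                fams[i] = f"noise{noise_counter:04d}"
                noise_counter += 1
            n = flank_genes + len(fams) + flank_genes
            cid = f"org{org:03d}_c0"
            plans.append(
                GenomePlan(
                    f"organism{org:03d}",
                    [ContigPlan(cid, n)],
                    runs=[
                        PlantedRun(cid, flank_genes, tuple(fams),
                                   label=f"class{c}")
                    ],
                )
            )
            labels.append(f"class{c}")
            org += 1
    truth = {
        "class_sizes": list(class_sizes),
        "templates": [list(t) for t in templates],
        "anchor_family": anchor_family,
        "labels": labels,
        "n_organisms": sum(class_sizes),
        "family_universe": sorted({f for t in templates for f in t}),
    }
    return plans, truth


# ---------------------------------------------------------------------------
# isotopologue spectra

def gen_isotopologue(
    natural_envelope: np.ndarray | None = None,
    label_fraction: float = 0.49,
    shift: int = 10,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Simulated isotopologue spectra for a labeling experiment.

    Each sample replicate is ``(1-f) * envelope + f * envelope shifted by
    ``shift`` mass units``, with per-entry multiplicative lognormal noise
    of the given coefficient of variation; each control replicate is the
    noisy envelope alone.  Returns (samples, controls, truth).
    """
    from .enrichment import IsotopologueSpectrum

    if not 0.0 <= label_fraction <= 1.0:
        raise ValueError("label_fraction must lie in [0, 1]")
    if shift < 0:
        raise ValueError("shift must be nonnegative")
    env = np.asarray(
        DEFAULT_ENVELOPE if natural_envelope is None else natural_envelope, dtype=float
    )
    env = env / env.sum()
    rng = np.random.default_rng(seed)
    k = shift + env.size  # spectrum covers M+0 .. M+(shift + envelope width - 1)
    base = np.zeros(k)
    base[: env.size] += (1.0 - label_fraction) * env
    base[shift : shift + env.size] += label_fraction * env
    ctrl_base = np.zeros(k)
    ctrl_base[: env.size] = env
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal

    def noisy(vec: np.ndarray, tag: str, i: int) -> IsotopologueSpectrum:
        factors = rng.lognormal(mean=mu, sigma=sigma, size=k) if cv > 0 else np.ones(k)
        return IsotopologueSpectrum(sample_id=f"{tag}_{i}", intensities=vec * factors)

    samples = [noisy(base, "sample", i) for i in range(n_replicates)]
    controls = [noisy(ctrl_base, "control", i) for i in range(n_replicates)]
    truth = {
        "label_fraction": label_fraction,
        "shift": shift,
        "cv": cv,
        "n_replicates": n_replicates,
        "envelope": env.tolist(),
    }
    return samples, controls, truth
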