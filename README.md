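# nnmine

Genome-mining toolkit for discovering biosynthetic gene clusters (BGCs)
that encode *N*-nitrosating and *N*-hydroxylating enzymes — the kind of
desk analysis that connects an enzyme of known chemistry (such as the
streptozotocin oxygenase SznF) to uncharacterized clusters encoding new
natural products.

`nnmine` is for natural-product genome miners who already have a homolog
set (FASTA) and annotated genomes (GFF3 or a simple gene-table TSV) and
want a reproducible, scriptable version of the standard workflow:

1. **Sequence similarity network (SSN)** — all-vs-all Smith–Waterman
   alignment with affine gaps; an edge connects proteins with
   Karlin–Altschul e-value `E = K·m·n·exp(−λS)` at or below a stringent
   threshold (default `1e-110`); connected components approximate
   isofunctional groups.
2. **Active-site fingerprints** — each homolog is globally aligned to a
   reference enzyme and annotated metal-binding positions are mapped
   through the alignment; a domain is called *active* when enough expected
   residues are conserved (defaults: all 3 cupin histidines, ≥ 5 of the 7
   HDO iron ligands). Homologs that keep the cupin triad but lost the HDO
   ligands are the signature of *N*-nitrosation-only chemistry.
3. **Genomic neighborhoods** — windows of ±*w* genes around anchor genes;
   family co-occurrence counts; BGC classes by single-linkage clustering
   of Jaccard similarity between neighborhood gene-content profiles; and
   longest conserved runs of consecutive genes between two genomes
   (orientation-aware synteny blocks).
4. **Stable-isotope enrichment** — percent enrichment from isotopologue
   intensity vectors, `100·(f_label(sample) − f_label(control))`, with
   mean ± sample SD over replicates.

A synthetic-data module generates every input with planted ground truth
(protein families with controlled conservation, genomes with planted
co-occurrences, neighborhood classes and synteny blocks, spectra with a
known label fraction), so the whole pipeline is testable without any
database access.

## Worked example

```python
import numpy as np
from nnmine import (ScoringScheme, build_ssn, components, evaluate_protein,
                    FingerprintDefinition, ProteinRecord)
from nnmine.synth import (FamilySpec, gen_protein_family, make_fingerprint_spec,
                          random_reference, gen_isotopologue)
from nnmine.enrichment import summarize_enrichment, default_shift_set

rng = np.random.default_rng(0)
scheme = ScoringScheme.load("BLOSUM62")

# two enzyme families, 8 members each
seqs = []
for name in ("sznF_like", "chmM_like"):
    ref = random_reference(300, rng)
    recs, _ = gen_protein_family(
        FamilySpec(name, ref, n_members=8, mutation_rate=0.2), seed=1)
    seqs += recs
graph = build_ssn(seqs, scheme, threshold=1e-80)
clusters = components(graph)
print(f"SSN: {graph.n_nodes} nodes, {graph.n_edges} edges -> "
      f"{clusters.n_clusters} clusters, sizes {clusters.sizes}")

# fingerprint a homolog that conserves only the cupin triad
ref = ProteinRecord("ref", random_reference(300, rng))
sites = {"HDO": [25, 60, 95, 130, 165, 200, 235], "cupin": [255, 270, 285]}
fp = FingerprintDefinition.from_reference(ref, sites)
spec = make_fingerprint_spec("homolog", ref.sequence, sites, ["cupin"], 1, 0.2)
(homolog,), _ = gen_protein_family(spec, seed=2)
result = evaluate_protein(homolog, fp, scheme)
print("fingerprint:", {d: f"{result.match_fraction[d]:.2f}/{result.status[d]}"
                       for d in sites})

# isotope enrichment: 49% planted label at mass shift M+10
samples, controls, _ = gen_isotopologue(label_fraction=0.49, shift=10,
                                        cv=0.05, n_replicates=3, seed=3)
res = summarize_enrichment(samples, controls,
                           default_shift_set(10, len(samples[0])),
                           substrate="15N4,13C6-arginine", label_shift=10)
print(f"enrichment: {res.substrate} = {res.mean:.2f} +/- {res.sd:.2f} %")
```

prints

```
SSN: 16 nodes, 56 edges -> 2 clusters, sizes [8, 8]
fingerprint: {'HDO': '0.00/inactive', 'cupin': '1.00/active'}
enrichment: 15N4,13C6-arginine = 48.57 +/- 1.36 %
```

The two planted families separate into two 8-member SSN clusters; the
synthetic homolog built with randomized HDO sites and frozen cupin sites
is called HDO-inactive / cupin-active; and the 49 %-labeled spectra are
recovered as 48.6 ± 1.4 % enrichment from three noisy replicates.

A command-line interface mirrors the library
(`nnmine ssn | fingerprint | neighbors | cooccur | enrich | simulate`),
e.g.

```sh
nnmine ssn --fasta seqs.faa --evalue 1e-110 --out graph.graphml --clusters clusters.tsv
```

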