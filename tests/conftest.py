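import numpy as np
import pytest

from nnmine.align import ScoringScheme
from nnmine.records import ProteinRecord
from nnmine.synth import FamilySpec, gen_protein_family, random_reference


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.load("BLOSUM62")


@pytest.fixture(scope="session")
def planted_families(scheme):
    """3 planted families x 10 members (length 120, mutation rate 0.2)."""
    rng = np.random.default_rng(20240124)
    seqs, labels = [], {}
    for f in range(3):
        ref = random_reference(120, rng)
        spec = FamilySpec(
            family_id=f"fam{f}", reference=ref, n_members=10, mutation_rate=0.2
        )
        recs, _ = gen_protein_family(spec, seed=500 + f)
        seqs.extend(recs)
        labels.update({r.id: f for r in recs})
    return seqs, labels


@pytest.fixture()
def toy_proteins():
    return [
        ProteinRecord("a", "MKV"),
        ProteinRecord("b", "MKV"),
        ProteinRecord("c", "GHWL"),
    ]
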