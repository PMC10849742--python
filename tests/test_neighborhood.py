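import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nnmine.neighborhood import (
    classify_bgc_types,
    conserved_block,
    cooccurrence,
    extract_neighborhoods,
    profile,
)
from nnmine.records import GeneRecord, GenomeTable
from nnmine.synth import (
    ContigPlan,
    GenomePlan,
    PlantedGene,
    gen_genomes,
    make_bgc_class_plans,
    make_block_plans,
)

from _oracles import bruteforce_conserved_block


def _table(families, genome_id="gnm", contig="c1", strand="+"):
    genes = [
        GeneRecord(f"g{i}", contig, 1 + i * 100, 50 + i * 100, strand, fam)
        for i, fam in enumerate(families)
    ]
    return GenomeTable(genome_id, genes)


class TestExtractNeighborhoods:
    def test_mid_contig_window(self):
        gt = _table(["a", "b", "anchor", "c", "d", "e"])
        nbhds = extract_neighborhoods(gt, "anchor", 2)
        assert len(nbhds) == 1
        assert nbhds[0].families == ["a", "b", "anchor", "c", "d"]

    def test_truncated_at_contig_start(self):
        gt = _table(["anchor", "b", "c", "d"])
        (n,) = extract_neighborhoods(gt, "anchor", 2)
        assert n.families == ["anchor", "b", "c"]

    def test_minus_strand_anchor_reported_5prime_to_3prime(self):
        gt = _table(["a", "b", "anchor", "c", "d"], strand="-")
        (n,) = extract_neighborhoods(gt, "anchor", 1)
        assert n.families == ["c", "anchor", "b"]

    def test_absent_family_gives_empty_list(self):
        assert extract_neighborhoods(_table(["a", "b"]), "nope", 3) == []

    def test_size_bound_and_contiguity_for_all_anchors(self):
        rng = np.random.default_rng(12)
        fams = [f"f{rng.integers(5)}" for _ in range(40)]
        gt = _table(fams)
        for w in (0, 3, 10):
            for n in extract_neighborhoods(gt, "f0", w):
                assert len(n) <= 2 * w + 1
                assert n.anchor in n.members
                starts = sorted(g.start for g in n.members)
                idx = [(s - 1) // 100 for s in starts]
                assert idx == list(range(idx[0], idx[0] + len(idx)))

    def test_planted_anchor_count(self):
        plan = GenomePlan(
            "g0",
            [ContigPlan("c0", 60)],
            genes=[PlantedGene("c0", i * 8 + 3, "anchor") for i in range(7)],
        )
        tables, _ = gen_genomes([plan], ["fill1", "fill2"], seed=5)
        assert len(extract_neighborhoods(tables[0], "anchor", 2)) == 7


class TestCooccurrence:
    def test_adjacent_pair_counts_once(self):
        gt = _table(["a", "b"])
        count, witnesses = cooccurrence([gt], "a", "b", 1)
        assert count == 1
        assert witnesses == [("gnm", "g0", "g1")]

    def test_different_contigs_never_cooccur(self):
        genes = [
            GeneRecord("g1", "c1", 1, 50, "+", "a"),
            GeneRecord("g2", "c2", 1, 50, "+", "b"),
        ]
        count, _ = cooccurrence([GenomeTable("gnm", genes)], "a", "b", 10)
        assert count == 0

    def test_two_nearby_b_genes_count_once_and_asymmetry(self):
        gt = _table(["b", "a", "b"])
        assert cooccurrence([gt], "a", "b", 1)[0] == 1
        assert cooccurrence([gt], "b", "a", 1)[0] == 2

    def test_invariant_under_genome_order_and_translation(self):
        g1 = _table(["a", "x", "b"], genome_id="g1")
        g2 = _table(["b", "a"], genome_id="g2")
        base = cooccurrence([g1, g2], "a", "b", 2)[0]
        assert cooccurrence([g2, g1], "a", "b", 2)[0] == base
        shifted = g1.translated("c1", 10_000)
        assert cooccurrence([shifted, g2], "a", "b", 2)[0] == base

    def test_planted_count_recovered(self):
        from nnmine.synth import make_cooccurrence_plans

        plans, truth = make_cooccurrence_plans(
            n_pairs=9, n_lone_a=4, n_genomes=6, seed=2
        )
        tables, _ = gen_genomes(plans, [f"fill{i}" for i in range(50)], seed=3)
        count, _ = cooccurrence(
            tables, truth["family_a"], truth["family_b"], truth["max_offset"]
        )
        assert count == 9


class TestProfile:
    def test_presence_and_counts_over_universe(self):
        gt = _table(["x", "x", "y"])
        (n,) = extract_neighborhoods(gt, "y", 5)
        p = profile(n, ["x", "y", "z"])
        assert p.universe == ("x", "y", "z", "other")
        assert p.presence.tolist() == [1, 1, 0, 0]
        assert p.counts.tolist() == [2, 1, 0, 0]

    def test_empty_universe_buckets_everything_to_other(self):
        gt = _table(["x", "y"])
        (n,) = extract_neighborhoods(gt, "x", 5)
        p = profile(n, [])
        assert p.universe == ("other",)
        assert p.counts.tolist() == [2]

    def test_planted_class_template_reproduced(self):
        plans, truth = make_bgc_class_plans(class_sizes=(1,), flank_genes=0,
                                            flips_per_neighborhood=0, seed=6)
        tables, _ = gen_genomes(plans, ["fill"], seed=7)
        (n,) = extract_neighborhoods(tables[0], truth["anchor_family"], 15)
        p = profile(n, truth["family_universe"])
        assert p.present_families - {"other"} == set(truth["templates"][0])


class TestClassifyBgcTypes:
    def _profiles(self, family_sets, universe):
        profs = []
        for i, fams in enumerate(family_sets):
            gt = _table(list(fams), genome_id=f"org{i}")
            (n,) = extract_neighborhoods(gt, fams[0], len(fams))
            profs.append(profile(n, universe))
        return profs

    def test_identical_profiles_one_class(self):
        profs = self._profiles([("a", "b", "c")] * 4, ["a", "b", "c"])
        result = classify_bgc_types(profs, 0.5)
        assert result.n_classes == 1
        assert result.organisms_per_class == [4]

    def test_disjoint_profiles_all_separate(self):
        profs = self._profiles([("a", "b"), ("c", "d"), ("e", "f")],
                               ["a", "b", "c", "d", "e", "f"])
        result = classify_bgc_types(profs, 0.1)
        assert result.n_classes == 3

    def test_class_count_monotone_in_cut(self):
        sets = [("a", "b", "c"), ("a", "b", "d"), ("e", "f", "g"), ("h", "i", "j")]
        profs = self._profiles(sets, sorted({f for s in sets for f in s}))
        counts = [classify_bgc_types(profs, c).n_classes for c in (0.0, 0.4, 0.8, 1.0)]
        assert counts[0] == 1
        assert counts[-1] == len(sets)
        assert counts == sorted(counts)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_bgc_types([], 0.5)
        profs = self._profiles([("a", "b")], ["a", "b"])
        with pytest.raises(ValueError):
            classify_bgc_types(profs, 1.5)

    def test_consensus_families_majority(self):
        profs = self._profiles(
            [("a", "b", "c"), ("a", "b", "d")], ["a", "b", "c", "d"]
        )
        result = classify_bgc_types(profs, 0.4)
        assert result.n_classes == 1
        assert result.consensus_families[0] >= {"a", "b"}


class TestConservedBlock:
    def test_identical_contigs_full_length(self):
        a = _table(["u", "v", "w", "x", "y"], genome_id="A")
        b = _table(["u", "v", "w", "x", "y"], genome_id="B")
        assert conserved_block(a, b).length == 5

    def test_no_shared_families_zero(self):
        a = _table(["u", "v"], genome_id="A")
        b = _table(["x", "y"], genome_id="B")
        assert conserved_block(a, b).length == 0

    def test_reversed_block_detected(self):
        a = _table(["f1", "p", "q", "r", "s", "f2"], genome_id="A")
        b = _table(["z1", "s", "r", "q", "p", "z2"], genome_id="B")
        blk = conserved_block(a, b)
        assert blk.length == 4
        assert blk.reversed_in_b
        assert blk.families == ("p", "q", "r", "s")

    def test_planted_17_gene_block_with_inversion(self):
        plans, truth = make_block_plans(block_len=17, flank_genes=12,
                                        reversed_in_b=True, seed=1)
        ta, _ = gen_genomes(plans[:1], [f"fa{i}" for i in range(300)], seed=2)
        tb, _ = gen_genomes(plans[1:], [f"fb{i}" for i in range(300)], seed=3)
        blk = conserved_block(ta[0], tb[0])
        assert blk.length == 17
        assert blk.reversed_in_b
        assert list(blk.families) == truth["block_families"]
        assert blk.start_index_a == truth["start_index_a"]
        assert blk.start_index_b == truth["start_index_b"]

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        fa=st.lists(st.sampled_from("abcd"), min_size=1, max_size=12),
        fb=st.lists(st.sampled_from("abcd"), min_size=1, max_size=12),
    )
    def test_matches_bruteforce_oracle(self, fa, fb):
        a = _table(fa, genome_id="A")
        b = _table(fb, genome_id="B")
        assert conserved_block(a, b).length == bruteforce_conserved_block(fa, fb)
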