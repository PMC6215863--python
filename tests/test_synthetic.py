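import numpy as np
import pytest

from xenocomp.composition import CODONS, codon_profile, count_kmers
from xenocomp.divergence import kl_nats_from_counts
from xenocomp.phylo import GeneTree, nj_tree, poisson_distance, rf_distance
from xenocomp.synthetic import (
    DEFAULT_BASE_TREE_NEWICK,
    FOCAL_CLADE,
    SWAP_ATTACH,
    MarkovModel,
    gc_biased_codon_usage,
    gen_codon_cds,
    gen_genome,
    gen_operon_insert,
    implant,
    lgt_scenario,
    sim_gene_families,
)


class TestMarkovModel:
    def test_conditionals_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovModel(order=0, probs=np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_gc_target_reached(self):
        g = gen_genome(MarkovModel.from_gc(0.6), 100_000, seed=5)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g.sequence)
        assert gc == pytest.approx(0.6, abs=0.01)

    def test_determinism(self):
        a = gen_genome(MarkovModel.from_gc(0.45), 5_000, seed=9)
        b = gen_genome(MarkovModel.from_gc(0.45), 5_000, seed=9)
        assert a.sequence == b.sequence

    @pytest.mark.parametrize("order", [1, 2])
    def test_higher_order_conditional_convergence(self, order):
        rng = np.random.default_rng(order)
        probs = rng.dirichlet([5, 5, 5, 5], size=4**order)
        model = MarkovModel(order=order, probs=probs, label=f"o{order}")
        seq = gen_genome(model, 100_000, seed=11).sequence
        counts = count_kmers(seq, order + 1, revcomp_extend=False).reshape(
            4**order, 4
        )
        emp = counts / counts.sum(axis=1, keepdims=True)
        tv = 0.5 * np.abs(emp - probs).sum(axis=1)
        assert tv.max() <= 0.02


class TestCodonCds:
    def test_concentrated_usage(self):
        usage = np.zeros(64)
        usage[CODONS.index("ATG")] = 1.0
        cds = gen_codon_cds(usage, 5, seed=1)
        assert cds == "ATG" * 5 + "TAA"
        assert len(cds) == 3 * 5 + 3

    def test_large_sample_matches_usage(self):
        usage = gc_biased_codon_usage(0.55)
        cds = gen_codon_cds(usage, 10_000, seed=2)
        prof = codon_profile([cds[:-3]])  # drop terminal stop
        assert np.abs(prof.frequencies - usage).max() <= 0.01

    def test_stop_mass_rejected(self):
        usage = np.zeros(64)
        usage[CODONS.index("TAA")] = 1.0
        with pytest.raises(ValueError, match="stop"):
            gen_codon_cds(usage, 5, seed=0)

    def test_distinct_usages_give_positive_codon_kl(self):
        a = codon_profile([gen_codon_cds(gc_biased_codon_usage(0.4), 2000, seed=3)])
        b = codon_profile([gen_codon_cds(gc_biased_codon_usage(0.6), 2000, seed=4)])
        assert kl_nats_from_counts(a.counts, b.counts) > 0.05


class TestOperonInsert:
    def test_structure_and_order_tag(self):
        donor = MarkovModel.from_gc(0.6)
        seq, locus = gen_operon_insert(donor, seed=0)
        assert locus.order_tag == "CAB"
        assert [l for l, _ in locus.genes] == ["xmoC", "xmoA", "xmoB"]
        assert all((f.end - f.start) % 3 == 0 for _, f in locus.genes)
        assert locus.span == (0, len(seq))

    def test_abc_mode(self):
        seq, locus = gen_operon_insert(MarkovModel.from_gc(0.6), seed=0, order="ABC")
        assert locus.order_tag == "ABC"

    def test_mean_spanning_length(self):
        rng = np.random.default_rng(42)
        lengths = [
            len(gen_operon_insert(MarkovModel.from_gc(0.6), seed=rng)[0])
            for _ in range(300)
        ]
        assert np.mean(lengths) == pytest.approx(2730, rel=0.02)


class TestImplant:
    def _bits(self, seed=0, n=2):
        host = gen_genome(MarkovModel.from_gc(0.4, label="host"), 120_000, seed=seed)
        donor = MarkovModel.from_gc(0.6, label="donor")
        rng = np.random.default_rng(seed + 1)
        inserts = []
        for i in range(n):
            s, loc = gen_operon_insert(donor, seed=rng)
            loc.operon_id = f"f{i}"
            inserts.append((s, loc, "donor"))
        return host, inserts

    def test_length_conservation_and_truth_slicing(self):
        host, inserts = self._bits()
        genome, loci, truth = implant(host, inserts, seed=5)
        assert len(genome.sequence) == len(host.sequence) + sum(
            len(s) for s, _, _ in inserts
        )
        for (s, _, _), rec in zip(inserts, truth.inserts):
            assert genome.sequence[rec["start"] : rec["end"]] == s

    def test_spacing_honored(self):
        host, inserts = self._bits(n=3)
        _, _, truth = implant(host, inserts, seed=6, min_spacing=5000)
        recs = sorted(truth.inserts, key=lambda r: r["start"])
        gaps = [b["start"] - a["end"] for a, b in zip(recs, recs[1:])]
        assert all(g >= 5000 for g in gaps)

    def test_oversized_insert_rejected(self):
        host = gen_genome(MarkovModel.from_gc(0.4), 20_000, seed=0)
        _, ins = self._bits()
        with pytest.raises(ValueError, match="host length / 10"):
            implant(host, ins, seed=0)

    def test_implanted_regions_diverge_more_than_native(self):
        # direct tetra KL of truth slices vs matched-size native slices
        wins = 0
        for seed in range(12):
            sc = lgt_scenario(seed, host_length=100_000, n_foreign=1, n_native=1)
            genome_counts = count_kmers(sc.genome.sequence, 4)
            by_id = {r["operon_id"]: r for r in sc.truth.inserts}
            kls = {}
            for oid, rec in by_id.items():
                region = sc.genome.sequence[rec["start"] : rec["end"]]
                kls[oid] = kl_nats_from_counts(count_kmers(region, 4), genome_counts)
            wins += kls["foreign_1"] > kls["native_1"]
        assert wins >= 11


class TestGeneFamilies:
    def test_no_perturbations_gives_congruent_genes(self):
        alns, truth = sim_gene_families(seq_len=500, seed=42)
        trees = [nj_tree(poisson_distance(a)) for a in alns]
        assert rf_distance(trees[0], trees[1]).rf == 0
        assert rf_distance(trees[0], trees[2]).rf == 0
        assert not any(truth.topology_swap.values())

    def test_swapped_gene_detected_against_both_others(self):
        alns, truth = sim_gene_families(
            swaps={2: (FOCAL_CLADE, SWAP_ATTACH)}, seq_len=500, seed=7
        )
        trees = [nj_tree(poisson_distance(a)) for a in alns]
        assert rf_distance(trees[0], trees[2]).rf == 0
        assert rf_distance(trees[0], trees[1]).rf > 0
        assert rf_distance(trees[2], trees[1]).rf > 0
        assert truth.topology_swap == {1: False, 2: True, 3: False}

    def test_swap_truth_tree_differs_from_base(self):
        _, truth = sim_gene_families(
            swaps={2: (FOCAL_CLADE, SWAP_ATTACH)}, seq_len=10, seed=0
        )
        base = GeneTree.from_newick(DEFAULT_BASE_TREE_NEWICK)
        swapped = GeneTree.from_newick(truth.gene_trees[2])
        assert rf_distance(base, swapped).rf > 0
        assert sorted(swapped.leaf_names) == sorted(base.leaf_names)

    def test_swap_target_inside_clade_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            sim_gene_families(
                swaps={1: (FOCAL_CLADE, frozenset({"V1", "B1"}))}, seq_len=10, seed=0
            )

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sim_gene_families(
                rate_multipliers={1: (FOCAL_CLADE, 0.0)}, seq_len=10, seed=0
            )

    def test_determinism(self):
        a1, _ = sim_gene_families(seq_len=100, seed=3)
        a2, _ = sim_gene_families(seq_len=100, seed=3)
        assert [x.rows for x in a1] == [x.rows for x in a2]

    def test_branch_length_controls_divergence(self):
        # expected p between two tips at distance t is (19/20)(1-exp(-20t/19))
        alns, _ = sim_gene_families(n_genes=1, seq_len=2000, seed=12)
        aln = alns[0]
        a, b = aln.row("V1"), aln.row("V2")  # path length 0.2
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        expected = (19 / 20) * (1 - np.exp(-20 * 0.2 / 19))
        assert p == pytest.approx(expected, abs=0.03)
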