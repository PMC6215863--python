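import math

import dendropy
import numpy as np
import pytest

from xenocomp.phylo import (
    Alignment,
    DistanceMatrix,
    GeneTree,
    concat_alignment,
    nj_tree,
    poisson_distance,
    rate_ratio,
    rf_distance,
    tree_path_distances,
)
from xenocomp.synthetic import random_tree


class TestPoissonDistance:
    def test_identical_sequences(self):
        aln = Alignment(names=["a", "b"], rows=["MKVL", "MKVL"])
        assert poisson_distance(aln).d[0, 1] == 0.0

    def test_correction_formula(self):
        # 1 difference in 10 sites: p=0.1, d = -ln(0.9)
        aln = Alignment(names=["a", "b"], rows=["MKVLAAAAAA", "MKVLAAAAAW"])
        assert poisson_distance(aln).d[0, 1] == pytest.approx(-math.log(0.9))
        assert -math.log(0.9) == pytest.approx(0.10536, abs=1e-5)

    def test_pairwise_gap_deletion(self):
        # 10 columns, 2 gapped, 3 differences among the 8 compared
        a = "MKVLAAAA--"
        b = "MKWLCCAAAA"[:8] + "--"
        aln = Alignment(names=["a", "b"], rows=[a, b])
        d = poisson_distance(aln).d[0, 1]
        assert d == pytest.approx(-math.log(1 - 3 / 8))

    def test_saturated_pair_errors(self):
        aln = Alignment(names=["a", "b"], rows=["AAAA", "WWWW"])
        with pytest.raises(ValueError, match="saturated pair"):
            poisson_distance(aln)

    def test_zero_overlap_errors(self):
        aln = Alignment(names=["a", "b"], rows=["AA--", "--WW"])
        with pytest.raises(ValueError, match="zero-overlap"):
            poisson_distance(aln)

    def test_permutation_equivariance_and_d_geq_p(self, rng):
        base = rng.choice(list("ACDEFGHIKL"), 60)
        rows = []
        for _ in range(4):
            row = base.copy()
            hit = rng.random(60) < 0.25
            row[hit] = rng.choice(list("ACDEFGHIKL"), int(hit.sum()))
            rows.append("".join(row))
        names = ["t1", "t2", "t3", "t4"]
        dm = poisson_distance(Alignment(names=names, rows=rows))
        perm = [2, 0, 3, 1]
        dm2 = poisson_distance(
            Alignment(names=[names[i] for i in perm], rows=[rows[i] for i in perm])
        )
        assert np.allclose(dm.d[np.ix_(perm, perm)], dm2.d)
        # multiple-hit correction never shrinks the raw proportion
        p = 1 - np.exp(-dm.d)
        assert (dm.d >= p - 1e-12).all()


class TestNjTree:
    def test_three_taxa_three_point_solution(self):
        dm = DistanceMatrix(
            names=["a", "b", "c"],
            d=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = nj_tree(dm)
        back = tree_path_distances(tree)
        idx = [back.names.index(x) for x in dm.names]
        assert np.allclose(back.d[np.ix_(idx, idx)], dm.d, atol=1e-12)

    def test_quartet_split(self):
        # AB close, CD close, cross distances large -> split AB|CD
        d = np.array(
            [
                [0.0, 0.2, 1.0, 1.1],
                [0.2, 0.0, 1.1, 1.0],
                [1.0, 1.1, 0.0, 0.2],
                [1.1, 1.0, 0.2, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(names=list("ABCD"), d=d))
        assert frozenset("CD") in tree.splits() or frozenset("AB") in tree.splits()

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_additive_trees(self, seed):
        n = 5 + seed % 4
        true = random_tree([f"t{i}" for i in range(n)], seed)
        est = nj_tree(tree_path_distances(true))
        assert rf_distance(true, est).rf == 0
        # additive matrix reproduced exactly
        dm, dm2 = tree_path_distances(true), tree_path_distances(est)
        idx = [dm2.names.index(x) for x in dm.names]
        assert np.allclose(dm.d, dm2.d[np.ix_(idx, idx)], atol=1e-9)

    def test_matches_dendropy_nj_topology(self):
        true = random_tree([f"t{i}" for i in range(7)], 123)
        dm = tree_path_distances(true)
        mine = nj_tree(dm)
        csv = "," + ",".join(dm.names) + "\n" + "\n".join(
            dm.names[i] + "," + ",".join(str(x) for x in dm.d[i])
            for i in range(len(dm.names))
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        theirs = GeneTree.from_newick(
            pdm.nj_tree().as_string(schema="newick", suppress_rooting=True)
        )
        assert rf_distance(mine, theirs).rf == 0

    def test_too_few_taxa(self):
        dm = DistanceMatrix(names=["a", "b"], d=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(dm)


class TestNewick:
    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_and_dendropy_agreement(self, seed):
        t = random_tree([f"t{i}" for i in range(6)], seed)
        text = t.to_newick()
        back = GeneTree.from_newick(text)
        assert rf_distance(t, back).rf == 0
        dt = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(l.taxon.label for l in dt.leaf_node_iter()) == sorted(
            t.leaf_names
        )
        assert dt.length() == pytest.approx(
            sum(n.length for n in t.postorder() if n is not t.root)
        )


class TestConcatAlignment:
    def _parts(self, cols=400):
        names = ["a", "b", "c"]
        return [
            Alignment(names=names, rows=["M" * cols for _ in names])
            for _ in range(3)
        ]

    def test_full_length_kept(self):
        cat = concat_alignment(self._parts(), min_len=910)
        assert cat.length == 1200 and cat.names == ["a", "b", "c"]

    def test_taxon_missing_from_one_part_excluded(self):
        parts = self._parts()
        parts[1] = Alignment(names=["a", "b"], rows=["M" * 400] * 2)
        cat = concat_alignment(parts, min_len=0)
        assert cat.names == ["a", "b"]

    def test_short_rows_dropped_by_min_len(self):
        parts = self._parts(cols=200)  # 600 total non-gap < 910
        cat_off = concat_alignment(parts, min_len=0)
        assert cat_off.names == ["a", "b", "c"]
        cat_on = concat_alignment(parts, min_len=910)
        assert cat_on.names == []

    def test_empty_intersection_errors(self):
        parts = [
            Alignment(names=["a"], rows=["MM"]),
            Alignment(names=["b"], rows=["MM"]),
        ]
        with pytest.raises(ValueError, match="no taxa shared"):
            concat_alignment(parts)


class TestRfDistance:
    def test_identical_topologies(self):
        t = random_tree(list("abcdef"), 5)
        assert rf_distance(t, t.copy()).rf == 0

    def test_swapped_quartet_is_maximal(self):
        t1 = GeneTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = GeneTree.from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        rep = rf_distance(t1, t2)
        assert rep.rf == 2 and rep.rf_normalized == 1.0

    def test_prunes_to_shared_leaves(self):
        t1 = GeneTree.from_newick("(((a:1,b:1):1,c:1):1,(d:1,e:1):1);")
        t2 = GeneTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        rep = rf_distance(t1, t2)
        assert rep.n_shared == 4

    def test_too_few_shared_leaves(self):
        t1 = GeneTree.from_newick("((a:1,b:1):1,c:1);")
        t2 = GeneTree.from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="shared leaves"):
            rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(8))
    def test_metric_properties_and_dendropy_oracle(self, seed):
        names = list("abcdefg")
        t1, t2, t3 = (random_tree(names, 100 * seed + i) for i in range(3))
        d12 = rf_distance(t1, t2).rf
        d13 = rf_distance(t1, t3).rf
        d23 = rf_distance(t2, t3).rf
        assert d12 == rf_distance(t2, t1).rf  # symmetry
        assert d13 <= d12 + d23  # triangle inequality
        tns = dendropy.TaxonNamespace()
        dd = [
            dendropy.Tree.get(data=t.to_newick(), schema="newick", taxon_namespace=tns)
            for t in (t1, t2)
        ]
        assert d12 == dendropy.calculate.treecompare.symmetric_difference(*dd)


class TestRateRatio:
    def test_ultrametric_tree_ratio_one(self):
        t = GeneTree.from_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,(o1:2,o2:2):1);"
        )
        rep = rate_ratio(t, focal={"a", "b"}, outgroup={"o1", "o2"})
        assert rep.rate_ratio == pytest.approx(1.0)

    def test_scaled_clade_recovers_multiplier(self):
        t = GeneTree.from_newick(
            "(((a:3,b:3):3,(c:1,d:1):1):1,(o1:2,o2:2):1);"
        )
        rep = rate_ratio(t, focal={"a", "b"}, outgroup={"o1", "o2"})
        assert rep.rate_ratio == pytest.approx(3.0)

    def test_focal_cannot_be_all_leaves(self):
        t = GeneTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="background"):
            rate_ratio(t, focal={"a", "b", "c", "d"}, outgroup=set())
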