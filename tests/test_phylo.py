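import dendropy
import numpy as np
import pytest

from cd300evo.align import Alignment
from cd300evo.evaluation import _random_additive_tree
from cd300evo.phylo import (
    DistanceMatrix,
    SaturationError,
    bootstrap,
    nj_tree,
    paralog_sister_fraction,
    protein_distance,
)


class TestProteinDistance:
    def test_identical_rows_are_zero(self):
        msa = Alignment(["a", "b"], ["MKVL", "MKVL"])
        assert protein_distance(msa, "p").values[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        d = protein_distance(Alignment(["a", "b"], [row_a, row_b]), "p")
        assert d.values[0, 1] == pytest.approx(0.10)

    def test_poisson_closed_form(self):
        rng = np.random.default_rng(6)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=200))
        b = "".join(rng.choice(aas, size=200))
        p = protein_distance(Alignment(["a", "b"], [a, b]), "p").values[0, 1]
        poisson = protein_distance(Alignment(["a", "b"], [a, b]), "poisson").values[0, 1]
        assert poisson == pytest.approx(-np.log(1 - p))

    def test_pairwise_deletion_of_gaps(self):
        d = protein_distance(Alignment(["a", "b"], ["MK-L", "MKV-"]), "p")
        assert d.values[0, 1] == 0.0  # only the two ungapped columns count

    def test_saturation_raises_with_pair_names(self):
        msa = Alignment(["left", "right"], ["AAAA", "CCCC"])
        with pytest.raises(SaturationError, match="left"):
            protein_distance(msa, "poisson")


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(d)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        # three-point formulas: la = (dab + dac - dbc) / 2, etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxa_recovers_true_split(self):
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        newick = tree.as_string(schema="newick")
        # a+b vs c+d is the unique internal bipartition
        tree.encode_bipartitions()
        masks = {
            frozenset(
                leaf.taxon.label for leaf in edge.head_node.leaf_iter()
            )
            for edge in tree.preorder_internal_edge_iter()
        }
        assert {"a", "b"} in masks or {"c", "d"} in masks

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_additive_matrices_reconstructed_exactly(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            true_tree, labels, d = _random_additive_tree(rng, n)
            est = nj_tree(DistanceMatrix(labels, d))
            est = dendropy.Tree.get(
                data=est.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=true_tree.taxon_namespace,
                preserve_underscores=True,
            )
            for t in (true_tree, est):
                t.is_rooted = False
                t.update_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(true_tree, est) == 0

    def test_matches_dendropy_nj_topology(self):
        rng = np.random.default_rng(33)
        _, labels, d = _random_additive_tree(rng, 7)
        ours = nj_tree(DistanceMatrix(labels, d))
        ns = dendropy.TaxonNamespace(labels)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_pdm_csv(labels, d), taxon_namespace=ns, delimiter=","
        )
        theirs = pdm.nj_tree()
        ours = dendropy.Tree.get(
            data=ours.as_string(schema="newick"), schema="newick",
            taxon_namespace=ns, preserve_underscores=True,
        )
        for t in (ours, theirs):
            t.is_rooted = False
            t.update_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0

    def test_clock_like_matrix_matches_upgma_topology(self):
        rng = np.random.default_rng(44)
        # ultrametric distances from a balanced clock tree
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        ns = dendropy.TaxonNamespace(labels)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_pdm_csv(labels, d), taxon_namespace=ns, delimiter=","
        )
        upgma = pdm.upgma_tree()
        ours = dendropy.Tree.get(
            data=nj_tree(DistanceMatrix(labels, d)).as_string(schema="newick"),
            schema="newick", taxon_namespace=ns, preserve_underscores=True,
        )
        for t in (ours, upgma):
            t.is_rooted = False
            t.update_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, upgma) == 0


def _pdm_csv(labels, d):
    import io

    lines = ["," + ",".join(labels)]
    for i, lab in enumerate(labels):
        lines.append(lab + "," + ",".join(str(x) for x in d[i]))
    return io.StringIO("\n".join(lines))


def _clade_alignment():
    rows = {
        "s1|A": "AAAAAAAAAAAAAAAAAAAA",
        "s2|A": "AAAAAAAAAAAAAAAAAACC",
        "s3|A": "TTTTTTTTTTTTTTTTTTAA",
        "s4|A": "TTTTTTTTTTTTTTTTTTCC",
    }
    return Alignment(list(rows), list(rows.values()), "protein")


class TestBootstrap:
    def test_deep_split_gets_high_support(self):
        tree = bootstrap(_clade_alignment(), n_reps=100, seed=5, model="p")
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        assert max(supports) >= 95

    def test_supports_deterministic_under_seed(self):
        a = bootstrap(_clade_alignment(), n_reps=20, seed=9, model="p")
        b = bootstrap(_clade_alignment(), n_reps=20, seed=9, model="p")
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_supports_invariant_to_row_order(self):
        aln = _clade_alignment()
        perm = Alignment(list(reversed(aln.labels)), list(reversed(aln.rows)), "protein")
        sup_a = _support_map(bootstrap(aln, n_reps=50, seed=2, model="p"))
        sup_b = _support_map(bootstrap(perm, n_reps=50, seed=2, model="p"))
        assert sup_a == sup_b

    def test_identical_sequences_do_not_crash(self):
        rows = {f"s{i}|A": "AAAAAAAA" for i in range(4)}
        aln = Alignment(list(rows), list(rows.values()), "protein")
        tree = bootstrap(aln, n_reps=10, seed=1, model="p")
        assert len(tree.leaf_nodes()) == 4

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap(_clade_alignment(), n_reps=5)


def _support_map(tree):
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or not node.label:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        bipartition = frozenset({clade, all_taxa - clade})
        out[bipartition] = node.label
    return out


class TestParalogSisterFraction:
    def test_species_paired_tree_is_one(self):
        tree = dendropy.Tree.get(
            data="((s1|A:1,s1|C:1):1,(s2|A:1,s2|C:1):1,(s3|A:1,s3|C:1):1);",
            schema="newick",
        )
        assert paralog_sister_fraction(tree) == 1.0

    def test_gene_clade_tree_is_zero(self):
        tree = dendropy.Tree.get(
            data="((s1|A:1,(s2|A:1,s3|A:1):1):1,(s1|C:1,(s2|C:1,s3|C:1):1):1);",
            schema="newick",
        )
        assert paralog_sister_fraction(tree) == 0.0

    def test_only_two_paralog_species_counted(self):
        tree = dendropy.Tree.get(
            data="((s1|A:1,s1|C:1):1,(s2|A:1,s3|A:1):1);", schema="newick"
        )
        assert paralog_sister_fraction(tree) == 1.0

    def test_no_paired_species_errors(self):
        tree = dendropy.Tree.get(data="(s1|A:1,s2|A:1,s3|A:1);", schema="newick")
        with pytest.raises(ValueError, match="both paralogs"):
            paralog_sister_fraction(tree)

    def test_branch_lengths_do_not_matter(self):
        t1 = dendropy.Tree.get(
            data="((s1|A:1,s1|C:2):3,(s2|A:4,s2|C:5):6,s3|A:9);", schema="newick"
        )
        t2 = dendropy.Tree.get(
            data="((s1|A:9,s1|C:8):7,(s2|A:6,s2|C:5):4,s3|A:1);", schema="newick"
        )
        assert paralog_sister_fraction(t1) == paralog_sister_fraction(t2)
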