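import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from plangpcr.io_formats import SequenceRecord
from plangpcr.phylogeny import (
    DistanceMatrix,
    MultipleAlignment,
    bootstrap_support,
    jc_distance,
    neighbor_joining,
    progressive_align,
    root_with_outgroup,
    tree_path_lengths,
    write_bayesian_run_parameters,
)

AA = list("ACDEFGHIKLNPQRSTVWY")


def random_additive_matrix(n_taxa, seed):
    """Oracle: distances from a random tree are additive by construction."""
    rng = np.random.RandomState(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        taxon_namespace=tns,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_taxa, n_taxa))
    for (i, t1), (j, t2) in itertools.combinations(enumerate(tns), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(t1, t2)
    return DistanceMatrix(taxa, d)


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "ACDEFGHIKL", "protein") for i in range(2)]
        aln = progressive_align(recs)
        assert aln.rows[0][1] == aln.rows[1][1] == "ACDEFGHIKL"

    def test_single_deletion_recovers_needleman_wunsch_optimum(self):
        # oracle: exhaustive NW DP over the two sequences
        from Bio.Align import substitution_matrices

        a, b = "ACDEFG", "ACEFG"
        m = substitution_matrices.load("BLOSUM62")
        gap = -6.0
        dp = np.full((len(a) + 1, len(b) + 1), -np.inf)
        dp[0, :] = gap * np.arange(len(b) + 1)
        dp[:, 0] = gap * np.arange(len(a) + 1)
        for i in range(1, len(a) + 1):
            for j in range(1, len(b) + 1):
                dp[i, j] = max(
                    dp[i - 1, j - 1] + m[a[i - 1], b[j - 1]],
                    dp[i - 1, j] + gap,
                    dp[i, j - 1] + gap,
                )
        aln = progressive_align(
            [SequenceRecord("x", a, "protein"), SequenceRecord("y", b, "protein")]
        )
        ra, rb = aln.rows[0][1], aln.rows[1][1]
        assert ra == "ACDEFG" and rb == "AC-EFG"
        matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
        assert matches == 5
        assert dp[len(a), len(b)] > -np.inf  # oracle table filled

    def test_identical_pair_among_three_stays_identical(self):
        recs = [
            SequenceRecord("a", "ACDEFGHIKLVW", "protein"),
            SequenceRecord("b", "ACDEFGHIKLVW", "protein"),
            SequenceRecord("c", "ACDKFGHIKYVW", "protein"),
        ]
        aln = progressive_align(recs)
        rows = dict(aln.rows)
        assert rows["a"] == rows["b"]

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([SequenceRecord("a", "ACD", "protein")])


class TestJcDistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment([("a", "ACDEF"), ("b", "ACDEF")])
        assert jc_distance(aln).d[0, 1] == 0.0

    def test_known_value_at_p_0_1(self):
        # direct evaluation: -(19/20) ln(1 - 0.1*20/19) = 0.1056645
        rows = [("a", "A" * 10), ("b", "C" + "A" * 9)]
        d = jc_distance(MultipleAlignment(rows)).d[0, 1]
        assert d == pytest.approx(0.1056645, abs=1e-6)

    def test_saturated_pair_capped_and_flagged(self):
        rows = [("a", "ACDEFGHIKLNPQRSTVWYA"), ("b", "CDEFGHIKLNPQRSTVWYAC")]
        dm = jc_distance(MultipleAlignment(rows))
        assert dm.d[0, 1] == 10.0
        assert dm.saturated[0, 1]

    def test_monotone_in_mismatch_fraction(self):
        base = "A" * 50
        prev = -1.0
        for k in range(0, 40, 5):
            rows = [("a", base), ("b", "C" * k + "A" * (50 - k))]
            d = jc_distance(MultipleAlignment(rows)).d[0, 1]
            assert d > prev
            prev = d

    def test_gapped_columns_pairwise_deleted(self):
        rows = [("a", "AC-EF"), ("b", "ACD-F")]
        # shared ungapped columns: 1,2,5 -> all match
        assert jc_distance(MultipleAlignment(rows)).d[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = neighbor_joining(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_four_taxon_recovers_topology_and_lengths(self):
        # oracle: enumerate the 3 unrooted quartet topologies and check fit
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        dm = DistanceMatrix(list("ABCD"), d)
        tree = neighbor_joining(dm)
        pl = tree_path_lengths(tree)
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert pl[frozenset((a, b))] == pytest.approx(d[i, j], abs=1e-9)
        # four-point condition picks AB|CD; verify that split is in the tree
        sums = {
            "AB|CD": d[0, 1] + d[2, 3],
            "AC|BD": d[0, 2] + d[1, 3],
            "AD|BC": d[0, 3] + d[1, 2],
        }
        assert min(sums, key=sums.get) == "AB|CD"

    def test_exact_on_random_additive_matrices(self):
        for seed in range(100):
            dm = random_additive_matrix(5 + seed % 8, seed)
            tree = neighbor_joining(dm)
            pl = tree_path_lengths(tree)
            for (i, a), (j, b) in itertools.combinations(enumerate(dm.ids), 2):
                assert pl[frozenset((a, b))] == pytest.approx(
                    dm.d[i, j], abs=1e-9
                )

    def test_topology_matches_independent_nj_implementation(self):
        # cross-check against scikit-bio's neighbor joining on noisy
        # (non-additive) matrices: same algorithm, same splits
        import io

        from skbio import DistanceMatrix as SkbioDM, TreeNode
        from skbio.tree import nj as skbio_nj

        for seed in range(5):
            rng = np.random.RandomState(seed)
            dm = random_additive_matrix(7, seed)
            noise = rng.uniform(0, 0.05, dm.d.shape)
            noisy = dm.d + (noise + noise.T) * (1 - np.eye(len(dm.ids)))
            ours = neighbor_joining(DistanceMatrix(dm.ids, noisy))
            theirs = skbio_nj(SkbioDM(noisy, dm.ids))

            def splits_dendropy(tree):
                leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
                out = set()
                for n in tree.preorder_node_iter():
                    if n.parent_node is None or n.is_leaf():
                        continue
                    side = frozenset(l.taxon.label for l in n.leaf_iter())
                    if 2 <= len(side) <= len(leaves) - 2:
                        out.add(min(side, leaves - side,
                                    key=lambda s: (len(s), tuple(sorted(s)))))
                return out

            def splits_skbio(tree):
                leaves = frozenset(t.name for t in tree.tips())
                out = set()
                for n in tree.non_tips(include_self=True):
                    side = frozenset(t.name for t in n.tips())
                    if 2 <= len(side) <= len(leaves) - 2:
                        out.add(min(side, leaves - side,
                                    key=lambda s: (len(s), tuple(sorted(s)))))
                return out

            assert splits_dendropy(ours) == splits_skbio(theirs)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            neighbor_joining(dm)


def _clade_alignment(seed=1, n_var=60):
    """Two 3-taxon clades separated by many substitutions."""
    rng = np.random.RandomState(seed)
    base = "".join(rng.choice(AA, 120))
    far = list(base)
    for i in rng.choice(120, n_var, replace=False):
        far[i] = rng.choice(AA)
    far = "".join(far)

    def mut(s, n):
        s = list(s)
        for i in rng.choice(len(s), n, replace=False):
            s[i] = rng.choice(AA)
        return "".join(s)

    rows = [(f"A{i}", mut(base, 4)) for i in range(3)]
    rows += [(f"B{i}", mut(far, 4)) for i in range(3)]
    return MultipleAlignment(rows)


class TestBootstrap:
    def test_separated_clades_get_high_support(self):
        supports = []
        for seed in range(10):
            tree = bootstrap_support(_clade_alignment(seed + 1), 100, seed=seed)
            labels = [
                float(n.label)
                for n in tree.preorder_node_iter()
                if n.label and not n.is_leaf()
            ]
            clade = {
                frozenset(l.taxon.label for l in n.leaf_iter()): n
                for n in tree.preorder_node_iter()
            }
            key = frozenset({"A0", "A1", "A2"})
            key2 = frozenset({"B0", "B1", "B2"})
            node = clade.get(key) or clade.get(key2)
            assert node is not None
            supports.append(float(node.label))
        assert np.median(supports) >= 95

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(_clade_alignment(), 1, seed=0)
        labels = {
            float(n.label)
            for n in tree.preorder_node_iter()
            if n.label and not n.is_leaf()
        }
        assert labels <= {0.0, 100.0}

    def test_deterministic_under_seed(self):
        t1 = bootstrap_support(_clade_alignment(), 25, seed=9)
        t2 = bootstrap_support(_clade_alignment(), 25, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_invariant_to_leaf_order(self):
        aln = _clade_alignment()
        perm = MultipleAlignment(list(reversed(aln.rows)))
        def support_map(tree):
            out = {}
            leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            for n in tree.preorder_node_iter():
                if n.label and not n.is_leaf():
                    side = frozenset(l.taxon.label for l in n.leaf_iter())
                    key = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
                    out[key] = float(n.label)
            return out
        s1 = support_map(bootstrap_support(aln, 50, seed=4))
        s2 = support_map(bootstrap_support(perm, 50, seed=4))
        assert s1 == s2


class TestRooting:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_single_taxon_outgroup_roots_on_pendant_edge(self):
        t = self._tree("((A:1,B:1):1,C:1,O:4);")
        rooted = root_with_outgroup(t, ["O"])
        children = rooted.seed_node.child_nodes()
        sides = [
            {l.taxon.label for l in c.leaf_iter()} for c in children
        ]
        assert {"O"} in sides
        o_edge = [c for c in children if {l.taxon.label for l in c.leaf_iter()} == {"O"}][0]
        assert o_edge.edge.length == pytest.approx(2.0)

    def test_cherry_outgroup_roots_on_internal_edge(self):
        t = self._tree("((A:1,B:1):2,(O1:1,O2:1):2,C:3);")
        rooted = root_with_outgroup(t, ["O1", "O2"])
        sides = [
            {l.taxon.label for l in c.leaf_iter()}
            for c in rooted.seed_node.child_nodes()
        ]
        assert {"O1", "O2"} in sides

    def test_paraphyletic_outgroup_rejected(self):
        t = self._tree("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        with pytest.raises(ValueError, match="not monophyletic"):
            root_with_outgroup(t, ["A", "C"])


def test_bayesian_sidecar_records_settings(tmp_path):
    p = tmp_path / "run.tsv"
    write_bayesian_run_parameters(p)
    text = p.read_text()
    assert "WAG" in text and "200000" in text and "0.25" in text
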