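import math
import random

import dendropy
import numpy as np
import pytest

from sugarporter.phylo import (
    CladeAssignment,
    DistanceMatrix,
    bootstrap_supports,
    collapse_short_edges,
    extract_supported_clades,
    leaf_set,
    nj_tree,
    pairwise_distances,
    propagate_substrate_labels,
    read_tree,
    rf_distance,
    root_on_outgroup,
    tree_splits,
    trim_gap_columns,
    write_tree,
)
from sugarporter.seqio import MSA, ProteinRecord


def random_additive_case(seed: int, n_leaves: int):
    """A random tree plus the exact distance matrix it induces."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(taxa)
    pyr = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        taxon_namespace=tns, rng=pyr,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = pyr.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n_leaves, n_leaves))
    for i, ti in enumerate(tns):
        for j, tj in enumerate(tns):
            D[i, j] = pdm.distance(ti, tj)
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree, DistanceMatrix(labels=[t.label for t in tns], matrix=D)


class TestTrim:
    def test_twenty_percent_boundary(self):
        rows = [f"r{i}" for i in range(10)]
        # column 0: 2/10 gaps (kept), column 1: 3/10 gaps (removed)
        col0 = ["-"] * 2 + ["A"] * 8
        col1 = ["-"] * 3 + ["C"] * 7
        msa = MSA(rows, [a + b for a, b in zip(col0, col1)])
        out = trim_gap_columns(msa, max_gap_fraction=0.20)
        assert out.n_cols == 1
        assert [s[0] for s in out.sequences] == col0

    def test_gap_free_alignment_unchanged(self):
        msa = MSA(["a", "b"], ["ACDEF", "ACDEF"])
        assert trim_gap_columns(msa) == msa

    def test_hand_counted_columns(self):
        # 5 rows x 8 columns; gap counts per column: 0,1,2,0,3,1,5,0
        rows = [
            "AC-DA-GT",
            "ACCD--GT",
            "A-CDA--T",
            "ACCDA-GT",
            "ACC-AC-T",
        ]
        msa = MSA([f"s{i}" for i in range(5)], rows)
        out = trim_gap_columns(msa, max_gap_fraction=0.20)
        # kept: gap fraction <= 0.2 -> columns 0,1,3,4,7 (counts 0,1,0,3? no)
        kept = [k for k in range(8) if [r[k] for r in rows].count("-") / 5 <= 0.2]
        assert out.sequences == ["".join(r[k] for k in kept) for r in rows]

    def test_idempotent(self, family):
        seqs = {r.id: r.sequence for r in family.records}
        ids = sorted(seqs)[:10]
        msa = MSA(ids, [seqs[i] for i in ids])
        once = trim_gap_columns(msa)
        assert trim_gap_columns(once) == once

    def test_fully_trimmed_is_an_error(self):
        msa = MSA(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError, match="fully trimmed"):
            trim_gap_columns(msa, max_gap_fraction=0.20)


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        msa = MSA(["a", "b", "c"], ["ACDE", "ACDE", "ACDE"])
        dm = pairwise_distances(msa)
        assert np.allclose(dm.matrix, 0.0)

    def test_poisson_closed_form_at_half(self):
        msa = MSA(["a", "b"], ["AACC", "AAGG"])  # p = 0.5
        dm = pairwise_distances(msa, correction="poisson")
        assert dm.matrix[0, 1] == pytest.approx(math.log(2.0))

    def test_four_taxon_hand_matrix(self):
        msa = MSA(["a", "b", "c", "d"], ["AAAA", "AAAC", "AA-C", "CCCC"])
        dm = pairwise_distances(msa, correction="p")
        # pairwise deletion: (a,c) and (b,c) share 3 columns
        expected = {
            ("a", "b"): 1 / 4, ("a", "c"): 1 / 3, ("a", "d"): 1.0,
            ("b", "c"): 0.0, ("b", "d"): 3 / 4, ("c", "d"): 2 / 3,
        }
        for (x, y), want in expected.items():
            i, j = dm.labels.index(x), dm.labels.index(y)
            assert dm.matrix[i, j] == pytest.approx(want)

    def test_poisson_dominates_p_distance(self, rng):
        msa = MSA(
            [f"s{i}" for i in range(6)],
            ["".join(rng.choice(list("ACDEFGHIKL"), 50)) for _ in range(6)],
        )
        p = pairwise_distances(msa, correction="p").matrix
        d = pairwise_distances(msa, correction="poisson").matrix
        off = ~np.eye(6, dtype=bool)
        assert np.all(d[off] >= p[off])

    def test_no_shared_columns_names_the_pair(self):
        msa = MSA(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            pairwise_distances(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=["a", "b", "c"], matrix=D))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_recovery(self, seed):
        true_tree, dm = random_additive_case(seed, n_leaves=6)
        assert rf_distance(nj_tree(dm), true_tree) == 0

    def test_matches_scikit_bio_on_random_matrix(self, rng):
        # independent NJ implementation as a cross-check
        skbio = pytest.importorskip("skbio")
        n = 7
        base = rng.uniform(0.1, 1.0, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"t{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(labels=labels, matrix=D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        their_splits = set()
        all_leaves = frozenset(labels)
        ref = min(all_leaves)
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= n - 2:
                their_splits.add(below if ref not in below else all_leaves - below)
        assert tree_splits(mine) == their_splits

    def test_tie_break_is_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=list("abcd"), matrix=D)
        s1 = nj_tree(dm).as_string(schema="newick")
        s2 = nj_tree(dm).as_string(schema="newick")
        assert s1 == s2

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(labels=["a", "b"], matrix=np.zeros((2, 2))))

    def test_branch_lengths_never_negative(self, rng):
        base = rng.uniform(0.0, 1.0, size=(6, 6))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(DistanceMatrix(labels=[f"t{i}" for i in range(6)], matrix=D))
        assert all((e.length or 0) >= 0 for e in tree.preorder_edge_iter())


class TestBootstrap:
    def test_fixed_seed_is_bit_identical(self):
        msa = MSA(list("abcde"), ["A" * 30, "A" * 30, "C" * 30, "C" * 30, "G" * 30])
        t1 = bootstrap_supports(msa, replicates=25, seed=9)
        t2 = bootstrap_supports(msa, replicates=25, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_perfectly_separating_columns_give_full_support(self):
        # one clade-separating signal repeated in every column
        msa = MSA(list("abcde"), ["A" * 50, "A" * 50, "C" * 50, "C" * 50, "G" * 50])
        tree = bootstrap_supports(msa, replicates=50, seed=1)
        supports = [
            int(n.label)
            for n in tree.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert supports and all(s == 100 for s in supports)

    def test_supports_within_bounds(self, rng):
        msa = MSA(
            [f"s{i}" for i in range(8)],
            ["".join(rng.choice(list("ACDEFG"), 40)) for _ in range(8)],
        )
        tree = bootstrap_supports(msa, replicates=20, seed=3)
        for node in tree.preorder_node_iter():
            if node.label is not None and not node.is_leaf():
                assert 0 <= int(node.label) <= 100

    def test_replicates_must_be_positive(self):
        msa = MSA(list("abc"), ["AA", "AC", "CC"])
        with pytest.raises(ValueError, match="replicates"):
            bootstrap_supports(msa, replicates=0, seed=1)


def star_tree_with_supports(supports: dict[frozenset, int]):
    """Build a rooted 3-clade + outgroup tree with chosen clade supports."""
    newick = (
        "((o1:0.05,o2:0.05){og}:0.4,(((a1:0.05,a2:0.05){A}:0.3,"
        "(b1:0.05,b2:0.05){B}:0.3){AB}:0.005,(c1:0.05,c2:0.05){C}:0.3){in}:0.4):0.0;"
    )
    newick = newick.format(**{k: supports.get(k, "") for k in ("og", "A", "B", "C", "AB", "in")})
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


class TestRooting:
    def test_single_leaf_outgroup(self):
        dm = DistanceMatrix(
            labels=["o", "x", "y", "z"],
            matrix=np.array(
                [[0, 1, 1, 1], [1, 0, 0.2, 0.3], [1, 0.2, 0, 0.3], [1, 0.3, 0.3, 0]]
            ),
        )
        rooted = root_on_outgroup(nj_tree(dm), {"o"})
        sides = [leaf_set(c) for c in rooted.seed_node.child_nodes()]
        assert frozenset({"o"}) in sides

    def test_outgroup_cannot_be_everything(self):
        _, dm = random_additive_case(1, 5)
        with pytest.raises(ValueError, match="every leaf"):
            root_on_outgroup(nj_tree(dm), set(dm.labels))

    def test_non_monophyletic_outgroup_reports_split(self):
        dm = DistanceMatrix(
            labels=["o1", "o2", "x", "y", "z"],
            matrix=np.array(
                [
                    [0, 0.2, 1, 1, 1],
                    [0.2, 0, 1, 1, 1],
                    [1, 1, 0, 0.2, 0.3],
                    [1, 1, 0.2, 0, 0.3],
                    [1, 1, 0.3, 0.3, 0],
                ]
            ),
        )
        tree = nj_tree(dm)
        with pytest.raises(ValueError, match="not monophyletic"):
            root_on_outgroup(tree, {"o1", "x"})

    def test_missing_outgroup_id(self):
        _, dm = random_additive_case(2, 5)
        with pytest.raises(ValueError, match="not in tree"):
            root_on_outgroup(nj_tree(dm), {"nope"})

    def test_eight_taxon_two_leaf_outgroup_topology(self):
        # ((o1,o2),((x1,x2),(y1,y2)),(z1,z2)) distances built from the tree
        newick = "((o1:1,o2:1):2,(((x1:0.1,x2:0.1):0.5,(y1:0.1,y2:0.1):0.5):0.3,(z1:0.1,z2:0.1):0.8):2);"
        true = dendropy.Tree.get(data=newick, schema="newick")
        pdm = true.phylogenetic_distance_matrix()
        taxa = list(true.taxon_namespace)
        D = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
        dm = DistanceMatrix(labels=[t.label for t in taxa], matrix=D)
        rooted = root_on_outgroup(nj_tree(dm), {"o1", "o2"})
        sides = [leaf_set(c) for c in rooted.seed_node.child_nodes()]
        assert frozenset({"o1", "o2"}) in sides
        ingroup = next(s for s in sides if "x1" in s)
        assert ingroup == frozenset({"x1", "x2", "y1", "y2", "z1", "z2"})

    def test_supports_preserved_across_rooting(self):
        msa = MSA(
            list("abcdeo"),
            ["A" * 40, "A" * 40, "C" * 40, "C" * 40, "G" * 40, "T" * 40],
        )
        tree = bootstrap_supports(msa, replicates=20, seed=5)
        before = {
            frozenset(leaf_set(n)): n.label
            for n in tree.preorder_node_iter()
            if n.label and not n.is_leaf()
        }
        rooted = root_on_outgroup(tree, {"o"})
        after = {
            frozenset(leaf_set(n)): n.label
            for n in rooted.preorder_node_iter()
            if n.label and not n.is_leaf()
        }
        # every ingroup split keeps its support value
        for split, label in after.items():
            if split in before:
                assert label == before[split]
        assert frozenset({"a", "b"}) in after


class TestCladeExtraction:
    def test_full_support_with_root_split_gives_one_clade(self):
        tree = star_tree_with_supports({"og": 100, "A": 100, "B": 100, "C": 100, "AB": 100, "in": 100})
        asn = extract_supported_clades(
            tree,
            candidates={"a1", "a2", "b1", "b2", "c1", "c2"},
            references=set(),
            include_root_split=True,
            min_branch_length=0.0,
        )
        assert len(asn.clades) == 1
        assert set(asn.clades[0].members) == {"a1", "a2", "b1", "b2", "c1", "c2"}

    def test_zero_support_leaves_everything_unplaced(self):
        tree = star_tree_with_supports({"og": 0, "A": 0, "B": 0, "C": 0, "AB": 0, "in": 0})
        asn = extract_supported_clades(
            tree, candidates={"a1", "a2", "b1", "b2", "c1", "c2"}, references=set()
        )
        assert asn.clades == []
        assert set(asn.unplaced) == {"a1", "a2", "b1", "b2", "c1", "c2"}

    def test_short_backbone_edges_collapse_to_planted_clades(self):
        # AB is a spuriously supported near-zero edge; collapsing it leaves
        # the three real clades
        tree = star_tree_with_supports({"og": 100, "A": 100, "B": 100, "C": 100, "AB": 80, "in": 100})
        asn = extract_supported_clades(
            tree,
            candidates={"a1", "a2", "b1", "b2", "c1", "c2"},
            references=set(),
        )
        got = {frozenset(c.members) for c in asn.clades}
        assert got == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
            frozenset({"c1", "c2"}),
        }

    def test_partition_accounts_for_every_candidate(self):
        tree = star_tree_with_supports({"og": 100, "A": 100, "B": 30, "C": 100, "AB": 10, "in": 100})
        candidates = {"a1", "a2", "b1", "b2", "c1", "c2"}
        asn = extract_supported_clades(tree, candidates=candidates, references=set())
        placed = {m for c in asn.clades for m in c.members if m in candidates}
        assert placed | set(asn.unplaced) == candidates
        assert not placed & set(asn.unplaced)

    def test_strict_threshold(self):
        tree = star_tree_with_supports({"og": 100, "A": 60, "B": 61, "C": 100, "AB": 0, "in": 100})
        inclusive = extract_supported_clades(
            tree, candidates={"a1", "a2", "b1", "b2", "c1", "c2"}, references=set()
        )
        strict = extract_supported_clades(
            tree,
            candidates={"a1", "a2", "b1", "b2", "c1", "c2"},
            references=set(),
            strict=True,
        )
        assert {frozenset(c.members) for c in inclusive.clades} >= {frozenset({"a1", "a2"})}
        assert frozenset({"a1", "a2"}) not in {frozenset(c.members) for c in strict.clades}


class TestLabelPropagation:
    def make_assignment(self):
        from sugarporter.phylo import Clade

        return CladeAssignment(
            clades=[
                Clade("C1", ["r1", "r2", "x1"], 90),
                Clade("C2", ["x2", "x3"], 80),
            ],
            unplaced=[],
        )

    def test_union_of_reference_labels(self):
        refs = [
            ProteinRecord(id="r1", sequence="A", is_reference=True, substrate_labels={"D-glucose"}),
            ProteinRecord(id="r2", sequence="A", is_reference=True, substrate_labels={"D-xylose"}),
        ]
        asn = propagate_substrate_labels(self.make_assignment(), refs)
        assert asn.clades[0].substrate_labels == {"D-glucose", "D-xylose"}

    def test_clade_without_references_is_unknown(self):
        asn = propagate_substrate_labels(self.make_assignment(), [])
        assert asn.clades[1].substrate_labels == {"unknown"}


class TestNewickRoundTrip:
    def test_random_tree_round_trips(self, tmp_path):
        tree, _ = random_additive_case(11, 10)
        for i, node in enumerate(tree.preorder_node_iter()):
            if not node.is_leaf() and node is not tree.seed_node:
                node.label = str(50 + i)
        write_tree(tree, tmp_path / "t.nwk")
        back = read_tree(tmp_path / "t.nwk")
        assert rf_distance(tree, back) == 0
        original = {
            frozenset(leaf_set(n)): (n.label, n.edge.length)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n is not tree.seed_node
        }
        recovered = {
            frozenset(leaf_set(n)): (n.label, n.edge.length)
            for n in back.preorder_node_iter()
            if not n.is_leaf() and n is not back.seed_node
        }
        for split, (label, length) in original.items():
            got_label, got_length = recovered[split]
            assert got_label == label
            assert got_length == pytest.approx(length, abs=1e-6)

    def test_quoted_labels_preserved(self, tmp_path):
        path = tmp_path / "q.nwk"
        path.write_text("('taxon one':1.0,'taxon two':2.0,t3:0.5);\n")
        tree = read_tree(path)
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert labels == {"taxon one", "taxon two", "t3"}

    def test_known_bipartitions_from_fixture(self, tmp_path):
        path = tmp_path / "f.nwk"
        path.write_text("((a:1,b:1):1,(c:1,d:1):1,e:1);\n")
        tree = read_tree(path)
        # splits are keyed by the side not containing the smallest label,
        # so {a,b} is reported as its complement {c,d,e}
        assert tree_splits(tree) == {frozenset({"c", "d"}), frozenset({"c", "d", "e"})}

    def test_malformed_newick_raises(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((a,b,(c;)\n")
        with pytest.raises(ValueError, match="malformed"):
            read_tree(path)


def test_collapse_preserves_long_edges():
    tree = star_tree_with_supports({"og": 100, "A": 100, "B": 100, "C": 100, "AB": 90, "in": 100})
    collapsed = collapse_short_edges(tree, min_length=0.02)
    splits = tree_splits(collapsed)
    assert frozenset({"a1", "a2"}) in splits or frozenset({"a1", "a2"}) in {
        leaf_set(n) for n in collapsed.preorder_node_iter() if not n.is_leaf()
    }
    # the 0.02-length AB edge is gone
    assert all(
        leaf_set(n) != frozenset({"a1", "a2", "b1", "b2"})
        for n in collapsed.preorder_node_iter()
        if not n.is_leaf()
    )
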