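"""Neighbor joining, Newick output, and kinship-threshold families."""

import numpy as np
import pytest

from herdgen import (
    Pedigree,
    PedigreeMember,
    SimConfig,
    assign_sows,
    build_boar_families,
    gene_drop,
    kinship_from_g,
    neighbor_joining,
    newick_string,
    simulate_founders,
    vanraden_g,
    write_newick,
)
from herdgen.relatedness import DistanceMatrix, KinshipMatrix

from tree_utils import edge_map, leaf_distances, random_binary_tree


def dm(values, labels):
    return DistanceMatrix(values=np.asarray(values, dtype=float), labels=labels)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 3.0, 4.0, 5.0
        tree = neighbor_joining(dm([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]], list("ABC")))
        lengths = {child.label: length for child, length in tree.children}
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree: (A:1, B:2) -- internal 5 -- (C:3, D:4)
        D = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0],
            ],
            dtype=float,
        )
        # verify the four-point condition before trusting the fixture
        assert D[0, 1] + D[2, 3] <= D[0, 2] + D[1, 3] == D[0, 3] + D[1, 2]
        tree = neighbor_joining(dm(D, list("ABCD")))
        edges = edge_map(tree, set("ABCD"))
        assert edges[frozenset("A")] == pytest.approx(1.0)
        assert edges[frozenset("B")] == pytest.approx(2.0)
        assert edges[frozenset("C")] == pytest.approx(3.0)
        assert edges[frozenset("D")] == pytest.approx(4.0)
        assert edges[frozenset("AB")] == pytest.approx(5.0)

    def test_random_additive_trees_recovered_exactly(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            truth = random_binary_tree(n, rng)
            dist = leaf_distances(truth)
            got = neighbor_joining(dist)
            want_edges = edge_map(truth, dist.labels)
            got_edges = edge_map(got, dist.labels)
            assert set(got_edges) == set(want_edges)
            for key, length in want_edges.items():
                assert got_edges[key] == pytest.approx(length, abs=1e-9)

    def test_structural_properties_on_random_metric(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 15))
            pts = rng.random((n, 3))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            labels = [f"L{i}" for i in range(n)]
            tree = neighbor_joining(dm(D, labels))
            assert sorted(tree.leaf_labels()) == sorted(labels)
            assert len(tree.children) == 3

    def test_small_or_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm([[0, 1], [1, 0]], ["a", "b"]))
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(dm(bad, list("abc")))


class TestNewick:
    def test_three_leaf_pattern(self):
        tree = neighbor_joining(dm([[0, 2, 3], [2, 0, 3], [3, 3, 0]], list("ABC")))
        s = newick_string(tree)
        assert s.startswith("(") and s.endswith(");")
        assert all(f"{lab}:" in s for lab in "ABC")

    def test_parse_back_with_dendropy(self, tmp_path, rng):
        import dendropy

        truth = random_binary_tree(8, rng)
        path = write_newick(neighbor_joining(leaf_distances(truth)), tmp_path / "t.nwk")
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
            truth.leaf_labels()
        )

    def test_negative_length_clamped(self):
        from herdgen.clustering import TreeNode

        tree = TreeNode(children=[(TreeNode(label="a"), -0.5), (TreeNode(label="b"), 1.0)])
        assert "a:0" in newick_string(tree, clamp_negative=True)
        assert "a:-0.5" in newick_string(tree, clamp_negative=False)

    def test_reserved_characters_quoted(self):
        from herdgen.clustering import TreeNode

        tree = TreeNode(children=[(TreeNode(label="a b"), 1.0), (TreeNode(label="c"), 1.0)])
        assert "'a b'" in newick_string(tree)


def ks_matrix(labels, pairs):
    n = len(labels)
    arr = np.eye(n)
    pos = {l: i for i, l in enumerate(labels)}
    for (a, b), v in pairs.items():
        arr[pos[a], pos[b]] = arr[pos[b], pos[a]] = v
    return KinshipMatrix(arr, labels)


class TestBoarFamilies:
    def test_three_linked_plus_three_isolated(self):
        boars = [f"b{i}" for i in range(6)]
        ks = ks_matrix(
            boars, {("b0", "b1"): 0.3, ("b0", "b2"): 0.2, ("b1", "b2"): 0.25}
        )
        fam = build_boar_families(ks, boars)
        sizes = sorted((len(v) for v in fam.families.values()), reverse=True)
        assert sizes == [3, 1, 1, 1]
        assert fam.families["A"] == ["b0", "b1", "b2"]

    def test_all_distant_gives_singletons(self):
        boars = ["x", "y", "z"]
        fam = build_boar_families(ks_matrix(boars, {}), boars)
        assert fam.n_families == 3

    def test_single_linkage_chain(self):
        boars = ["a", "b", "c"]
        ks = ks_matrix(boars, {("a", "b"): 0.15, ("b", "c"): 0.12, ("a", "c"): 0.01})
        fam = build_boar_families(ks, boars)
        assert fam.families == {"A": ["a", "b", "c"]}

    def test_raising_threshold_refines_partition(self, rng):
        boars = [f"b{i}" for i in range(8)]
        vals = {}
        for i in range(8):
            for j in range(i + 1, 8):
                vals[(boars[i], boars[j])] = float(rng.uniform(0, 0.4))
        ks = ks_matrix(boars, vals)
        low = build_boar_families(ks, boars, threshold=0.1)
        high = build_boar_families(ks, boars, threshold=0.25)
        low_of = {b: f for f, bs in low.families.items() for b in bs}
        for members in high.families.values():
            assert len({low_of[b] for b in members}) == 1

    def test_empty_boar_list_rejected(self):
        with pytest.raises(ValueError):
            build_boar_families(ks_matrix(["a"], {}), [])


class TestAssignSows:
    def test_assigned_to_qualifying_family(self):
        labels = ["b1", "b2", "sow"]
        ks = ks_matrix(labels, {("sow", "b2"): 0.3})
        fam = build_boar_families(ks, ["b1", "b2"])
        fam = assign_sows(ks, fam, ["sow"])
        b2_family = next(f for f, bs in fam.families.items() if "b2" in bs)
        assert fam.sow_assignments["sow"] == b2_family

    def test_below_threshold_unassigned(self):
        labels = ["b1", "b2", "sow"]
        ks = ks_matrix(labels, {("sow", "b1"): 0.09, ("sow", "b2"): 0.05})
        fam = build_boar_families(ks, ["b1", "b2"])
        fam = assign_sows(ks, fam, ["sow"])
        assert fam.sow_assignments["sow"] == "unassigned"

    def test_tie_broken_by_family_label(self):
        labels = ["b1", "b2", "sow"]
        ks = ks_matrix(labels, {("sow", "b1"): 0.2, ("sow", "b2"): 0.2})
        fam = build_boar_families(ks, ["b1", "b2"])
        fam = assign_sows(ks, fam, ["sow"])
        assert fam.sow_assignments["sow"] == "A"


class TestFamilyRecoveryOnGeneDrop:
    def test_planted_paternal_lines_recovered_exactly(self):
        """Four planted sire lines of three half-sib boars each are
        recovered perfectly when within-line kinship is far above the
        threshold and between-line kinship far below."""
        members = []
        for s in range(4):
            members.append(PedigreeMember(f"SIRE{s}", None, None, "male"))
        for s in range(4):
            for k in range(3):
                dam = f"DAM{s}{k}"
                members.append(PedigreeMember(dam, None, None, "female"))
                members.append(PedigreeMember(f"B{s}{k}", f"SIRE{s}", dam, "male"))
        ped = Pedigree(members)
        cfg = SimConfig(n_loci=8000, n_founders=len(ped.founder_ids), seed=17)
        founders = simulate_founders(cfg, sample_ids=ped.founder_ids)
        full = gene_drop(ped, founders, cfg, independent_loci=True)
        boars = [f"B{s}{k}" for s in range(4) for k in range(3)]
        ks = kinship_from_g(vanraden_g(full.select_samples(boars)))
        fam = build_boar_families(ks, boars, threshold=0.1)
        got = {frozenset(v) for v in fam.families.values()}
        want = {frozenset(f"B{s}{k}" for k in range(3)) for s in range(4)}
        assert got == want
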