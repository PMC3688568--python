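"""Distances, neighbor joining, bootstrap and outgroup classification."""

import subprocess

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from tprfam.phylo import (
    AlignedSet,
    DistanceMatrix,
    assign_subgroup,
    bootstrap_support,
    classify_by_outgroup,
    distance_matrix,
    nj_tree,
    pairwise_identity,
)
from tprfam.simulate import SimulationSpec, simulate_family


def random_additive_case(rng, n):
    """A random binary tree with positive branch lengths plus its exact
    path-length matrix (the additivity oracle for NJ)."""
    labels = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(labels)
    # random sequential attachment
    tree = dendropy.Tree(taxon_namespace=tns)
    a, b = dendropy.Node(taxon=tns.get_taxon("t0")), dendropy.Node(
        taxon=tns.get_taxon("t1")
    )
    tree.seed_node.add_child(a)
    tree.seed_node.add_child(b)
    edges = [a.edge, b.edge]
    for i in range(2, n):
        edge = edges[int(rng.integers(len(edges)))]
        old_child = edge.head_node
        parent = edge.tail_node
        mid = dendropy.Node()
        parent.remove_child(old_child)
        parent.add_child(mid)
        mid.add_child(old_child)
        leaf = dendropy.Node(taxon=tns.get_taxon(f"t{i}"))
        mid.add_child(leaf)
        edges.extend([mid.edge, leaf.edge, old_child.edge])
        edges = list({id(e): e for e in edges}.values())
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = np.array(
        [
            [pdm.distance(tns.get_taxon(x), tns.get_taxon(y)) for y in labels]
            for x in labels
        ]
    )
    return tree, DistanceMatrix(labels, D)


def path_length_matrix(tree, labels):
    tns = tree.taxon_namespace
    pdm = tree.phylogenetic_distance_matrix()
    return np.array(
        [
            [pdm.distance(tns.get_taxon(x), tns.get_taxon(y)) for y in labels]
            for x in labels
        ]
    )


class TestIdentityAndDistance:
    def test_identical_rows(self):
        assert pairwise_identity("ACDEF", "ACDEF") == 100

    def test_gapped_hand_count(self):
        """'AC-G' vs 'AT-G': 3 comparable columns, 2 matches."""
        assert pairwise_identity("AC-G", "AT-G") == pytest.approx(200 / 3)

    def test_disjoint_gap_masks(self):
        assert pairwise_identity("A--", "-AA") == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_identity("AC", "ACG")

    def test_matrix_matches_hand_counts(self):
        aln = AlignedSet(["a", "b", "c"], ["ACDE", "ACDF", "AAAA"])
        D = distance_matrix(aln)
        assert D.values[0, 1] == pytest.approx(0.25)  # 3/4 identical
        assert D.values[0, 2] == pytest.approx(0.75)  # 1/4 identical
        assert np.allclose(D.values, D.values.T)

    def test_matrix_symmetry_random(self, rng):
        aa = "ACDEFG-"
        rows = [
            "".join(aa[i] for i in rng.integers(len(aa), size=40)) for _ in range(6)
        ]
        D = distance_matrix(AlignedSet([f"s{i}" for i in range(6)], rows))
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        """d(ab)=3, d(ac)=4, d(bc)=5 -> branches 1, 2, 3."""
        D = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_four_taxon_additive_recovery(self):
        """Tree ((A:1,B:2):1,C:3,D:4) gives an additive matrix NJ must
        reproduce exactly."""
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels, D))
        assert np.allclose(path_length_matrix(tree, labels), D, atol=1e-12)

    def test_random_additive_oracle(self, rng):
        """NJ on exact path-length matrices: topology (RF=0) and branch
        lengths (1e-9) recovered, 4-12 taxa."""
        for _ in range(40):
            n = int(rng.integers(4, 13))
            true_tree, D = random_additive_case(rng, n)
            est = nj_tree(D)
            est2 = dendropy.Tree.get(
                data=est.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=true_tree.taxon_namespace,
            )
            est2.encode_bipartitions()
            true_tree.encode_bipartitions()
            assert treecompare.symmetric_difference(true_tree, est2) == 0
            assert np.allclose(
                path_length_matrix(est, D.labels), D.values, atol=1e-9
            )

    def test_taxon_order_invariance(self, rng):
        _, D = random_additive_case(rng, 7)
        perm = rng.permutation(7)
        Dp = DistanceMatrix(
            [D.labels[i] for i in perm], D.values[np.ix_(perm, perm)]
        )
        t1, t2 = nj_tree(D), nj_tree(Dp)
        tns = dendropy.TaxonNamespace(D.labels)
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert treecompare.symmetric_difference(a, b) == 0

    def test_agrees_with_ape_nj(self, rng):
        """Independent cross-check: R's ape::nj on the same matrix gives
        the same unrooted topology."""
        _, D = random_additive_case(rng, 8)
        # perturb away from additivity so the test is not vacuous
        noise = rng.uniform(0, 0.01, size=D.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        Dn = DistanceMatrix(D.labels, D.values + noise)
        mine = nj_tree(Dn)
        rows = "\n".join(",".join(str(x) for x in row) for row in Dn.values)
        rscript = (
            "suppressMessages(library(ape));"
            f"m <- matrix(scan(text='{';'.join(','.join(str(x) for x in row) for row in Dn.values)}', sep=',', quiet=TRUE), nrow={len(Dn.labels)}, byrow=TRUE);"
            f"rownames(m) <- colnames(m) <- c({', '.join(repr(l) for l in Dn.labels)});"
            "cat(write.tree(nj(as.dist(m))))"
        )
        res = subprocess.run(
            ["Rscript", "-e", rscript.replace(";", "\n")],
            capture_output=True,
            text=True,
            check=True,
        )
        tns = dendropy.TaxonNamespace(Dn.labels)
        ape_tree = dendropy.Tree.get(
            data=res.stdout.strip(), schema="newick", taxon_namespace=tns
        )
        my_tree = dendropy.Tree.get(
            data=mine.as_string(schema="newick"), schema="newick", taxon_namespace=tns
        )
        ape_tree.encode_bipartitions()
        my_tree.encode_bipartitions()
        assert treecompare.symmetric_difference(ape_tree, my_tree) == 0

    def test_determinism(self, rng):
        _, D = random_additive_case(rng, 9)
        assert nj_tree(D).as_string(schema="newick") == nj_tree(D).as_string(
            schema="newick"
        )


class TestBootstrap:
    def test_same_seed_identical_supports(self):
        sim = simulate_family(SimulationSpec(seed=11))
        aln = sim.aligned()
        _, s1 = bootstrap_support(aln, replicates=20, seed=3)
        _, s2 = bootstrap_support(aln, replicates=20, seed=3)
        assert s1 == s2

    def test_single_replicate_supports_binary(self):
        sim = simulate_family(SimulationSpec(seed=12))
        _, supports = bootstrap_support(sim.aligned(), replicates=1, seed=0)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_clean_clades_high_support(self):
        """Four clearly separated lineages: every true lineage clade gets
        >= 95% support at 100 replicates."""
        sim = simulate_family(
            SimulationSpec(seed=13, duplication_scope="terminal", duplication_rate=6.0)
        )
        _, supports = bootstrap_support(sim.aligned(), replicates=100, seed=1)
        for lin in ("fish", "amphibian", "bird_reptile", "mammal"):
            labels = frozenset(
                l for l, v in sim.lineage_map.items() if v == lin
            )
            if len(labels) < 2:
                continue
            assert supports[labels] >= 95


class TestClassification:
    def test_simulated_decoys_non_member(self):
        sim = simulate_family(SimulationSpec(seed=21, n_decoys=4))
        tree = nj_tree(distance_matrix(sim.aligned()))
        calls = classify_by_outgroup(
            tree, sim.outgroup_labels, sim.family_labels, sim.decoy_labels + sim.family_labels
        )
        assert all(calls[d] == "non_member" for d in sim.decoy_labels)
        assert all(calls[f] == "member" for f in sim.family_labels)

    def test_candidate_identical_to_reference(self):
        nwk = "((R1:0.01,CAND:0.01):1,R2:1,(O1:1,O2:1):2);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        calls = classify_by_outgroup(tree, ["O1", "O2"], ["R1", "R2"], ["CAND"])
        assert calls["CAND"] == "member"

    def test_candidate_on_outgroup_edge_is_non_member(self):
        """A candidate attached between the family and the outgroup is
        basal to the family: not a member."""
        nwk = "((R1:1,R2:1):1,CAND:1,(O1:1,O2:1):2);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        calls = classify_by_outgroup(tree, ["O1", "O2"], ["R1", "R2"], ["CAND"])
        assert calls["CAND"] == "non_member"

    def test_nonmonophyletic_outgroup_warns(self):
        nwk = "((R1:1,O1:1):1,R2:1,(O2:1,R3:1):1);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        with pytest.warns(UserWarning):
            classify_by_outgroup(tree, ["O1", "O2"], ["R1", "R2", "R3"], ["R3"])

    def test_empty_outgroup_rejected(self):
        nwk = "((A:1,B:1):1,C:1,D:1);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        with pytest.raises(ValueError):
            classify_by_outgroup(tree, [], ["A"], ["B"])


class TestSubgroups:
    def test_lineage_specific_expansion_recovered(self):
        """With duplications only after lineage splits, subgroups coincide
        with lineages: each subgroup is lineage-pure."""
        sim = simulate_family(SimulationSpec(seed=31))
        tree = nj_tree(distance_matrix(sim.aligned()))
        sub = assign_subgroup(tree, sim.lineage_map)
        groups: dict[str, set[str]] = {}
        for label, group in sub.items():
            if group != "outgroup":
                groups.setdefault(group, set()).add(sim.lineage_map[label])
        assert all(len(lineages) == 1 for lineages in groups.values())

    def test_single_lineage_single_subgroup(self):
        nwk = "((a:1,b:1):1,c:1,(o1:1,o2:1):3);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        sub = assign_subgroup(
            tree,
            {"a": "fish", "b": "fish", "c": "fish", "o1": "outgroup", "o2": "outgroup"},
        )
        assert len({v for k, v in sub.items() if v != "outgroup"}) == 1

    def test_pre_split_duplication_two_subgroups(self):
        """A duplication before a lineage split interleaves lineages: the
        mixed clade resolves into >= 2 subgroups per lineage copy."""
        nwk = "(((f1:1,m1:1):0.5,(f2:1,m2:1):0.5):1,x:3,(o1:1,o2:1):3);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        sub = assign_subgroup(
            tree,
            {
                "f1": "fish",
                "f2": "fish",
                "m1": "mammal",
                "m2": "mammal",
                "x": "fish",
                "o1": "outgroup",
                "o2": "outgroup",
            },
        )
        fish_groups = {sub["f1"], sub["f2"]}
        assert len(fish_groups) == 2
        assert sub["m1"] != sub["m2"]
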