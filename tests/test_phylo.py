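import itertools

import numpy as np
import pytest

from indolepath.phylo import (
    DistanceMatrix,
    distance_matrix,
    exclusive_clades,
    global_identity,
    neighbor_joining,
    read_newick,
)
from indolepath.synthetic import mutate_to_identity, random_protein
from oracles import random_additive_tree


class TestGlobalIdentity:
    def test_identical(self):
        assert global_identity("MKLVWA", "MKLVWA") == 100.0

    def test_single_substitution(self):
        assert global_identity("ACDE", "ACDF") == 75.0

    def test_symmetric(self):
        a = random_protein(40, 1).sequence
        b = random_protein(40, 2).sequence
        assert global_identity(a, b) == pytest.approx(global_identity(b, a))


class TestDistanceMatrix:
    def test_identical_sequences_zero_distance(self):
        s = random_protein(30, 3).sequence
        dm = distance_matrix({"a": s, "b": s, "c": s})
        assert np.allclose(dm.d, 0.0)

    def test_symmetry_and_range(self):
        seqs = {f"x{i}": random_protein(40, 10 + i).sequence for i in range(4)}
        dm = distance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert (dm.d >= 0).all() and (dm.d <= 1).all()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "a", "b"], np.zeros((3, 3)))

    def test_asymmetric_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], m)


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        # a = (d_ab + d_ac - d_bc)/2, etc.
        (center,) = [n for n in t.adjacency if n not in t.leaves]
        assert t.adjacency[center]["a"] == pytest.approx(0.1)
        assert t.adjacency[center]["b"] == pytest.approx(0.2)
        assert t.adjacency[center]["c"] == pytest.approx(0.4)

    def test_additive_four_leaf_recovery(self):
        # distances generated from tree ((A:2,B:3):1,(C:4,D:5))
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        t = neighbor_joining(DistanceMatrix(labels, d))
        for i, j in itertools.combinations(range(4), 2):
            assert t.leaf_distance(labels[i], labels[j]) == pytest.approx(d[i, j], abs=1e-12)
        assert frozenset({"A", "B"}) in t.bipartitions()

    def test_random_additive_trees_recovered(self):
        """NJ reproduces topology (all bipartitions) and path lengths on
        additive matrices from random 5-8 leaf trees."""
        rng = np.random.default_rng(41)
        for rep in range(12):
            n = int(rng.integers(5, 9))
            labels, d, true_bips = random_additive_tree(rng, n)
            t = neighbor_joining(DistanceMatrix(labels, d))
            got = {
                min(b, frozenset(labels) - b, key=sorted)
                for b in t.bipartitions()
                if 2 <= len(b) <= n - 2
            }
            assert got == true_bips  # Robinson-Foulds distance 0
            for i, j in itertools.combinations(range(n), 2):
                assert t.leaf_distance(labels[i], labels[j]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_topology_agrees_with_skbio(self):
        """Independent oracle: scikit-bio's NJ on the same matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        rng = np.random.default_rng(43)
        labels, d, _ = random_additive_tree(rng, 6)
        ours = neighbor_joining(DistanceMatrix(labels, d))
        theirs = nj(SkbioDM(d, ids=labels))
        ours_bips = {
            min(b, frozenset(labels) - b, key=sorted)
            for b in ours.bipartitions()
            if 2 <= len(b) <= 4
        }
        theirs_bips = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= 4:
                theirs_bips.add(min(side, frozenset(labels) - side, key=sorted))
        assert theirs_bips <= ours_bips

    def test_newick_round_trip(self, tmp_path):
        rng = np.random.default_rng(47)
        labels, d, _ = random_additive_tree(rng, 5)
        t = neighbor_joining(DistanceMatrix(labels, d))
        path = tmp_path / "t.nwk"
        t.to_newick(path)
        back = read_newick(path)
        assert sorted(back.leaves) == sorted(t.leaves)
        for i, j in itertools.combinations(range(5), 2):
            assert back.leaf_distance(labels[i], labels[j]) == pytest.approx(
                t.leaf_distance(labels[i], labels[j]), rel=1e-6
            )


class TestExclusiveClades:
    def _tree_from(self, labels, d):
        return neighbor_joining(DistanceMatrix(labels, np.asarray(d, dtype=float)))

    def test_clean_monophyletic_group(self):
        # 4 close leaves of one species, 2 distant others
        labels = ["a1", "a2", "a3", "a4", "b1", "c1"]
        d = np.full((6, 6), 0.8)
        np.fill_diagonal(d, 0.0)
        for i, j in itertools.combinations(range(4), 2):
            d[i, j] = d[j, i] = 0.1
        t = self._tree_from(labels, d)
        rep = exclusive_clades(
            t, {"a1": "S", "a2": "S", "a3": "S", "a4": "S", "b1": "T", "c1": "U"}
        )
        assert (frozenset({"a1", "a2", "a3", "a4"}), "S", "no support") in rep.clades

    def test_fully_mixed_labels(self):
        rng = np.random.default_rng(53)
        labels, d, _ = random_additive_tree(rng, 6)
        t = self._tree_from(labels, d)
        species = {l: ("X" if i % 2 else "Y") for i, l in enumerate(labels)}
        rep = exclusive_clades(t, species)
        # alternating labels along index order need not align with the tree,
        # but no clade may mix species
        for leaves, sp, _ in rep.clades:
            assert {species[l] for l in leaves} == {sp}

    def test_unlabeled_leaf_rejected(self):
        labels = ["a", "b", "c", "d"]
        d = np.array([[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], dtype=float)
        t = self._tree_from(labels, d)
        with pytest.raises(ValueError, match="d"):
            exclusive_clades(t, {"a": "S", "b": "S", "c": "T"})

    def test_invariant_under_leaf_reordering(self):
        rng = np.random.default_rng(59)
        labels, d, _ = random_additive_tree(rng, 7)
        species = {l: ("S" if i < 3 else f"sp{i}") for i, l in enumerate(labels)}
        t1 = self._tree_from(labels, d)
        perm = list(rng.permutation(len(labels)))
        labels2 = [labels[i] for i in perm]
        d2 = d[np.ix_(perm, perm)]
        t2 = self._tree_from(labels2, d2)
        r1 = {frozenset(c[0]) for c in exclusive_clades(t1, species).clades}
        r2 = {frozenset(c[0]) for c in exclusive_clades(t2, species).clades}
        assert r1 == r2

    def test_planted_divergent_clusters_detected(self):
        """Emulates divergent same-species homolog types: 3 planted clusters
        for one species among distinct-species background homologs."""
        base = random_protein(120, 61).sequence
        seqs = {}
        species = {}
        rng_seed = 200
        for c in range(3):
            # cluster centers mutually far (~35% between-identity); members
            # tight around each center (high within-identity); each cluster
            # gets a different-species sister lineage so the clusters are
            # separated in the tree rather than forming one block
            center, _ = mutate_to_identity(base, 35.0, seed=70 + c)
            for m in range(3):
                mut, _ = mutate_to_identity(center.sequence, 80.0, seed=rng_seed + c * 10 + m)
                sid = f"sal_t{c + 1}_{m}"
                seqs[sid] = mut.sequence
                species[sid] = "L. salivarius"
            sister, _ = mutate_to_identity(center.sequence, 55.0, seed=400 + c)
            seqs[f"bg{c}"] = sister.sequence
            species[f"bg{c}"] = f"other{c}"
        out, _ = mutate_to_identity(base, 60.0, seed=500)
        seqs["bg3"] = out.sequence
        species["bg3"] = "other3"
        dm = distance_matrix(seqs)
        tree = neighbor_joining(dm)
        rep = exclusive_clades(tree, species)
        sal = sorted(
            [sorted(leaves) for leaves, sp, _ in rep.clades if sp == "L. salivarius"]
        )
        expected = sorted(
            [sorted(f"sal_t{c + 1}_{m}" for m in range(3)) for c in range(3)]
        )
        assert sal == expected
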