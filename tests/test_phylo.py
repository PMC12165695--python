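"""Structural distances, neighbor joining, Newick and PHYLIP I/O."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from hepnscout.phylo import (
    combined_distance_matrix,
    is_monophyletic,
    neighbor_joining,
    read_newick,
    read_phylip,
    sequence_distance_matrix,
    structural_distance_matrix,
    write_newick,
    write_phylip,
)
from hepnscout.synth import make_extended, make_helix, perturb

from conftest import random_additive_matrix


class TestStructuralDistances:
    def test_identical_structures_zero_matrix(self):
        copies = [make_helix(30, id=f"c{i}") for i in range(3)]
        dm = structural_distance_matrix(copies)
        assert np.allclose(dm.data, 0.0, atol=1e-9)

    def test_family_separation_and_symmetry(self):
        hel = make_helix(40, id="hb")
        ext = make_extended(40, id="eb")
        structs = [perturb(hel, 0.3, seed=i, id=f"h{i}") for i in range(3)]
        structs += [perturb(ext, 0.3, seed=i, id=f"e{i}") for i in range(3)]
        dm = structural_distance_matrix(structs)
        assert np.allclose(dm.data, dm.data.T, atol=1e-9)
        within = [dm[f"h{i}", f"h{j}"] for i in range(3) for j in range(3) if i < j]
        within += [dm[f"e{i}", f"e{j}"] for i in range(3) for j in range(3) if i < j]
        between = [dm[f"h{i}", f"e{j}"] for i in range(3) for j in range(3)]
        assert max(within) < min(between)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            structural_distance_matrix([make_helix(20, id="a"), make_helix(20, id="b")])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
        tree = neighbor_joining(dm)
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):3, C:4, D:5) -> additive distances
        dm = DistanceMatrix(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
            ["A", "B", "C", "D"],
        )
        tree = neighbor_joining(dm)
        out = tree.tip_tip_distances()
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert out[a, b] == pytest.approx(dm[a, b], abs=1e-9)
        # A and B are siblings across an internal edge
        assert is_monophyletic(tree, {"A", "B"})

    def test_exact_recovery_on_random_additive_matrices(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(4, 13))
            dm = random_additive_matrix(rng, n)
            tree = neighbor_joining(dm)
            out = tree.tip_tip_distances()
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1 :]:
                    assert out[a, b] == pytest.approx(dm[a, b], abs=1e-9), f"trial {trial}"

    def test_duplicate_labels_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix(np.zeros((3, 3)), ["A", "A", "B"])

    def test_asymmetric_rejected(self):
        m = DistanceMatrix([[0, 1, 2], [1, 0, 3], [2, 3, 0]], list("ABC"))
        m.data[0, 1] = 5.0
        with pytest.raises(ValueError):
            neighbor_joining(m)


class TestNewick:
    def test_three_leaf_star_serialization(self, tmp_path):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
        tree = neighbor_joining(dm)
        path = tmp_path / "star.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert sorted(text.strip("();").split(",")) == ["A:1", "B:1", "C:3"]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        dm = random_additive_matrix(rng, 7)
        tree = neighbor_joining(dm)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        out = back.tip_tip_distances()
        ref = tree.tip_tip_distances()
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1 :]:
                assert out[a, b] == pytest.approx(ref[a, b], abs=1e-9)

    def test_labels_with_spaces_quoted(self, tmp_path):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["seq one", "B", "C"])
        tree = neighbor_joining(dm)
        path = tmp_path / "q.nwk"
        write_newick(tree, path)
        assert "'seq one'" in path.read_text()
        back = read_newick(path)
        assert {t.name for t in back.tips()} == {"seq one", "B", "C"}


class TestCladeAndCombined:
    def test_planted_families_form_clades(self):
        hel = make_helix(40, id="hb")
        ext = make_extended(40, id="eb")
        structs = [perturb(hel, 0.3, seed=i, id=f"h{i}") for i in range(4)]
        structs += [perturb(ext, 0.3, seed=i, id=f"e{i}") for i in range(4)]
        tree = neighbor_joining(structural_distance_matrix(structs))
        assert is_monophyletic(tree, {f"h{i}" for i in range(4)})
        assert is_monophyletic(tree, {f"e{i}" for i in range(4)})
        assert not is_monophyletic(tree, {"h0", "e0"})

    def test_combined_distance_weighting(self):
        ids = list("ABC")
        ds = DistanceMatrix([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]], ids)
        dq = DistanceMatrix([[0, 0.8, 0.4], [0.8, 0, 0.2], [0.4, 0.2, 0]], ids)
        half = combined_distance_matrix(ds, dq, weight=0.5)
        assert half["A", "B"] == pytest.approx(0.5)
        assert np.allclose(combined_distance_matrix(ds, dq, 1.0).data, ds.data)

    def test_sequence_distance_identity(self):
        a = make_helix(30, sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL", id="a")
        b = make_helix(30, sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL", id="b")
        c = make_helix(30, sequence="MMMMMMMMMMWWWWWWWWWWYYYYYYYYYY", id="c")
        dm = sequence_distance_matrix([a, b, c])
        assert dm["a", "b"] == pytest.approx(0.0)
        assert dm["a", "c"] > 0.5


class TestPhylip:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        dm = random_additive_matrix(rng, 5)
        path = tmp_path / "m.phylip"
        write_phylip(dm, path)
        back = read_phylip(path)
        assert list(back.ids) == list(dm.ids)
        assert np.allclose(back.data, dm.data, atol=1e-8)
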