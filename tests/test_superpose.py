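"""Superposition, TM-score and alignment: oracles and invariants."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hepnscout.structio import Structure
from hepnscout.superpose import (
    align_structures,
    alignment_zscore,
    kabsch_superpose,
    tm_d0,
    tm_score,
)
from hepnscout.synth import make_extended, make_helix, perturb


def random_rigid_motion(seed: int):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


class TestKabsch:
    def test_identity(self, helix20):
        _, _, rmsd = kabsch_superpose(helix20.coords, helix20.coords)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_recovers_rigid_motion(self, helix20):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t0 = np.array([5.0, -2.0, 1.0])
        Q = helix20.coords @ Rz.T + t0
        R, t, rmsd = kabsch_superpose(helix20.coords, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        # recovered transform inverts the applied motion
        assert np.allclose(R, Rz.T, atol=1e-9)
        assert np.allclose(R @ Q.T + t[:, None], helix20.coords.T, atol=1e-8)

    def test_matches_numeric_minimization_oracle(self):
        """Unit square with one corner lifted 1 A out of plane: compare the
        closed-form solution against brute-force numeric minimization over
        rotation vectors."""
        P = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        Q = P.copy()
        Q[2, 2] = 1.0

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            Qr = Q @ R.T
            # optimal translation given the rotation is the centroid shift
            diff = (P - P.mean(0)) - (Qr - Qr.mean(0))
            return np.sqrt((diff**2).sum() / len(P))

        best = min(
            minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in [np.zeros(3), [0.3, 0, 0], [0, 0.3, 0], [0, 0, 0.3], [0.2, 0.2, 0.2]]
        )
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(best, abs=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rmsd_invariant_under_rigid_motion(self, seed, helix40):
        rng = np.random.default_rng(seed)
        Q = helix40.coords + rng.normal(0, 1.0, helix40.coords.shape)
        _, _, base = kabsch_superpose(helix40.coords, Q)
        R, t = random_rigid_motion(seed)
        _, _, moved = kabsch_superpose(helix40.coords @ R.T + t, Q)
        assert moved == pytest.approx(base, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTMScore:
    def test_self_alignment_is_one(self, helix40):
        pairs = [(i, i) for i in range(1, 41)]
        assert tm_score(pairs, helix40.coords, helix40.coords, 40) == pytest.approx(1.0)

    def test_empty_pairs_zero(self, helix40):
        assert tm_score([], helix40.coords, helix40.coords, 40) == 0.0

    @pytest.mark.parametrize("n,L", [(10, 40), (25, 25), (5, 60)])
    def test_all_pairs_at_d0_give_half_per_term(self, n, L):
        """Each pair at distance exactly d0(L) contributes 1/2, so the
        direct-summation score is n / (2 L)."""
        rng = np.random.default_rng(0)
        P = rng.uniform(-10, 10, (n, 3))
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        Q = P + tm_d0(L) * dirs
        pairs = [(i, i) for i in range(1, n + 1)]
        got = tm_score(pairs, P, Q, L, optimize=False)
        assert got == pytest.approx(n / (2 * L), abs=1e-12)

    def test_d0_clamped_for_short_chains(self):
        assert tm_d0(8) == 0.5
        assert tm_d0(100) == pytest.approx(1.24 * np.cbrt(85) - 1.8)


class TestAlignStructures:
    def test_self_alignment(self, helix40):
        aln = align_structures(helix40, helix40)
        assert aln.pairs == [(i, i) for i in range(1, 41)]
        assert aln.tm_query == pytest.approx(1.0, abs=1e-9)
        assert aln.rmsd_aligned == pytest.approx(0.0, abs=1e-9)

    def test_perturbed_copy_recovers_planted_pairing(self, helix40):
        noisy = perturb(helix40, 0.5, seed=11, id="helix40_noisy")
        aln = align_structures(helix40, noisy)
        correct = sum(1 for q, t in aln.pairs if q == t)
        assert correct >= 0.9 * len(helix40)
        assert aln.tm_query > 0.75

    def test_unrelated_fold_scores_below_threshold_and_below_perturbed(self, helix40):
        noisy = perturb(helix40, 0.5, seed=11, id="helix40_noisy")
        ext = make_extended(40, id="ext40")
        tm_related = align_structures(helix40, noisy).tm_query
        tm_unrelated = align_structures(helix40, ext).tm_query
        assert tm_unrelated < 0.5
        assert tm_unrelated < tm_related

    def test_too_short_raises(self):
        tiny = make_helix(6, id="tiny")
        with pytest.raises(ValueError):
            align_structures(tiny, tiny)

    def test_role_swap_symmetry(self, helix40):
        other = perturb(make_helix(55, id="h55"), 0.6, seed=5, id="h55n")
        ab = align_structures(helix40, other)
        ba = align_structures(other, helix40)
        assert ab.tm_query == pytest.approx(ba.tm_target, abs=1e-12)
        assert ab.tm_target == pytest.approx(ba.tm_query, abs=1e-12)
        assert sorted((t, q) for q, t in ab.pairs) == sorted(ba.pairs)

    @pytest.mark.parametrize("na,nb,seed", [(24, 24, 0), (30, 22, 1), (16, 28, 2)])
    def test_never_below_contiguous_block_oracle(self, na, nb, seed):
        """On small structures the heuristic alignment must score at least
        as well as exhaustive search over all gapless contiguous-block
        pairings (it may beat blocks, never fall below)."""
        rng = np.random.default_rng(seed)
        a = Structure("a", np.arange(1, na + 1), "A" * na, np.cumsum(rng.normal(0, 2, (na, 3)), 0))
        b = Structure("b", np.arange(1, nb + 1), "A" * nb, np.cumsum(rng.normal(0, 2, (nb, 3)), 0))
        L = min(na, nb)
        best_block = 0.0
        for length in range(8, L + 1):
            for i in range(na - length + 1):
                for j in range(nb - length + 1):
                    pairs = [(i + k + 1, j + k + 1) for k in range(length)]
                    best_block = max(best_block, tm_score(pairs, a.coords, b.coords, L))
        aln = align_structures(a, b)
        heuristic = tm_score(aln.pairs, a.coords, b.coords, L)
        assert heuristic >= best_block - 1e-9


class TestZScore:
    def test_self_comparison_significant(self):
        """Self-comparison of a two-domain fold stands far above its
        block-shuffle null. (A single ideal helix is unsuitable here: every
        5-residue block has identical geometry, so shuffled decoys remain
        near-perfect self-matches and the null is degenerately strong.)"""
        from hepnscout.synth import make_chimera

        c, _ = make_chimera(("HE", "HE"), id="zself")
        z = alignment_zscore(c, c, n_null=50, seed=1)
        assert z > 5

    def test_deterministic_and_orders_folds(self, helix40):
        ext = make_extended(40, id="ext40")
        z_unrelated = alignment_zscore(helix40, ext, n_null=20, seed=3)
        z_self = alignment_zscore(helix40, helix40, n_null=20, seed=3)
        assert z_unrelated < z_self
        assert alignment_zscore(helix40, ext, n_null=20, seed=3) == z_unrelated

    def test_requires_minimum_null(self, helix40):
        with pytest.raises(ValueError):
            alignment_zscore(helix40, helix40, n_null=5, seed=0)
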