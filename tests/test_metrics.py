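"""Superposition RMSD, distance-matrix RMSD, and ensemble metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tracefold.metrics import (
    drmsd,
    drmsd_max,
    max_distance_matrix,
    per_residue_rmsd,
    superpose_rmsd,
)
from tracefold.structure import Chain


def chain_of(coords):
    return Chain.from_coords(np.asarray(coords, dtype=float))


def brute_force_rmsd(a, b):
    """Independent superposition oracle: rotation grid + local refinement."""
    P = a.coords - a.coords.mean(axis=0)
    Q = b.coords - b.coords.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 7)
    for x in grid:
        for y in grid:
            for z in grid:
                res = minimize(cost, x0=[x, y, z], method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-12})
                best = min(best, res.fun)
    return best


def random_chain(rng, n=5):
    return chain_of(rng.uniform(-10, 10, size=(n, 3)))


def rigid_copy(chain, rng):
    R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    return chain.with_coords(chain.coords @ R.T + rng.uniform(-5, 5, 3))


CHIRAL = chain_of([[0, 0, 0], [6, 0, 0], [6, 6, 0], [6, 6, 6], [0, 6, 6]])


class TestSuperposeRmsd:
    def test_identical_chains_give_zero(self, rng):
        chain = random_chain(rng)
        assert superpose_rmsd(chain, chain) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_rigid_motion(self, rng):
        chain = random_chain(rng)
        assert superpose_rmsd(chain, rigid_copy(chain, rng)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_symmetric(self, rng):
        a, b = random_chain(rng), random_chain(rng)
        assert superpose_rmsd(a, b) == pytest.approx(superpose_rmsd(b, a), abs=1e-9)

    def test_matches_brute_force_oracle_on_small_instances(self, rng):
        for n in (4, 5, 6):
            a, b = random_chain(rng, n), random_chain(rng, n)
            assert superpose_rmsd(a, b) == pytest.approx(
                brute_force_rmsd(a, b), abs=1e-3
            )

    def test_reflection_is_not_free(self):
        mirrored = CHIRAL.with_coords(CHIRAL.coords * np.array([1, 1, -1]))
        assert superpose_rmsd(CHIRAL, mirrored) > 0.5

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            superpose_rmsd(random_chain(rng, 4), random_chain(rng, 5))


class TestDrmsd:
    def test_identical_chains_give_zero(self, rng):
        chain = random_chain(rng)
        assert drmsd(chain, chain) == 0.0

    def test_blind_to_reflection_and_rigid_motion(self, rng):
        mirrored = CHIRAL.with_coords(CHIRAL.coords * np.array([1, 1, -1]))
        assert drmsd(CHIRAL, mirrored) == pytest.approx(0.0, abs=1e-9)
        assert drmsd(CHIRAL, rigid_copy(CHIRAL, rng)) == pytest.approx(0.0, abs=1e-9)

    def test_three_point_case_with_one_distance_off_by_one(self):
        native = chain_of([[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        # same |ab| = 3 and |ac| = 4, but |bc| = 4 instead of 5
        phi = np.arcsin(0.375)
        model = chain_of(
            [[0, 0, 0], [3, 0, 0], [4 * np.sin(phi), 4 * np.cos(phi), 0]]
        )
        assert drmsd(native, model) == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-9)

    def test_zero_iff_identical_distance_matrices(self, rng):
        a = random_chain(rng)
        b = random_chain(rng)
        assert drmsd(a, b) > 0
        assert drmsd(a, a.with_coords(-a.coords)) == pytest.approx(0.0, abs=1e-9)


class TestMaxDistanceMatrix:
    def test_single_model_is_its_own_matrix(self, rng):
        chain = random_chain(rng)
        np.testing.assert_allclose(
            max_distance_matrix([chain]), chain.distance_matrix()
        )

    def test_dominates_every_member(self, rng):
        models = [random_chain(rng) for _ in range(4)]
        mdm = max_distance_matrix(models)
        for m in models:
            assert np.all(mdm >= m.distance_matrix() - 1e-12)

    def test_hand_computed_two_model_maxima(self):
        a = chain_of([[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        b = chain_of([[0, 0, 0], [5, 0, 0], [0, 1, 0]])
        mdm = max_distance_matrix([a, b])
        assert mdm[0, 1] == pytest.approx(5.0)       # max(3, 5)
        assert mdm[0, 2] == pytest.approx(4.0)       # max(4, 1)
        assert mdm[1, 2] == pytest.approx(np.sqrt(26.0))  # max(5, sqrt(26))


class TestDrmsdMax:
    def test_ensemble_of_native_copies_gives_zero(self, rng):
        native = random_chain(rng)
        assert drmsd_max([native, native, native], native) == pytest.approx(0.0)

    def test_two_model_toy_case_from_direct_formula(self):
        native = chain_of([[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        stretched = chain_of([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        mdm = max_distance_matrix([native, stretched])
        iu = np.triu_indices(3, k=1)
        expect = np.sqrt(np.mean((mdm[iu] - native.distance_matrix()[iu]) ** 2))
        assert drmsd_max([native, stretched], native) == pytest.approx(expect)
        assert expect > 0

    def test_at_least_mean_contribution_of_perturbed_model(self, rng):
        native = random_chain(rng)
        moved = native.with_coords(native.coords * 1.3)
        assert drmsd_max([native, moved], native) >= 0


class TestPerResidueRmsd:
    def test_native_copies_give_flat_zero_profile(self, rng):
        native = random_chain(rng, 8)
        profile = per_residue_rmsd([native, native], native)
        np.testing.assert_allclose(profile, 0.0, atol=1e-9)

    def test_localized_displacement_shows_up_locally(self, y_linked):
        native = y_linked.chain
        lo, hi = y_linked.loop_ranges[0]
        coords = native.coords.copy()
        coords[lo:hi] += np.array([3.0, 0.0, 0.0])
        moved = native.with_coords(coords)
        profile = per_residue_rmsd([moved], native)
        assert profile[lo:hi].mean() > 3 * np.delete(profile, np.s_[lo:hi]).mean()

    def test_profile_mean_square_consistent_with_global_rmsd(self, rng):
        native = random_chain(rng, 8)
        models = [random_chain(rng, 8) for _ in range(3)]
        profile = per_residue_rmsd(models, native)
        global_msd = np.mean(
            [superpose_rmsd(m, native) ** 2 for m in models]
        )
        assert np.mean(profile**2) == pytest.approx(global_msd, rel=1e-9)
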