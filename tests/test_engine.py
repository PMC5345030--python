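"""Refinement steps, perturbation, and the full simulation loop."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from tracefold.engine import (
    SimConfig,
    local_window_pairs,
    make_circle_start,
    perturb_sses,
    simulate,
    step_bonded,
    step_local_window,
    step_pair_restraints,
    step_repulsion,
    step_sse_ideal,
)
from tracefold.metrics import superpose_rmsd
from tracefold.structure import Chain, detect_sses


def two_point_chain(d):
    return Chain.from_coords(np.array([[0.0, 0, 0], [d, 0, 0]]))


def spaced_chain(*gaps):
    xs = np.concatenate([[0.0], np.cumsum(gaps)])
    return Chain.from_coords(np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)]))


def sep(chain, i=0, j=-1):
    return float(np.linalg.norm(chain.coords[j] - chain.coords[i]))


class TestStepBonded:
    def test_ideal_bond_is_a_fixed_point(self):
        chain = two_point_chain(6.0)
        np.testing.assert_allclose(step_bonded(chain).coords, chain.coords)

    def test_long_bond_contracts_by_one_step(self):
        assert sep(step_bonded(two_point_chain(8.0))) == pytest.approx(7.5)

    def test_short_bond_stretches(self):
        assert sep(step_bonded(two_point_chain(5.0))) == pytest.approx(5.5)

    def test_coincident_points_separate_deterministically(self):
        chain = Chain.from_coords(np.zeros((2, 3)))
        moved = step_bonded(chain)
        assert sep(moved) > 0
        np.testing.assert_allclose(step_bonded(chain).coords, moved.coords)

    def test_random_chain_converges_to_six(self, rng):
        chain = Chain.from_coords(rng.uniform(0, 50, size=(20, 3)))
        for _ in range(5000):
            chain = step_bonded(chain)
        bonds = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
        assert np.round(bonds.mean()) == 6
        assert np.all(np.abs(bonds - 6.0) < 0.5)


class TestStepRepulsion:
    def test_close_pair_pushed_apart_by_one_step(self):
        chain = spaced_chain(4.0, 4.0)  # residues 0 and 2 are 8 A apart
        assert sep(step_repulsion(chain), 0, 2) == pytest.approx(8.5)

    def test_pair_beyond_threshold_untouched(self):
        chain = spaced_chain(5.5, 5.5)  # 11 A end to end
        np.testing.assert_allclose(step_repulsion(chain).coords, chain.coords)

    def test_excluded_pair_untouched(self):
        chain = spaced_chain(4.0, 4.0)
        out = step_repulsion(chain, excluded_pairs=[(0, 2)])
        np.testing.assert_allclose(out.coords, chain.coords)

    def test_bonded_neighbours_never_repelled(self):
        chain = two_point_chain(6.0)
        np.testing.assert_allclose(step_repulsion(chain).coords, chain.coords)


class TestStepLocalWindow:
    def make(self, native_d, current_d):
        native = spaced_chain(native_d / 2, native_d / 2)
        current = spaced_chain(current_d / 2, current_d / 2)
        return current, local_window_pairs(native)

    def test_native_distance_is_fixed_point(self):
        current, nld = self.make(10.0, 10.0)
        np.testing.assert_allclose(
            step_local_window(current, nld).coords, current.coords
        )

    def test_beyond_gate_untouched(self):
        current, nld = self.make(10.0, 19.0)
        assert sep(step_local_window(current, nld), 0, 2) == pytest.approx(19.0)

    def test_inside_gate_moves_toward_native_by_step(self):
        current, nld = self.make(10.0, 12.0)
        assert sep(step_local_window(current, nld), 0, 2) == pytest.approx(11.5)


class TestStepPairRestraints:
    def test_distant_pair_contracts_by_step(self):
        chain = two_point_chain(30.0)
        assert sep(step_pair_restraints(chain, [(0, 1)])) == pytest.approx(29.5)

    def test_pair_below_target_untouched(self):
        chain = two_point_chain(16.0)
        out = step_pair_restraints(chain, [(0, 1)])
        np.testing.assert_allclose(out.coords, chain.coords)

    def test_one_sided_convergence_to_target(self):
        chain = two_point_chain(30.0)
        seps = []
        for _ in range(60):
            chain = step_pair_restraints(chain, [(0, 1)])
            seps.append(sep(chain))
        assert seps[-1] == pytest.approx(17.0, abs=0.25)
        # never increases and never crosses below the target
        assert all(b <= a + 1e-9 for a, b in zip(seps, seps[1:]))
        assert all(s >= 17.0 - 1e-9 for s in seps)


class TestStepSseIdeal:
    def test_template_geometry_is_fixed_point(self, helix6):
        chain, pairs = helix6
        sses = detect_sses(pairs)
        np.testing.assert_allclose(
            step_sse_ideal(chain, sses).coords, chain.coords, atol=1e-9
        )

    def test_scaled_element_moves_back_toward_template(self, helix6):
        chain, pairs = helix6
        sses = detect_sses(pairs)
        swollen = chain.with_coords(chain.coords * 1.2)
        template = pdist(chain.coords)
        before = np.sqrt(np.mean((pdist(swollen.coords) - template) ** 2))
        after_chain = step_sse_ideal(swollen, sses)
        after = np.sqrt(np.mean((pdist(after_chain.coords) - template) ** 2))
        assert after < before

    def test_loop_residues_untouched(self, stemloop):
        sses = detect_sses(stemloop.ss.pairs)
        swollen = stemloop.chain.with_coords(stemloop.chain.coords * 1.1)
        out = step_sse_ideal(swollen, sses)
        lo, hi = stemloop.loop_ranges[0]
        np.testing.assert_allclose(out.coords[lo:hi], swollen.coords[lo:hi])


class TestPerturbSses:
    def test_zero_level_leaves_chain_unchanged(self, y_linked):
        sses = detect_sses(y_linked.ss.pairs)
        cfg = SimConfig(perturb_translation=0.0)
        out = perturb_sses(y_linked.chain, sses, cfg, np.random.default_rng(3))
        np.testing.assert_allclose(out.coords, y_linked.chain.coords)

    def test_rigid_motion_preserves_internal_distances(self, y_linked):
        sses = detect_sses(y_linked.ss.pairs)
        cfg = SimConfig(perturb_translation=0.1)
        out = perturb_sses(y_linked.chain, sses, cfg, np.random.default_rng(3))
        for sse in sses:
            np.testing.assert_allclose(
                pdist(out.coords[sse.members]),
                pdist(y_linked.chain.coords[sse.members]),
                atol=1e-9,
            )
        # loop residues are not directly displaced
        for lo, hi in y_linked.loop_ranges:
            np.testing.assert_allclose(
                out.coords[lo:hi], y_linked.chain.coords[lo:hi]
            )

    def test_same_seed_same_displacement(self, y_linked):
        sses = detect_sses(y_linked.ss.pairs)
        cfg = SimConfig(perturb_translation=0.08)
        a = perturb_sses(y_linked.chain, sses, cfg, np.random.default_rng(9))
        b = perturb_sses(y_linked.chain, sses, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.coords, b.coords)


class TestMakeCircleStart:
    def test_radius_and_spacing(self):
        chain = make_circle_start(100)
        radii = np.linalg.norm(chain.coords - chain.coords.mean(axis=0), axis=1)
        np.testing.assert_allclose(radii, 600.0 / (2 * np.pi), rtol=1e-9)
        bonds = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
        np.testing.assert_allclose(bonds, bonds[0], rtol=1e-9)

    def test_bonds_near_ideal_for_long_chains(self):
        for L in (30, 100, 300):
            chain = make_circle_start(L)
            bonds = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
            assert abs(bonds[0] - 6.0) / 6.0 < 0.01

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            make_circle_start(2)


class TestSimulate:
    def test_refinement_only_run_preserves_consistent_start(self, stemloop):
        cfg = SimConfig(cycles=200, perturb_translation=0.0, replicates=1, seed=5)
        result = simulate(stemloop.chain, stemloop.ss, [], cfg)
        assert superpose_rmsd(result.models[0], stemloop.chain) < 1.0

    def test_perturbed_run_drifts_from_start(self, y_linked):
        cfg = SimConfig(cycles=300, perturb_translation=0.08, replicates=3, seed=5)
        result = simulate(y_linked.chain, y_linked.ss, [], cfg)
        rmsds = [superpose_rmsd(m, y_linked.chain) for m in result.models]
        assert np.mean(rmsds) > 0.5

    def test_bit_reproducible_ensembles(self, y_linked):
        cfg = SimConfig(cycles=50, perturb_translation=0.08, replicates=2, seed=17)
        a = simulate(y_linked.chain, y_linked.ss, [(0, 30)], cfg)
        b = simulate(y_linked.chain, y_linked.ss, [(0, 30)], cfg)
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.coords, mb.coords)

    def test_replicates_differ_from_each_other(self, y_linked):
        cfg = SimConfig(cycles=50, perturb_translation=0.08, replicates=2, seed=17)
        result = simulate(y_linked.chain, y_linked.ss, [], cfg)
        assert not np.allclose(result.models[0].coords, result.models[1].coords)

    def test_diagnostics_track_bonds_and_restraints(self, stemloop):
        cfg = SimConfig(
            cycles=20, perturb_translation=0.02, replicates=1, seed=1, diagnostics=True
        )
        result = simulate(stemloop.chain, stemloop.ss, [(0, 8)], cfg)
        assert len(result.diagnostics["mean_bond"]) == 20
        assert all(5.0 < b < 7.0 for b in result.diagnostics["mean_bond"])
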