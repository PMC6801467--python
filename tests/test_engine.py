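"""Displacement-state grids, reversible-work profiles, local partition
functions, and their thermodynamic behavior."""

import math

import numpy as np
import pytest

from movetype import (
    Atom,
    ComplexPose,
    ClashError,
    Conformer,
    Molecule,
    MTSamplingConfig,
    PotentialModel,
    ThermoContext,
    atom_log_partition,
    atom_state_grid,
    axis_work_profile,
    local_log_partition,
    pair_energy,
    pair_state_vector,
)
from movetype.engine import AtomStateGrid

from conftest import harmonic_potential, zero_potential


def atom_at(x, y=0.0, z=0.0, element="C"):
    return Atom(element, (x, y, z), atom_id=0)


class TestPairStateVector:
    def test_zero_potential_all_zero(self):
        v = pair_state_vector(atom_at(3.0), atom_at(0.0), model=zero_potential())
        assert v.energies.shape == (21,)
        assert np.all(v.energies == 0.0)

    def test_middle_state_is_minimum_at_lj_minimum(self, model):
        a, b = atom_at(0.0), atom_at(0.0)
        _, rmin = model.combine(a, b)
        cfg = MTSamplingConfig(n_states_per_axis=1, displacement_unit=0.05)
        v = pair_state_vector(atom_at(rmin), atom_at(0.0), cfg, model)
        assert v.energies.argmin() == 1  # convexity at the minimum

    def test_harmonic_matches_closed_form(self):
        k, r0 = 2.0, 3.0
        model = harmonic_potential(k, r0)
        cfg = MTSamplingConfig()
        v = pair_state_vector(atom_at(3.2), atom_at(0.0), cfg, model)
        ks = np.arange(-10, 11)
        expected = 0.5 * k * (3.2 + ks * cfg.displacement_unit - r0) ** 2
        np.testing.assert_allclose(v.energies, expected, atol=1e-12)

    def test_center_equals_input_geometry_energy(self, model):
        v = pair_state_vector(atom_at(3.7), atom_at(0.0), model=model)
        assert v.center_energy == pytest.approx(
            pair_energy(atom_at(3.7), atom_at(0.0), 3.7, model)
        )

    def test_crossing_origin_clamps_to_inf(self):
        cfg = MTSamplingConfig(distance_range=1.0, displacement_unit=0.05)
        v = pair_state_vector(atom_at(0.02), atom_at(0.0), cfg, zero_potential())
        assert math.isinf(v.energies[0])


class TestAxisWorkProfile:
    def test_on_axis_work_equals_energy_difference(self, model):
        # direct energy-difference oracle for a collinear neighbor
        r0 = 4.5
        a = atom_at(r0)
        nb = atom_at(0.0)
        cfg = MTSamplingConfig()
        prof = axis_work_profile(a.position, a, [nb], "x", cfg, model)
        mid = prof.cumulative_work.size // 2
        for steps in (40, 100, -40, -100):
            delta = steps * cfg.step
            got = prof.cumulative_work[mid + steps]
            want = pair_energy(a, nb, r0 + delta, model) - pair_energy(a, nb, r0, model)
            assert got == pytest.approx(want, abs=0.01)

    def test_perpendicular_neighbor_first_step_vanishes(self, model):
        a = atom_at(0.0)
        nb = atom_at(0.0, y=3.8)
        cfg = MTSamplingConfig()
        prof = axis_work_profile(a.position, a, [nb], "x", cfg, model)
        mid = prof.cumulative_work.size // 2
        first = prof.cumulative_work[mid + 1] - prof.cumulative_work[mid]
        assert abs(first) < 1e-6  # cos(theta) ~ 0 at step zero

    def test_no_neighbors_gives_all_zero(self, model):
        a = atom_at(0.0)
        prof = axis_work_profile(a.position, a, [], "x", model=model)
        assert np.all(prof.cumulative_work == 0.0)

    def test_collision_truncates_with_inf(self):
        a = atom_at(0.3)
        nb = atom_at(0.0)
        prof = axis_work_profile(a.position, a, [nb], "x", model=zero_potential())
        assert math.isinf(prof.cumulative_work[0])  # the -0.5 A end hits r < 0.1

    def test_refinement_stability_under_step_halving(self, model):
        a, nb = atom_at(4.4), atom_at(0.0)
        ends = []
        for step in (0.02, 0.01, 0.005):
            cfg = MTSamplingConfig(step=step)
            prof = axis_work_profile(a.position, a, [nb], "x", cfg, model)
            ends.append(prof.cumulative_work[-1])
        err1, err2 = abs(ends[0] - ends[1]), abs(ends[1] - ends[2])
        assert err2 <= 0.75 * err1 + 1e-9  # O(step) convergence


class TestAtomStateGrid:
    def test_zero_potential_grid_is_zero(self):
        a, nb = atom_at(3.0), atom_at(0.0)
        grid = atom_state_grid(a.position, a, [nb], model=zero_potential())
        assert np.all(grid.energies == 0.0)

    def test_axis_slice_equals_axis_profile(self, model):
        a, nb = atom_at(4.0), atom_at(0.0)
        cfg = MTSamplingConfig()
        grid = atom_state_grid(a.position, a, [nb], cfg, model)
        prof = axis_work_profile(a.position, a, [nb], "x", cfg, model)
        np.testing.assert_allclose(
            grid.energies[:, cfg.n_states_per_axis, cfg.n_states_per_axis],
            prof.state_energies(cfg),
            atol=1e-12,
        )

    def test_against_brute_force_reevaluation(self, model):
        # single on-axis neighbor: re-evaluate the pair energy at every 3-D
        # displacement and compare with the separable axis-work sum
        a, nb = atom_at(4.2), atom_at(0.0)
        cfg = MTSamplingConfig()
        grid = atom_state_grid(a.position, a, [nb], cfg, model)
        offsets = grid.offsets()
        e0 = pair_energy(a, nb, 4.2, model)
        brute = np.array(
            [
                pair_energy(a, nb, float(np.linalg.norm(a.position + off - nb.position)), model)
                - e0
                for off in offsets
            ]
        )
        np.testing.assert_allclose(grid.energies.ravel(), brute, atol=0.05)

    def test_zero_displacement_state_is_zero(self, model):
        a, nb = atom_at(3.9), atom_at(0.0)
        grid = atom_state_grid(a.position, a, [nb], model=model)
        n = grid.config.n_states_per_axis
        assert grid.energies[n, n, n] == 0.0


class TestAtomLogPartition:
    def test_all_zero_grid_log_z_zero(self, thermo, small_config):
        ax = np.zeros(5)
        grid = AtomStateGrid(0, (ax, ax, ax), small_config)
        assert atom_log_partition(grid, thermo).log_z == pytest.approx(0.0, abs=1e-12)

    def test_half_clashed_grid_average_convention(self, thermo, small_config):
        # states {0, +inf} -> Z = (1+0)/2
        ax0 = np.array([0.0])
        grid = AtomStateGrid(0, (np.array([0.0, math.inf]), ax0, ax0), small_config)
        assert atom_log_partition(grid, thermo).log_z == pytest.approx(math.log(0.5))

    def test_random_grid_matches_high_precision_sum(self, thermo, small_config):
        from math import exp, fsum, log

        rng = np.random.default_rng(5)
        axes = tuple(rng.uniform(-2.0, 2.0, size=3) for _ in range(3))
        grid = AtomStateGrid(0, axes, small_config)
        es = grid.energies.ravel()
        expected = log(fsum(exp(-e / thermo.rt) for e in es) / es.size)
        assert atom_log_partition(grid, thermo).log_z == pytest.approx(expected, abs=1e-12)

    def test_fully_clashed_is_error(self, thermo, small_config):
        ax = np.array([math.inf, math.inf])
        with pytest.raises(ClashError):
            atom_log_partition(AtomStateGrid(0, (ax, ax, ax), small_config), thermo)

    def test_no_overflow_for_extreme_energies(self, thermo, small_config):
        for sign in (+1, -1):
            ax = np.array([sign * 500.0 / 3.0] * 3)
            lp = atom_log_partition(AtomStateGrid(0, (ax, ax, ax), small_config), thermo)
            assert math.isfinite(lp.log_z)
            assert lp.ensemble_energy == pytest.approx(sign * 500.0, rel=1e-9)

    def test_low_temperature_limit_reaches_grid_minimum(self, small_config):
        rng = np.random.default_rng(9)
        axes = tuple(rng.uniform(-1.5, 1.5, size=5) for _ in range(3))
        grid = AtomStateGrid(0, axes, small_config)
        emin = grid.energies.min()
        errs = []
        for tk in (50.0, 5.0, 0.5):
            lp = atom_log_partition(grid, ThermoContext(temperature=tk))
            errs.append(abs(lp.ensemble_energy - emin))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01


class TestLocalLogPartition:
    def test_single_movable_atom_reduction(self, ring_system, thermo, small_config, model):
        from movetype.potential import configuration_energy

        protein, guest = ring_system
        mol = Molecule([Atom("C", (0.0, 0.0, 0.0), atom_id=0)], [], name="probe")
        pose = ComplexPose(protein, Conformer(mol, mol.positions))
        lp = local_log_partition(pose, None, small_config, model, thermo)
        a = mol.atoms[0]
        grid = atom_state_grid(a.position, a, protein.atoms, small_config, model)
        expected = (
            atom_log_partition(grid, thermo).log_z
            - configuration_energy(pose, model) / thermo.rt
        )
        assert lp.log_z == pytest.approx(expected, rel=1e-12)

    def test_zero_potential_reduces_to_config_weight(self, small_config, thermo):
        model = zero_potential()
        _, mol = __import__("movetype").make_toy_system("chain-4", seed=1)
        conf = Conformer(mol, mol.positions)
        lp = local_log_partition(conf, None, small_config, model, thermo)
        # zero pair potential: every atomic grid is flat, so only the
        # configuration's own (torsion + solvation) weight remains
        from movetype.potential import configuration_energy

        assert lp.log_z == pytest.approx(
            -configuration_energy(conf, model) / thermo.rt, rel=1e-9
        )

    def test_clashed_configuration_is_flagged_not_fatal(self, small_config, thermo, model):
        atoms = [Atom("C", (0, 0, 0), atom_id=0), Atom("C", (0.05, 0, 0), atom_id=1)]
        mol = Molecule(atoms, [], name="clash")
        lp = local_log_partition(Conformer(mol, mol.positions), None, small_config, model, thermo)
        assert lp.clashed and lp.log_z == -math.inf
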