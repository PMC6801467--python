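"""Conformer/pose sampling, deduplication, and RMSD."""

import math

import numpy as np
import pytest

from movetype import (
    Atom,
    Conformer,
    Molecule,
    PotentialModel,
    SamplerParams,
    deduplicate,
    extract_binding_site,
    ligand_rmsd,
    make_toy_system,
    sample_conformers,
    sample_poses,
)
from movetype.potential import configuration_energy
from movetype.system import set_torsions

from conftest import single_atom_guest

FAST = SamplerParams(n_mc_steps=60, n_rotations=4, max_poses=10)


def triangle_conformer(shift=(0.0, 0.0, 0.0), energy=0.0):
    mol = triangle_conformer.mol
    return Conformer(mol, mol.positions + np.asarray(shift), energy)


triangle_conformer.mol = Molecule(
    [
        Atom("C", (0.0, 0.0, 0.0), atom_id=0),
        Atom("C", (1.0, 0.0, 0.0), atom_id=1),
        Atom("C", (0.0, 1.0, 0.0), atom_id=2),
    ],
    [],
    name="triangle",
)


class TestLigandRmsd:
    def test_identical_conformers_zero(self):
        a = triangle_conformer()
        assert ligand_rmsd(a, a) == 0.0

    def test_rigid_motion_removed_by_superposition(self):
        from scipy.spatial.transform import Rotation

        a = triangle_conformer()
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.8])
        b = Conformer(a.molecule, rot.apply(a.positions) + [4.0, -2.0, 1.0])
        assert ligand_rmsd(a, b, superpose=True) == pytest.approx(0.0, abs=1e-9)
        assert ligand_rmsd(a, b, superpose=False) > 1.0

    def test_hand_computed_three_point_value(self):
        # per-atom displacements (0,0,1), (0,0,1), (0,0,3):
        # rmsd = sqrt((1+1+9)/3) = 1.914854
        a = triangle_conformer()
        pos = a.positions.copy()
        pos[:, 2] += [1.0, 1.0, 3.0]
        b = Conformer(a.molecule, pos)
        assert ligand_rmsd(a, b) == pytest.approx(1.914854, abs=1e-6)

    def test_symmetry(self):
        a, b = triangle_conformer(), triangle_conformer(shift=(0.5, 0.2, -0.3))
        assert ligand_rmsd(a, b) == pytest.approx(ligand_rmsd(b, a))

    def test_atom_mismatch_is_error(self):
        a = triangle_conformer()
        other = Molecule([Atom("N", (0, 0, 0), atom_id=0)], [], name="n1")
        with pytest.raises(ValueError):
            ligand_rmsd(a, Conformer(other, other.positions))


class TestDeduplicate:
    def test_five_copies_collapse_to_one(self):
        items = [triangle_conformer(energy=float(i)) for i in range(5)]
        assert len(deduplicate(items, 0.3)) == 1

    def test_all_distant_items_retained(self):
        items = [
            triangle_conformer(shift=(5.0 * i, 0, 0), energy=float(i)) for i in range(4)
        ]
        assert len(deduplicate(items, 0.3, rmsd=lambda x, y: ligand_rmsd(x, y))) == 4

    def test_greedy_maximal_selection_on_mixed_fixture(self):
        # six conformers at staggered offsets; the kept set must be a
        # best-energy-first maximal packing at the threshold
        rmsd = lambda x, y: ligand_rmsd(x, y)  # receptor frame
        items = [
            triangle_conformer(shift=(0.0, 0, 0), energy=-3.0),
            triangle_conformer(shift=(0.4, 0, 0), energy=-2.5),
            triangle_conformer(shift=(1.4, 0, 0), energy=-2.0),
            triangle_conformer(shift=(1.5, 0, 0), energy=-4.0),  # best overall
            triangle_conformer(shift=(9.0, 0, 0), energy=1.0),
            triangle_conformer(shift=(9.2, 0, 0), energy=0.5),
        ]
        kept = deduplicate(items, 1.0, rmsd=rmsd)
        energies = sorted(c.internal_energy for c in kept)
        assert energies == [-4.0, -3.0, 0.5]
        # exhaustive check: pairwise separation and maximality
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert rmsd(a, b) >= 1.0
        for item in items:
            if not any(item is k for k in kept):
                assert any(
                    rmsd(item, k) < 1.0 and k.internal_energy <= item.internal_energy
                    for k in kept
                )

    def test_idempotent(self):
        items = [triangle_conformer(shift=(0.4 * i, 0, 0), energy=float(i)) for i in range(6)]
        once = deduplicate(items, 1.0, rmsd=lambda x, y: ligand_rmsd(x, y))
        twice = deduplicate(once, 1.0, rmsd=lambda x, y: ligand_rmsd(x, y))
        assert once == twice


class TestSampleConformers:
    def test_rigid_molecule_gives_single_conformer(self):
        _, mol = make_toy_system("pair", seed=0)
        ens = sample_conformers(mol, FAST, seed=3)
        assert ens.n_distinct == 1

    def test_deterministic_per_seed(self):
        _, mol = make_toy_system("chain-4", seed=1)
        a = sample_conformers(mol, FAST, seed=9)
        b = sample_conformers(mol, FAST, seed=9)
        assert a.n_distinct == b.n_distinct
        for ca, cb in zip(a.conformers, b.conformers):
            np.testing.assert_array_equal(ca.positions, cb.positions)
            assert ca.internal_energy == cb.internal_energy

    def test_energies_sorted(self):
        _, mol = make_toy_system("chain-5", seed=1)
        ens = sample_conformers(mol, FAST, seed=2)
        energies = [c.internal_energy for c in ens.conformers]
        assert energies == sorted(energies)

    def test_butane_like_minima_match_torsion_scan(self):
        # exhaustive 1-degree torsion scan as the oracle for the single
        # rotatable bond: anti plus the two gauche wells
        # solvation off: the surface-area term is intentionally coarse and
        # would litter the 1-degree scan with spurious shallow minima
        _, mol = make_toy_system("chain-4", seed=1)
        model = PotentialModel(solvation_rule=lambda c: 0.0)
        angles = np.radians(np.arange(0.0, 360.0, 1.0))
        prof = np.array(
            [
                configuration_energy(Conformer(mol, set_torsions(mol, mol.positions, [t])), model)
                for t in angles
            ]
        )
        is_min = (prof < np.roll(prof, 1)) & (prof <= np.roll(prof, -1))
        scan_minima = np.sort(prof[is_min])
        assert is_min.sum() == 3
        ens = sample_conformers(mol, SamplerParams(n_mc_steps=120), seed=4, model=model)
        assert ens.n_distinct == 3
        sampled = np.sort([c.internal_energy for c in ens.conformers])
        np.testing.assert_allclose(sampled, scan_minima, atol=0.05)


class TestSamplePoses:
    def test_deterministic_per_seed(self, ring_system):
        protein, guest = ring_system
        ens = sample_conformers(guest, FAST, seed=1)
        site = extract_binding_site(protein, center=(0, 0, 0), radius=4.5)
        a = sample_poses(protein, ens, site, FAST, seed=5)
        b = sample_poses(protein, ens, site, FAST, seed=5)
        assert len(a) == len(b)
        for pa, pb in zip(a.poses, b.poses):
            np.testing.assert_array_equal(
                pa.ligand_conformer.positions, pb.ligand_conformer.positions
            )

    def test_poses_ranked_and_clash_free(self, ring_system):
        protein, guest = ring_system
        ens = sample_conformers(guest, FAST, seed=1)
        site = extract_binding_site(protein, center=(0, 0, 0), radius=4.5)
        poses = sample_poses(protein, ens, site, FAST, seed=5)
        assert len(poses) >= 1
        energies = [p.interaction_energy for p in poses.poses]
        assert energies == sorted(energies)
        for p in poses.poses:
            assert p.min_protein_distance() >= FAST.hard_clash - 1e-6

    def test_single_atom_guest_recovers_pocket_center(self, ring_system):
        protein, _ = ring_system
        mol = single_atom_guest()
        ens = sample_conformers(mol, FAST, seed=0)
        site = extract_binding_site(protein, center=(0, 0, 0), radius=4.5)
        poses = sample_poses(protein, ens, site, FAST, seed=1)
        best = poses.poses[0].ligand_conformer.positions[0]
        assert np.linalg.norm(best) <= 0.5  # ring centroid is the global minimum

    def test_too_small_site_warns_and_returns_empty(self):
        protein, _ = make_toy_system("host-guest-ring", seed=1, ring_radius=1.0, n_pocket=6)
        _, guest = make_toy_system("chain-4", seed=1)
        ens = sample_conformers(guest, FAST, seed=0)
        site = extract_binding_site(protein, center=(0, 0, 0), radius=1.0)
        with pytest.warns(UserWarning, match="no clash-free pose"):
            poses = sample_poses(protein, ens, site, FAST, seed=0)
        assert len(poses) == 0

    def test_global_minimum_recovery_across_seeds(self, ring_system):
        # exhaustive 0.25 A grid oracle for the one-atom guest
        from movetype.potential import PairTable

        protein, _ = ring_system
        mol = single_atom_guest()
        model = PotentialModel()
        table = PairTable(mol.atoms, protein.atoms, model)
        tpos = protein.positions
        ax = np.arange(-4.5, 4.51, 0.25)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= 4.5]
        energies = []
        for p in pts:
            d = np.linalg.norm(tpos - p, axis=1)
            if d.min() < FAST.hard_clash:
                energies.append(np.inf)
            else:
                energies.append(table.energy(p[None, :], tpos))
        oracle_best = pts[int(np.argmin(energies))]
        ens = sample_conformers(mol, FAST, seed=0)
        site = extract_binding_site(protein, center=(0, 0, 0), radius=4.5)
        hits = 0
        for seed in range(20):
            poses = sample_poses(protein, ens, site, FAST, seed=seed)
            if len(poses) and np.linalg.norm(
                poses.poses[0].ligand_conformer.positions[0] - oracle_best
            ) <= 0.5:
                hits += 1
        assert hits >= 19  # >= 95% of 20 seeds
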