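"""Shared fixtures: toy molecules, text-format fixtures, potential models."""

from __future__ import annotations

import math

import numpy as np
import pytest

from movetype import (
    Atom,
    Conformer,
    Molecule,
    MTSamplingConfig,
    PotentialModel,
    ProteinTarget,
    ThermoContext,
    make_toy_system,
)


@pytest.fixture
def thermo() -> ThermoContext:
    return ThermoContext()


@pytest.fixture
def model() -> PotentialModel:
    return PotentialModel()


@pytest.fixture
def small_config() -> MTSamplingConfig:
    """Coarse sampling config small enough for joint brute-force enumeration."""
    return MTSamplingConfig(
        distance_range=0.2, step=0.005, displacement_unit=0.05, n_states_per_axis=2
    )


def zero_potential() -> PotentialModel:
    return PotentialModel(pair_energy_rule=lambda a, b, r: 0.0,
                          pair_force_rule=lambda a, b, r: 0.0)


def harmonic_potential(k: float, r0: float) -> PotentialModel:
    """Test potential k (r - r0)^2 / 2 with its analytic force."""
    return PotentialModel(
        pair_energy_rule=lambda a, b, r: 0.5 * k * (r - r0) ** 2,
        pair_force_rule=lambda a, b, r: -k * (r - r0),
    )


@pytest.fixture
def ring_system():
    return make_toy_system("host-guest-ring", seed=1)


@pytest.fixture
def pair_system():
    return make_toy_system("pair", seed=0)


def single_atom_guest() -> Molecule:
    """A one-atom ligand (the smallest dockable guest)."""
    return Molecule([Atom("C", (0.0, 0.0, 8.0), atom_id=0)], [], name="point-guest")


def chain_sdf_text(n: int, name: str = "chain") -> str:
    """V2000 molblock of an n-carbon zigzag chain (no hydrogens)."""
    half = math.radians(111.0) / 2
    dx, dz = 1.53 * math.sin(half), 1.53 * math.cos(half)
    pos = np.zeros((n, 3))
    for i in range(1, n):
        pos[i] = pos[i - 1] + [dx, 0.0, dz if i % 2 else -dz]
    lines = [name, "  movetype", "", f"{n:3d}{n - 1:3d}  0  0  0  0  0  0  0  0999 V2000"]
    for p in pos:
        lines.append(f"{p[0]:10.4f}{p[1]:10.4f}{p[2]:10.4f} C   0  0")
    for i in range(1, n):
        lines.append(f"{i:3d}{i + 1:3d}  1  0")
    lines += ["M  END", "$$$$", ""]
    return "\n".join(lines)


def _pdb_line(serial, name, resname, chain, resseq, x, y, z, element, altloc=" ") -> str:
    return (
        f"ATOM  {serial:>5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def three_residue_pdb() -> str:
    """A synthetic 3-residue glycine stretch plus one water."""
    rows = []
    serial = 1
    for resseq in range(1, 4):
        x0 = 3.8 * (resseq - 1)
        for name, dx in (("N", 0.0), ("CA", 1.2), ("C", 2.4), ("O", 3.0)):
            el = name[0]
            rows.append(_pdb_line(serial, name, "GLY", "A", resseq, x0 + dx, 0.0, 0.0, el))
            serial += 1
    rows.append(_pdb_line(serial, "O", "HOH", "A", 9, 30.0, 30.0, 30.0, "O"))
    return "\n".join(rows) + "\nEND\n"


def altloc_pdb() -> str:
    """One residue whose CA has A/B alternate locations."""
    rows = [
        _pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        _pdb_line(2, "CA", "ALA", "A", 1, 1.2, 0.0, 0.0, "C", altloc="A"),
        _pdb_line(3, "CA", "ALA", "A", 1, 1.3, 0.1, 0.0, "C", altloc="B"),
        _pdb_line(4, "C", "ALA", "A", 1, 2.4, 0.0, 0.0, "C"),
    ]
    return "\n".join(rows) + "\nEND\n"


def pocket_with_two_residues() -> ProteinTarget:
    """One residue 2.5 A from the origin-centered probe, another at 9 A."""
    atoms = [
        Atom("C", (2.5, 0.0, 0.0), atom_id=0, residue_tag="ALA:A:1"),
        Atom("C", (9.0, 0.0, 0.0), atom_id=1, residue_tag="GLY:A:2"),
    ]
    return ProteinTarget(atoms, name="two-residue-pocket")


def probe_conformer() -> Conformer:
    mol = Molecule([Atom("C", (0.0, 0.0, 0.0), atom_id=0)], [], name="probe")
    return Conformer(mol, mol.positions)
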