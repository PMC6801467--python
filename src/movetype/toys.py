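"""Synthetic toy systems: tiny hosts and guests every algorithm can run on.

Three registered families:

``pair``
    one protein pseudo-atom plus a one-atom ligand 3.5 A away — the
    smallest system with a nontrivial interaction.
``chain-N``
    an N-carbon zigzag chain ligand (N-3 rotatable bonds) with a small
    fixed 3-atom "protein" cluster far away.
``host-guest-ring``
    a ring of pocket pseudo-atoms (default 8, one residue each) of
    configurable radius with a 2-6 atom guest; the ring center is an
    attractive well at the default Lennard-Jones parameters, so binding
    is favorable by construction.

Generation is a pure function of (spec, seed): identical arguments give
bit-identical coordinates.
"""

from __future__ import annotations

import math

import numpy as np

from .system import Atom, Bond, Molecule, ProteinTarget

__all__ = ["make_toy_system", "TOY_FAMILIES"]

TOY_FAMILIES = ("pair", "chain-N", "host-guest-ring")

_CC_BOND = 1.53  # A
_CC_ANGLE = math.radians(111.0)


def _chain_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Zigzag carbon chain in the xz-plane with a tiny deterministic jitter."""
    pos = np.zeros((n, 3))
    half = _CC_ANGLE / 2.0
    dx, dz = _CC_BOND * math.sin(half), _CC_BOND * math.cos(half)
    for i in range(1, n):
        pos[i] = pos[i - 1] + np.array([dx, 0.0, dz if i % 2 else -dz])
    pos += rng.normal(scale=0.01, size=pos.shape)
    return pos - pos.mean(axis=0)


def _chain_molecule(n: int, rng: np.random.Generator, name: str) -> Molecule:
    pos = _chain_positions(n, rng)
    atoms = [Atom("C", pos[i], atom_id=i) for i in range(n)]
    bonds = [Bond(i, i + 1) for i in range(n - 1)]
    return Molecule(atoms, bonds, name=name)


def make_toy_system(spec: str, seed: int, **options) -> tuple[ProteinTarget, Molecule]:
    """Build one registered toy family; reproducible for a fixed seed.

    Options for ``host-guest-ring``: ``n_pocket`` (6-12, default 8),
    ``ring_radius`` (A, default 4.0), ``guest_atoms`` (2-6, default 2).
    """
    rng = np.random.default_rng(seed)
    if spec == "pair":
        protein = ProteinTarget(
            [Atom("C", (0.0, 0.0, 0.0), atom_id=0, residue_tag="PCK:A:1")],
            name="pair-host",
        )
        ligand = Molecule([Atom("C", (3.5, 0.0, 0.0), atom_id=0)], [], name="pair-guest")
        return protein, ligand
    if spec.startswith("chain-"):
        try:
            n = int(spec.split("-", 1)[1])
        except ValueError:
            raise ValueError(f"bad chain spec {spec!r}") from None
        if n < 2:
            raise ValueError("chain-N needs N >= 2")
        ligand = _chain_molecule(n, rng, spec)
        anchor = np.array([25.0, 0.0, 0.0])
        protein = ProteinTarget(
            [
                Atom("C", anchor + off, atom_id=k, residue_tag=f"PCK:A:{k + 1}")
                for k, off in enumerate(
                    [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (0.75, 1.3, 0.0)]
                )
            ],
            name="chain-host",
        )
        return protein, ligand
    if spec == "host-guest-ring":
        n_pocket = int(options.get("n_pocket", 8))
        if not 6 <= n_pocket <= 12:
            raise ValueError("n_pocket must be in 6..12")
        radius = float(options.get("ring_radius", 4.0))
        n_guest = int(options.get("guest_atoms", 2))
        if not 2 <= n_guest <= 6:
            raise ValueError("guest_atoms must be in 2..6")
        ring = []
        for k in range(n_pocket):
            ang = 2 * math.pi * k / n_pocket
            ring.append(
                Atom(
                    "C",
                    (radius * math.cos(ang), radius * math.sin(ang), 0.0),
                    atom_id=k,
                    residue_tag=f"PCK:A:{k + 1}",
                )
            )
        protein = ProteinTarget(ring, name="ring-host")
        guest = _chain_molecule(n_guest, rng, "ring-guest")
        # start the guest outside the pocket; samplers move it in
        guest = Molecule(
            [
                Atom("C", a.position + np.array([0.0, 0.0, 8.0]), atom_id=a.atom_id)
                for a in guest.atoms
            ],
            guest.bonds,
            name=guest.name,
        )
        return protein, guest
    raise ValueError(f"unknown toy family {spec!r}; known: {TOY_FAMILIES}")
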