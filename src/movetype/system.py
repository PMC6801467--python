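"""Molecular data model: atoms, molecules, conformers, targets, poses.

Coordinates are Cartesian Angstrom throughout; energies are kcal/mol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .elements import vdw_params

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Conformer",
    "ProteinTarget",
    "BindingSite",
    "ComplexPose",
    "MoleculeError",
]


class MoleculeError(ValueError):
    """Malformed molecular input (bad records, empty structures, ...)."""


@dataclass
class Atom:
    """One atom: element, position (A), partial charge (e), LJ parameters.

    ``vdw_params`` is ``(epsilon kcal/mol, r_min A)`` where ``r_min`` is the
    homonuclear pair equilibrium distance; pairs combine with geometric
    epsilon and arithmetic r_min.
    """

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_params: Optional[tuple[float, float]] = None
    atom_id: int = 0
    residue_tag: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise MoleculeError(f"atom {self.atom_id}: position must be a finite 3-vector")
        if self.vdw_params is None:
            self.vdw_params = vdw_params(self.element)
        eps, rmin = self.vdw_params
        if eps < 0 or rmin <= 0:
            raise MoleculeError(f"atom {self.atom_id}: invalid vdW parameters {self.vdw_params}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int = 1

    def as_tuple(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class Molecule:
    """A small molecule: ordered atoms, explicit bonds, rotatable bonds.

    A rotatable bond is an acyclic single bond between two heavy atoms, each
    bearing at least one further heavy neighbor (terminal bonds and ring
    bonds are not rotatable). Its movable-atom set is the connected
    component on the ``j`` side once the bond is removed, so rotating the
    bond moves exactly that set.
    """

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    name: str = "ligand"
    rotatable_bonds: list[tuple[Bond, frozenset[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise MoleculeError(f"bond {b} references invalid atom ids (n={n})")
        if not self.rotatable_bonds:
            self.rotatable_bonds = self.detect_rotatable_bonds()

    # -- graph helpers -------------------------------------------------
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def heavy_degree(self, idx: int) -> int:
        return sum(
            1
            for b in self.bonds
            if idx in (b.i, b.j) and self.atoms[b.j if b.i == idx else b.i].is_heavy
        )

    def detect_rotatable_bonds(self) -> list[tuple[Bond, frozenset[int]]]:
        g = self.graph()
        ring_edges = set()
        for cycle in nx.cycle_basis(g):
            m = len(cycle)
            for k in range(m):
                e = frozenset((cycle[k], cycle[(k + 1) % m]))
                ring_edges.add(e)
        out: list[tuple[Bond, frozenset[int]]] = []
        for b in self.bonds:
            if b.order != 1 or frozenset((b.i, b.j)) in ring_edges:
                continue
            ai, aj = self.atoms[b.i], self.atoms[b.j]
            if not (ai.is_heavy and aj.is_heavy):
                continue
            if self.heavy_degree(b.i) < 2 or self.heavy_degree(b.j) < 2:
                continue  # terminal heavy-heavy bond: nothing to rotate
            h = g.copy()
            h.remove_edge(b.i, b.j)
            movable = frozenset(nx.node_connected_component(h, b.j))
            out.append((b, movable))
        return out

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def exclusion_sets(self) -> tuple[set[frozenset], set[frozenset]]:
        """(excluded 1-2/1-3 pairs, 1-4 pairs) by bond-graph distance."""
        g = self.graph()
        excluded: set[frozenset] = set()
        pairs14: set[frozenset] = set()
        for i, dists in nx.all_pairs_shortest_path_length(g, cutoff=3):
            for j, d in dists.items():
                if j <= i:
                    continue
                if d in (1, 2):
                    excluded.add(frozenset((i, j)))
                elif d == 3:
                    pairs14.add(frozenset((i, j)))
        return excluded, pairs14


@dataclass
class Conformer:
    """One 3-D geometry of a molecule with its internal (solution-phase) energy."""

    molecule: Molecule
    positions: np.ndarray
    internal_energy: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.molecule.atoms), 3):
            raise MoleculeError("conformer positions must match molecule atom count")
        if not np.isfinite(self.internal_energy):
            raise MoleculeError("conformer internal energy must be finite")

    def atoms_at(self) -> list[Atom]:
        """Atoms of the molecule carried at this conformer's coordinates."""
        return [
            dataclasses.replace(a, position=self.positions[i])
            for i, a in enumerate(self.molecule.atoms)
        ]

    def copy(self) -> "Conformer":
        return Conformer(self.molecule, self.positions.copy(), self.internal_energy)


@dataclass
class ProteinTarget:
    """A (rigid) protein: atoms with residue tags plus a residue index."""

    atoms: list[Atom]
    name: str = "target"

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.residue_tag is None:
                raise MoleculeError(f"protein atom {a.atom_id} lacks a residue tag")

    @property
    def residues(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_tag, []).append(i)
        return out

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class BindingSite:
    residue_ids: frozenset[str]
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.residue_ids = frozenset(self.residue_ids)
        if self.radius <= 0:
            raise MoleculeError("binding-site radius must be positive")

    def validate_against(self, target: ProteinTarget) -> None:
        missing = self.residue_ids - set(target.residues)
        if missing:
            raise MoleculeError(f"site residues not in target: {sorted(missing)}")


@dataclass
class ComplexPose:
    """One bound-state configuration: a rigid target plus a placed conformer."""

    target: ProteinTarget
    ligand_conformer: Conformer
    pose_id: int = 0
    interaction_energy: float = float("nan")

    def ligand_positions(self) -> np.ndarray:
        return self.ligand_conformer.positions

    def min_protein_distance(self) -> float:
        from scipy.spatial import cKDTree

        tree = cKDTree(self.target.positions)
        d, _ = tree.query(self.ligand_conformer.positions, k=1)
        return float(np.min(d))


def extract_binding_site(
    target: ProteinTarget,
    reference: Optional[Conformer] = None,
    cutoff: float = 3.0,
    center: Optional[Sequence[float]] = None,
    radius: Optional[float] = None,
) -> BindingSite:
    """Residues with any atom within ``cutoff`` of the reference ligand.

    Either a reference :class:`Conformer` (+ ``cutoff``) or an explicit
    ``center`` + ``radius`` sphere must be given. Deterministic.
    """
    from scipy.spatial import cKDTree

    if reference is None and (center is None or radius is None):
        raise ValueError("provide a reference conformer or center+radius")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ppos = target.positions
    if reference is not None:
        tree = cKDTree(reference.positions)
        d, _ = tree.query(ppos, k=1)
        hit = d <= cutoff
        site_center = reference.positions.mean(axis=0)
        spread = float(np.max(np.linalg.norm(reference.positions - site_center, axis=1)))
        site_radius = spread + cutoff
    else:
        c = np.asarray(center, dtype=float)
        hit = np.linalg.norm(ppos - c, axis=1) <= radius
        site_center, site_radius = c, float(radius)
    residue_ids = {target.atoms[i].residue_tag for i in np.nonzero(hit)[0]}
    if not residue_ids:
        raise MoleculeError(
            "no residues found near the reference; try a larger cutoff/radius"
        )
    return BindingSite(frozenset(residue_ids), site_center, site_radius)


def set_torsions(
    molecule: Molecule, base_positions: np.ndarray, angles_rad: Iterable[float]
) -> np.ndarray:
    """Rotate each rotatable bond's movable set to the given torsion offsets.

    ``angles_rad[k]`` is applied as a rotation of rotatable bond ``k``'s
    movable atoms about the bond axis, relative to ``base_positions``.
    """
    from scipy.spatial.transform import Rotation

    pos = np.array(base_positions, dtype=float)
    for (bond, movable), ang in zip(molecule.rotatable_bonds, angles_rad):
        if ang == 0.0:
            continue
        axis_from, axis_to = pos[bond.i], pos[bond.j]
        axis = axis_to - axis_from
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            continue
        rot = Rotation.from_rotvec(axis / nrm * ang)
        idx = np.array(sorted(movable - {bond.j}), dtype=int)
        if idx.size:
            pos[idx] = rot.apply(pos[idx] - axis_to) + axis_to
    return pos
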