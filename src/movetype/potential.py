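"""Pluggable atom-pairwise potential with a documented default.

The default model is Lennard-Jones 12-6 plus Coulomb with a
distance-dependent dielectric eps(r) = 4r, smoothly switched to zero over a
1 A window ending at the 9 A cutoff, a 3-fold cosine torsion term on
rotatable bonds, and a surface-area-proportional implicit-solvation term.
Every piece sits behind a rule on :class:`PotentialModel`, so an alternative
energy model (different functional forms, tabulated torsions, another
solvation scheme) can be swapped in without touching the engine.

Conventions: energies kcal/mol, distances Angstrom; ``pair_force`` is the
magnitude of -dU/dr along the inter-atomic axis, positive = repulsive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

from .elements import PROBE_RADIUS, solvation_sigma
from .system import Atom, ComplexPose, Conformer

__all__ = [
    "ThermoContext",
    "PotentialModel",
    "ClashError",
    "pair_energy",
    "pair_force",
    "configuration_energy",
    "energy_components",
    "solvation_energy",
    "load_potential_config",
]

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)
HARD_OVERLAP = 0.1  # A; closer than this is treated as an invalid geometry


class ClashError(ValueError):
    """Atoms overlap so badly the configuration energy is meaningless."""


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and gas constant; RT in kcal/mol."""

    temperature: float = 298.15
    gas_constant: float = 1.987204e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class PotentialModel:
    """Parameters and pluggable rules of the pairwise energy model.

    ``dielectric`` is either the string ``"distance"`` (eps(r) =
    ``dielectric_factor`` * r) or a constant relative permittivity.
    """

    cutoff: float = 9.0
    switch_width: float = 1.0
    dielectric: Union[str, float] = "distance"
    dielectric_factor: float = 4.0
    coulomb_constant: float = COULOMB_CONSTANT
    scale_14: float = 0.5
    torsion_barrier: float = 1.0
    torsion_periodicity: int = 3
    solvation_rule: Optional[Callable[[Conformer], float]] = None
    vdw_overrides: dict = field(default_factory=dict)
    # custom pair rules replace LJ+Coulomb verbatim inside the cutoff
    # (no switching); the force rule defaults to a central difference of
    # the energy rule when only the latter is given
    pair_energy_rule: Optional[Callable] = None
    pair_force_rule: Optional[Callable] = None

    @property
    def r_on(self) -> float:
        return self.cutoff - self.switch_width

    def combine(self, a: Atom, b: Atom) -> tuple[float, float]:
        """Geometric-epsilon / arithmetic-r_min combination for a pair."""
        ea, ra = self.vdw_overrides.get(a.element.upper(), a.vdw_params)
        eb, rb = self.vdw_overrides.get(b.element.upper(), b.vdw_params)
        return math.sqrt(ea * eb), 0.5 * (ra + rb)

    def torsion_energy(self, angle_rad: float) -> float:
        n = self.torsion_periodicity
        return 0.5 * self.torsion_barrier * (1.0 + math.cos(n * angle_rad))


def _switch(r: float, r_on: float, r_off: float) -> tuple[float, float]:
    """C1 switching function S(r) and dS/dr (CHARMM form)."""
    if r <= r_on:
        return 1.0, 0.0
    if r >= r_off:
        return 0.0, 0.0
    c = (r_off**2 - r_on**2) ** 3
    a = r_off**2 - r * r
    b = r_off**2 + 2 * r * r - 3 * r_on**2
    s = a * a * b / c
    ds = (2 * a * (-2 * r) * b + a * a * (4 * r)) / c
    return s, ds


def _raw_pair(a: Atom, b: Atom, r: float, model: PotentialModel) -> tuple[float, float]:
    """Unswitched (U, dU/dr) of LJ + Coulomb for one pair at distance r."""
    eps, rmin = model.combine(a, b)
    u_lj = du_lj = 0.0
    if eps > 0.0:
        x6 = (rmin / r) ** 6
        u_lj = eps * (x6 * x6 - 2.0 * x6)
        du_lj = eps * (-12.0 * x6 * x6 + 12.0 * x6) / r
    qq = a.partial_charge * b.partial_charge
    u_c = du_c = 0.0
    if qq != 0.0:
        k = model.coulomb_constant * qq
        if model.dielectric == "distance":
            u_c = k / (model.dielectric_factor * r * r)
            du_c = -2.0 * u_c / r
        else:
            u_c = k / (float(model.dielectric) * r)
            du_c = -u_c / r
    return u_lj + u_c, du_lj + du_c


def pair_energy(a: Atom, b: Atom, r: float, model: Optional[PotentialModel] = None) -> float:
    """Switched pair energy (kcal/mol) of two atoms at distance r (A)."""
    model = model or PotentialModel()
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= model.cutoff:
        return 0.0
    if model.pair_energy_rule is not None:
        return float(model.pair_energy_rule(a, b, r))
    u, _ = _raw_pair(a, b, r, model)
    s, _ = _switch(r, model.r_on, model.cutoff)
    return u * s


def pair_force(a: Atom, b: Atom, r: float, model: Optional[PotentialModel] = None) -> float:
    """-d/dr of the switched pair energy; positive pushes the atoms apart."""
    model = model or PotentialModel()
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= model.cutoff:
        return 0.0
    if model.pair_force_rule is not None:
        return float(model.pair_force_rule(a, b, r))
    if model.pair_energy_rule is not None:
        h = 1e-6
        lo = model.pair_energy_rule(a, b, max(r - h, 1e-9))
        hi = model.pair_energy_rule(a, b, r + h)
        return float(-(hi - lo) / (2 * h))
    u, du = _raw_pair(a, b, r, model)
    s, ds = _switch(r, model.r_on, model.cutoff)
    return -(du * s + u * ds)


# ---------------------------------------------------------------------------
# surface area / solvation
# ---------------------------------------------------------------------------

def _sphere_points(n: int = 64) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


_SPHERE = _sphere_points(64)


def accessible_surface_areas(
    positions: np.ndarray, radii: np.ndarray, probe: float = PROBE_RADIUS
) -> np.ndarray:
    """Shrake-Rupley accessible areas (A^2) on raw coordinate arrays."""
    from scipy.spatial import cKDTree

    positions = np.asarray(positions, dtype=float)
    rr = np.asarray(radii, dtype=float) + probe
    tree = cKDTree(positions)
    areas = np.empty(len(positions))
    for i, (p, ri) in enumerate(zip(positions, rr)):
        pts = p + ri * _SPHERE
        nbrs = [j for j in tree.query_ball_point(p, ri + rr.max()) if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            exposed &= np.linalg.norm(pts - positions[j], axis=1) > rr[j]
            if not exposed.any():
                break
        areas[i] = 4.0 * math.pi * ri * ri * exposed.mean()
    return areas


def solvation_energy(conf: Conformer, model: Optional[PotentialModel] = None) -> float:
    """Surface-area-proportional implicit solvation term (kcal/mol)."""
    model = model or PotentialModel()
    if model.solvation_rule is not None:
        return float(model.solvation_rule(conf))
    atoms = conf.molecule.atoms
    radii = np.array([a.vdw_params[1] / 2.0 for a in atoms])
    areas = accessible_surface_areas(conf.positions, radii)
    sig = np.array([solvation_sigma(a.element) for a in atoms])
    return float(np.dot(sig, areas))


# ---------------------------------------------------------------------------
# whole-configuration energies
# ---------------------------------------------------------------------------

def _torsion_angle(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(float(np.dot(m, n2)), float(np.dot(n1, n2)))


def _torsion_term(conf: Conformer, model: PotentialModel) -> float:
    """One cosine term per rotatable bond, using one bracketing atom pair."""
    total = 0.0
    g = conf.molecule.graph()
    for bond, movable in conf.molecule.rotatable_bonds:
        i, j = bond.i, bond.j
        prev = [k for k in g.neighbors(i) if k != j and conf.molecule.atoms[k].is_heavy]
        nxt = [k for k in g.neighbors(j) if k != i and conf.molecule.atoms[k].is_heavy]
        if not prev or not nxt:
            continue
        ang = _torsion_angle(
            conf.positions[min(prev)], conf.positions[i], conf.positions[j],
            conf.positions[min(nxt)],
        )
        total += model.torsion_energy(ang)
    return total


def _intra_nonbonded(conf: Conformer, model: PotentialModel) -> float:
    mol = conf.molecule
    excluded, pairs14 = mol.exclusion_sets()
    pos = conf.positions
    total = 0.0
    n = len(mol.atoms)
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((i, j))
            if key in excluded:
                continue
            r = float(np.linalg.norm(pos[i] - pos[j]))
            if r < HARD_OVERLAP:
                raise ClashError(f"atoms {i},{j} overlap at r={r:.3f} A")
            if r >= model.cutoff:
                continue
            w = model.scale_14 if key in pairs14 else 1.0
            total += w * pair_energy(mol.atoms[i], mol.atoms[j], r, model)
    return total


def _cross_energy(pose: ComplexPose, model: PotentialModel) -> float:
    """Protein-ligand cross nonbonded energy (no exclusions across molecules)."""
    from scipy.spatial import cKDTree

    lig = pose.ligand_conformer
    latoms = lig.atoms_at()
    ppos = pose.target.positions
    tree = cKDTree(ppos)
    total = 0.0
    for la in latoms:
        for j in tree.query_ball_point(la.position, model.cutoff):
            pa = pose.target.atoms[j]
            r = float(np.linalg.norm(la.position - ppos[j]))
            if r < HARD_OVERLAP:
                raise ClashError(
                    f"ligand atom {la.atom_id} overlaps protein atom {pa.atom_id}"
                )
            total += pair_energy(la, pa, r, model)
    return total


class PairTable:
    """Vectorized pair parameters of two atom groups for fast cross sums."""

    def __init__(self, atoms_a, atoms_b, model: PotentialModel):
        self.atoms_a, self.atoms_b = list(atoms_a), list(atoms_b)
        combos = [[model.combine(a, b) for b in atoms_b] for a in atoms_a]
        self.eps = np.array([[c[0] for c in row] for row in combos])
        self.rmin = np.array([[c[1] for c in row] for row in combos])
        qa = np.array([a.partial_charge for a in atoms_a])
        qb = np.array([b.partial_charge for b in atoms_b])
        self.qq = np.outer(qa, qb)
        self.model = model

    def energy(self, pos_a: np.ndarray, pos_b: np.ndarray) -> float:
        """Total switched pair energy between the groups; ClashError on overlap."""
        m = self.model
        d = pos_a[:, None, :] - pos_b[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=-1))
        if np.any(r < HARD_OVERLAP):
            raise ClashError("overlapping atoms in cross-energy evaluation")
        if m.pair_energy_rule is not None:
            return float(
                sum(
                    pair_energy(a, b, float(r[i, j]), m)
                    for i, a in enumerate(self.atoms_a)
                    for j, b in enumerate(self.atoms_b)
                    if r[i, j] < m.cutoff
                )
            )
        with np.errstate(over="ignore"):
            x6 = (self.rmin / r) ** 6
            u = self.eps * (x6 * x6 - 2.0 * x6)
            if m.dielectric == "distance":
                u += m.coulomb_constant * self.qq / (m.dielectric_factor * r * r)
            else:
                u += m.coulomb_constant * self.qq / (float(m.dielectric) * r)
        r_on, r_off = m.r_on, m.cutoff
        a = r_off**2 - r * r
        b = r_off**2 + 2 * r * r - 3 * r_on**2
        s = np.where(
            r >= r_off, 0.0, np.where(r <= r_on, 1.0, a * a * b / (r_off**2 - r_on**2) ** 3)
        )
        return float(np.sum(u * s))


def energy_components(
    obj: Union[Conformer, ComplexPose], model: Optional[PotentialModel] = None
) -> dict:
    """Energy breakdown; keys: intra, torsion, solvation, cross, total.

    For a free :class:`Conformer` the cross term is zero. The protein's own
    internal energy is not evaluated: the target is rigid, so it is the same
    additive constant in every pose and cancels in all comparisons.
    """
    model = model or PotentialModel()
    if isinstance(obj, ComplexPose):
        conf = obj.ligand_conformer
        cross = _cross_energy(obj, model)
    else:
        conf, cross = obj, 0.0
    intra = _intra_nonbonded(conf, model)
    tors = _torsion_term(conf, model)
    solv = solvation_energy(conf, model)
    return {
        "intra": intra,
        "torsion": tors,
        "solvation": solv,
        "cross": cross,
        "total": intra + tors + solv + cross,
    }


def configuration_energy(
    obj: Union[Conformer, ComplexPose], model: Optional[PotentialModel] = None
) -> float:
    """Total configuration energy (kcal/mol): nonbonded + torsion + solvation."""
    return energy_components(obj, model)["total"]


def load_potential_config(path) -> PotentialModel:
    """Build a model from a key-value YAML/JSON-style config file.

    Recognized keys: cutoff, switch_width, dielectric, dielectric_factor,
    scale_14, torsion_barrier, torsion_periodicity, and an ``elements``
    mapping ``symbol -> [epsilon, r_min]`` of vdW overrides.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    overrides = {
        str(k).upper(): (float(v[0]), float(v[1]))
        for k, v in (raw.pop("elements", {}) or {}).items()
    }
    known = {
        k: raw[k]
        for k in (
            "cutoff", "switch_width", "dielectric", "dielectric_factor",
            "scale_14", "torsion_barrier", "torsion_periodicity",
        )
        if k in raw
    }
    return replace(PotentialModel(), vdw_overrides=overrides, **known)
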