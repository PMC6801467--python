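"""Free-state conformer and bound-state pose ensembles.

Conformers come from Metropolis Monte Carlo over rotatable-bond torsions
with local torsion-space minimization of accepted samples; poses from an
anchor grid over the binding-site sphere with randomized rigid rotations,
clash screening, and rigid-body refinement of the survivors. Both samplers
are deterministic per seed and deduplicate by heavy-atom RMSD (optimal
superposition for free conformers, receptor-frame for poses).

These are documented stand-ins wired to the same contracts the free-energy
assembly needs: a ranked set of distinct low-energy configurations. The
partition-function engine downstream is sampler-agnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .potential import ClashError, PairTable, PotentialModel, configuration_energy
from .system import BindingSite, ComplexPose, Conformer, Molecule, ProteinTarget, set_torsions

__all__ = [
    "SamplerParams",
    "ConformerEnsemble",
    "PoseEnsemble",
    "sample_conformers",
    "sample_poses",
    "deduplicate",
    "ligand_rmsd",
]


@dataclass(frozen=True)
class SamplerParams:
    """Knobs of both samplers (config keys ``sampler.*``)."""

    n_mc_steps: int = 150
    kT: float = 0.593  # Metropolis temperature, kcal/mol
    max_min_steps: int = 50
    dedup_rmsd_conformer: float = 0.3
    dedup_rmsd_pose: float = 1.0
    grid_spacing: float = 1.0
    n_rotations: int = 24
    hard_clash: float = 1.2  # A, minimum allowed ligand-protein distance
    max_conformers_docked: int = 5
    max_poses: int = 50


@dataclass
class ConformerEnsemble:
    conformers: list[Conformer]
    seed: int
    n_requested: int
    dedup_rmsd: float

    def __post_init__(self) -> None:
        self.conformers.sort(key=lambda c: c.internal_energy)

    @property
    def n_distinct(self) -> int:
        return len(self.conformers)


@dataclass
class PoseEnsemble:
    poses: list[ComplexPose]
    seed: int
    dedup_rmsd: float

    def __post_init__(self) -> None:
        self.poses.sort(key=lambda p: p.interaction_energy)

    def __len__(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# RMSD and deduplication
# ---------------------------------------------------------------------------

def ligand_rmsd(a: Conformer, b: Conformer, superpose: bool = False) -> float:
    """Heavy-atom RMSD between two conformers of the same molecule.

    With ``superpose`` the optimal rigid (Kabsch) superposition is applied
    first; without it the RMSD is taken in the common (receptor) frame.
    """
    if a.molecule is not b.molecule and [x.element for x in a.molecule.atoms] != [
        x.element for x in b.molecule.atoms
    ]:
        raise ValueError("conformers must share a molecule")
    idx = a.molecule.heavy_indices()
    pa, pb = a.positions[idx], b.positions[idx]
    if superpose and len(idx) > 1:
        ca, cb = pa.mean(axis=0), pb.mean(axis=0)
        rot, _ = Rotation.align_vectors(pa - ca, pb - cb)
        pb = rot.apply(pb - cb) + ca
    elif superpose:
        pb = pb - pb.mean(axis=0) + pa.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def deduplicate(items: Sequence, rmsd_threshold: float, key: Optional[Callable] = None,
                rmsd: Optional[Callable] = None) -> list:
    """Greedy best-energy-first selection keeping members >= threshold apart.

    Works on conformers (energy key = internal energy, superposed RMSD) and
    poses (interaction energy, receptor-frame RMSD) alike; idempotent.
    """
    if rmsd_threshold <= 0:
        raise ValueError("rmsd_threshold must be positive")
    items = list(items)
    if key is None:
        key = lambda x: x.internal_energy if isinstance(x, Conformer) else x.interaction_energy
    if rmsd is None:
        rmsd = lambda x, y: (
            ligand_rmsd(x, y, superpose=True)
            if isinstance(x, Conformer)
            else ligand_rmsd(x.ligand_conformer, y.ligand_conformer, superpose=False)
        )
    kept: list = []
    for item in sorted(items, key=key):
        if all(rmsd(item, other) >= rmsd_threshold for other in kept):
            kept.append(item)
    return kept


# ---------------------------------------------------------------------------
# free-state conformers
# ---------------------------------------------------------------------------

def _torsion_energy_fn(mol: Molecule, base: np.ndarray, model: PotentialModel):
    def fn(angles: np.ndarray) -> float:
        try:
            pos = set_torsions(mol, base, angles)
            return configuration_energy(Conformer(mol, pos), model)
        except ClashError:
            return 1e6
    return fn


def sample_conformers(
    mol: Molecule,
    params: Optional[SamplerParams] = None,
    seed: int = 0,
    model: Optional[PotentialModel] = None,
) -> ConformerEnsemble:
    """Metropolis Monte Carlo over torsions with local minimization.

    Each accepted Monte Carlo sample is relaxed in torsion space (bond
    lengths and angles rigid, <= ``max_min_steps`` minimizer iterations),
    scored with the full configuration energy (nonbonded + torsion +
    solvation), and the ensemble is deduplicated by superposed heavy-atom
    RMSD. A rigid molecule yields its single minimized input conformer.
    """
    params = params or SamplerParams()
    model = model or PotentialModel()
    rng = np.random.default_rng(seed)
    base = mol.positions
    k = len(mol.rotatable_bonds)
    if k == 0:
        conf = Conformer(mol, base.copy())
        conf.internal_energy = configuration_energy(conf, model)
        return ConformerEnsemble([conf], seed, 1, params.dedup_rmsd_conformer)
    energy = _torsion_energy_fn(mol, base, model)
    current = np.zeros(k)
    e_cur = energy(current)
    candidates: list[np.ndarray] = [current.copy()]
    for _ in range(params.n_mc_steps):
        proposal = current.copy()
        j = int(rng.integers(k))
        proposal[j] = (proposal[j] + rng.uniform(-math.pi, math.pi)) % (2 * math.pi)
        e_new = energy(proposal)
        if e_new <= e_cur or rng.random() < math.exp(-(e_new - e_cur) / params.kT):
            current, e_cur = proposal, e_new
            candidates.append(current.copy())
    conformers: list[Conformer] = []
    for angles in candidates:
        res = minimize(
            energy, angles, method="Nelder-Mead",
            options={"maxiter": params.max_min_steps, "xatol": 1e-3, "fatol": 1e-6},
        )
        pos = set_torsions(mol, base, res.x)
        conformers.append(Conformer(mol, pos, float(res.fun)))
    kept = deduplicate(conformers, params.dedup_rmsd_conformer)
    return ConformerEnsemble(kept, seed, len(candidates), params.dedup_rmsd_conformer)


# ---------------------------------------------------------------------------
# bound-state poses
# ---------------------------------------------------------------------------

def _anchor_grid(site: BindingSite, spacing: float) -> np.ndarray:
    n = int(math.floor(site.radius / spacing))
    ax = spacing * np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= site.radius]
    return pts + site.center


def _min_dist(target_pos: np.ndarray, lig_pos: np.ndarray) -> float:
    d = target_pos[:, None, :] - lig_pos[None, :, :]
    return float(np.sqrt(np.min(np.sum(d * d, axis=-1))))


def sample_poses(
    target: ProteinTarget,
    ensemble: ConformerEnsemble,
    site: BindingSite,
    params: Optional[SamplerParams] = None,
    seed: int = 0,
    model: Optional[PotentialModel] = None,
) -> PoseEnsemble:
    """Anchor-grid rigid docking of the conformer ensemble into the site.

    Ligand centers are placed on a grid over the site sphere; at each anchor
    every (top-ranked) conformer is tried in ``n_rotations`` random rigid
    orientations, clash-filtered, and the best orientation per anchor is
    refined with a rigid-body (6-dof) local minimization of the
    protein-ligand interaction energy. The protein stays fixed throughout,
    matching a rigid-receptor docking protocol. Poses are deduplicated by
    receptor-frame ligand RMSD and ranked by interaction energy.
    """
    params = params or SamplerParams()
    model = model or PotentialModel()
    site.validate_against(target)
    rng = np.random.default_rng(seed)
    tpos = target.positions
    anchors = _anchor_grid(site, params.grid_spacing)
    confs = ensemble.conformers[: params.max_conformers_docked]
    if not confs:
        warnings.warn("empty conformer ensemble; no poses generated")
        return PoseEnsemble([], seed, params.dedup_rmsd_pose)
    table = PairTable(confs[0].molecule.atoms, target.atoms, model)

    def cross(pos: np.ndarray) -> float:
        try:
            return table.energy(pos, tpos)
        except ClashError:
            return math.inf

    candidates: list[ComplexPose] = []
    for conf in confs:
        centered = conf.positions - conf.positions.mean(axis=0)
        for anchor in anchors:
            best_pos, best_e = None, math.inf
            rots = Rotation.random(params.n_rotations, random_state=np.random.RandomState(
                int(rng.integers(2**31 - 1))))
            for rot in rots:
                pos = rot.apply(centered) + anchor
                if _min_dist(tpos, pos) < params.hard_clash:
                    continue
                e = cross(pos)
                if e < best_e:
                    best_e, best_pos = e, pos
            if best_pos is None or not math.isfinite(best_e):
                continue
            candidates.append(
                ComplexPose(target, Conformer(conf.molecule, best_pos, conf.internal_energy),
                            interaction_energy=best_e)
            )
    candidates.sort(key=lambda p: p.interaction_energy)
    refined: list[ComplexPose] = []
    for cand in candidates[: params.max_poses]:
        conf = cand.ligand_conformer
        center = conf.positions.mean(axis=0)
        centered = conf.positions - center

        def objective(x: np.ndarray) -> float:
            pos = Rotation.from_rotvec(x[3:]).apply(centered) + center + x[:3]
            if _min_dist(tpos, pos) < params.hard_clash:
                return 1e6
            return cross(pos)

        res = minimize(objective, np.zeros(6), method="Powell",
                       options={"maxiter": params.max_min_steps, "maxfev": 400, "xtol": 1e-3})
        pos = Rotation.from_rotvec(res.x[3:]).apply(centered) + center + res.x[:3]
        if _min_dist(tpos, pos) < params.hard_clash or not res.fun < 1e5:
            continue
        refined.append(
            ComplexPose(target, Conformer(conf.molecule, pos, conf.internal_energy),
                        interaction_energy=float(res.fun))
        )
    kept = deduplicate(refined, params.dedup_rmsd_pose)
    if not kept:
        warnings.warn("no clash-free pose found in the binding site")
    for i, p in enumerate(kept):
        p.pose_id = i
    return PoseEnsemble(kept, seed, params.dedup_rmsd_pose)
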