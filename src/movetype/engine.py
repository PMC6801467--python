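"""The movable-type approximation: atom displacement states from pairwise
reversible work, and local partition functions.

The method extrapolates the energy landscape an atom sees under small
displacements without re-evaluating the full potential: for each movable
atom the force from every (fixed) neighbor is projected on a Cartesian axis
and accumulated step by step as reversible work, giving a per-axis energy
profile. The three axis profiles are summed on a displacement grid (the
separability approximation), the grid is Boltzmann-averaged into a per-atom
partition function, and the molecular local partition function is the
product of the atomic ones (the independence approximation) times the
Boltzmann factor of the configuration's own energy.

Partition functions are carried in the log domain throughout: for realistic
ensembles Z itself overflows double precision. We define Z as the *state
average* of Boltzmann factors, so a zero-potential grid has log Z = 0 and
grid-size constants cancel between free and bound states in the final
free-energy ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .potential import (
    ClashError,
    PotentialModel,
    ThermoContext,
    configuration_energy,
    pair_energy,
    pair_force,
)
from .system import Atom, ComplexPose, Conformer

__all__ = [
    "MTSamplingConfig",
    "PairStateVector",
    "AxisWorkProfile",
    "AtomStateGrid",
    "LogPartition",
    "pair_state_vector",
    "axis_work_profile",
    "atom_state_grid",
    "atom_log_partition",
    "local_log_partition",
    "gather_atoms",
    "neighbor_weights",
]

_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


@dataclass(frozen=True)
class MTSamplingConfig:
    """Displacement-sampling parameters.

    distance_range: total span (A) an atom is displaced along each axis.
    angle_range_deg: angular sampling window carried for provenance; the
        integrator recomputes the exact force projection at every step, so
        no tabulated angle grid is needed.
    step: reversible-work integration step Delta-r (A).
    displacement_unit: spacing Delta-tau (A) between partition-grid states.
    n_states_per_axis: states at +/- k*Delta-tau, k = 0..n (2n+1 per axis).
    """

    distance_range: float = 1.0
    angle_range_deg: float = 30.0
    step: float = 0.005
    displacement_unit: float = 0.05
    n_states_per_axis: int = 10

    def __post_init__(self) -> None:
        if self.step <= 0 or self.distance_range < self.step:
            raise ValueError("require step > 0 and distance_range >= step")
        if self.n_states_per_axis < 1:
            raise ValueError("n_states_per_axis must be >= 1")
        if self.displacement_unit < self.step - 1e-12:
            raise ValueError("displacement_unit must be >= step")
        if self.n_states_per_axis * self.displacement_unit > self.distance_range / 2 + 1e-9:
            raise ValueError("state grid must fit inside distance_range/2")

    @property
    def n_steps_half(self) -> int:
        return int(round((self.distance_range / 2) / self.step))

    @property
    def state_stride(self) -> int:
        return int(round(self.displacement_unit / self.step))

    def provenance(self) -> dict:
        return {
            "mt.distance_range": self.distance_range,
            "mt.angle_range_deg": self.angle_range_deg,
            "mt.step": self.step,
            "mt.displacement_unit": self.displacement_unit,
            "mt.n_states": self.n_states_per_axis,
        }


@dataclass
class PairStateVector:
    """Pair energies at relative displacements tau0 +/- k*Delta-tau."""

    atom_id: int
    neighbor_id: int
    reference_distance: float
    energies: np.ndarray  # length 2n+1, index 0 = tau0 - n*dtau

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 1 or self.energies.size % 2 != 1:
            raise ValueError("pair state vector must have odd length")

    @property
    def center_energy(self) -> float:
        return float(self.energies[self.energies.size // 2])


@dataclass
class AxisWorkProfile:
    """Cumulative reversible work along one axis.

    ``displacements[k]`` runs from -range/2 to +range/2 in Delta-r steps and
    ``cumulative_work[k]`` is the left-Riemann line integral of the summed
    neighbor forces projected on the axis, zero at zero displacement.
    """

    axis: str
    displacements: np.ndarray
    cumulative_work: np.ndarray

    def __post_init__(self) -> None:
        mid = self.cumulative_work.size // 2
        if self.cumulative_work[mid] != 0.0:
            raise ValueError("work at zero displacement must be 0")

    def state_energies(self, config: MTSamplingConfig) -> np.ndarray:
        """Energies at the coarse Delta-tau state grid (length 2n+1)."""
        mid = self.cumulative_work.size // 2
        stride = config.state_stride
        n = config.n_states_per_axis
        idx = mid + stride * np.arange(-n, n + 1)
        return self.cumulative_work[idx]


@dataclass
class AtomStateGrid:
    """Separable 3-D displacement energy grid E(dx,dy,dz) = Ex+Ey+Ez."""

    atom_id: int
    axis_energies: tuple[np.ndarray, np.ndarray, np.ndarray]
    config: MTSamplingConfig

    @property
    def energies(self) -> np.ndarray:
        ex, ey, ez = self.axis_energies
        return ex[:, None, None] + ey[None, :, None] + ez[None, None, :]

    @property
    def n_states(self) -> int:
        return int(np.prod([e.size for e in self.axis_energies]))

    def offsets(self) -> np.ndarray:
        """Cartesian displacement of every grid state, shape (n_states, 3)."""
        n = self.config.n_states_per_axis
        d = self.config.displacement_unit
        ax = d * np.arange(-n, n + 1)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class LogPartition:
    """A partition-function value in natural-log domain."""

    log_z: float
    n_states: int
    thermo: ThermoContext = field(default_factory=ThermoContext)
    clashed: bool = False

    @property
    def ensemble_energy(self) -> float:
        return -self.thermo.rt * self.log_z


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pair_state_vector(
    a: Atom,
    i: Atom,
    config: Optional[MTSamplingConfig] = None,
    model: Optional[PotentialModel] = None,
) -> PairStateVector:
    """Energy states of the A-i pair as A slides along the A-i axis.

    States sit at distances r0 + k*Delta-tau, k = -n..n; displacements that
    would push the pair through r <= 0 get +inf energy (excluded from any
    later partition sum). Independent of all other atoms.
    """
    config = config or MTSamplingConfig()
    model = model or PotentialModel()
    r0 = float(np.linalg.norm(a.position - i.position))
    if r0 <= 0:
        raise ValueError("atoms must be distinct")
    n = config.n_states_per_axis
    energies = np.empty(2 * n + 1)
    for idx, k in enumerate(range(-n, n + 1)):
        r = r0 + k * config.displacement_unit
        energies[idx] = math.inf if r <= 0 else pair_energy(a, i, r, model)
    return PairStateVector(a.atom_id, i.atom_id, r0, energies)


def axis_work_profile(
    a_position: np.ndarray,
    a_atom: Atom,
    neighbors: Sequence[Atom],
    axis: str,
    config: Optional[MTSamplingConfig] = None,
    model: Optional[PotentialModel] = None,
    weights: Optional[Sequence[float]] = None,
) -> AxisWorkProfile:
    """Cumulative reversible work on one atom moved along a Cartesian axis.

    At every Delta-r step the energy increment is sum_i dU_i/dr * cos(theta_i)
    * Delta-r with the inclination theta_i between the i->A vector and the
    axis recomputed at the atom's current (moved) position -- a left-Riemann
    line integral of the projected pair forces. ``weights`` scales each
    neighbor's force (used for 1-4 scaling); a step that collides with a
    neighbor (r < 0.1 A) truncates the profile with a +inf tail.
    """
    config = config or MTSamplingConfig()
    model = model or PotentialModel()
    if axis not in _AXES:
        raise ValueError("axis must be one of x, y, z")
    direction = _AXES[axis]
    w = np.ones(len(neighbors)) if weights is None else np.asarray(weights, float)
    m = config.n_steps_half
    dr = config.step
    npos = np.array([nb.position for nb in neighbors]) if neighbors else np.empty((0, 3))
    half: dict[int, np.ndarray] = {}
    for sign in (+1, -1):
        work = np.zeros(m + 1)
        pos = np.asarray(a_position, dtype=float).copy()
        dead = False
        for k in range(1, m + 1):
            if dead:
                work[k] = math.inf
                continue
            increment = 0.0
            for nb, wt, np_i in zip(neighbors, w, npos):
                vec = pos - np_i
                r = float(np.linalg.norm(vec))
                if r < 0.1:
                    dead = True
                    break
                if r >= model.cutoff:
                    continue
                cos_theta = float(np.dot(vec / r, direction))
                # dU/dr = -pair_force; moving by sign*dr changes r by
                # sign*cos_theta*dr for this neighbor
                increment += wt * (-pair_force(a_atom, nb, r, model)) * cos_theta * sign * dr
            if dead:
                work[k] = math.inf
                continue
            work[k] = work[k - 1] + increment
            pos = pos + sign * dr * direction
        half[sign] = work
    displacements = dr * np.arange(-m, m + 1)
    cumulative = np.concatenate([half[-1][::-1][:-1], half[+1]])
    return AxisWorkProfile(axis, displacements, cumulative)


def atom_state_grid(
    a_position: np.ndarray,
    a_atom: Atom,
    neighbors: Sequence[Atom],
    config: Optional[MTSamplingConfig] = None,
    model: Optional[PotentialModel] = None,
    weights: Optional[Sequence[float]] = None,
) -> AtomStateGrid:
    """Separable 3-D displacement energies: E = Ex + Ey + Ez per state.

    Each axis profile is computed independently and the grid is their outer
    sum; the joint landscape is never re-evaluated (that is the movable-type
    separability approximation, checked against a brute-force oracle in the
    benchmark module).
    """
    config = config or MTSamplingConfig()
    model = model or PotentialModel()
    axes = []
    for ax in ("x", "y", "z"):
        profile = axis_work_profile(a_position, a_atom, neighbors, ax, config, model, weights)
        axes.append(profile.state_energies(config))
    return AtomStateGrid(a_atom.atom_id, tuple(axes), config)


def atom_log_partition(
    grid: AtomStateGrid, thermo: Optional[ThermoContext] = None
) -> LogPartition:
    """State-averaged Boltzmann sum of one atom's displacement grid.

    log Z_A = logsumexp(-E/RT) - log(n_states); +inf energies contribute
    zero probability. All-clashed grids are an error.
    """
    thermo = thermo or ThermoContext()
    e = grid.energies.ravel()
    if e.size == 0:
        raise ValueError("empty state grid")
    if not np.any(np.isfinite(e)):
        raise ClashError(f"atom {grid.atom_id}: every displacement state clashes")
    lz = float(logsumexp(np.where(np.isinf(e), -np.inf, -e / thermo.rt)) - math.log(e.size))
    return LogPartition(lz, e.size, thermo)


def gather_atoms(configuration: Union[Conformer, ComplexPose]) -> list[Atom]:
    """All atoms of a configuration at their current coordinates.

    For a pose, ligand atoms come first (ids preserved), then protein atoms.
    """
    if isinstance(configuration, ComplexPose):
        return configuration.ligand_conformer.atoms_at() + list(configuration.target.atoms)
    return configuration.atoms_at()


def neighbor_weights(
    configuration: Union[Conformer, ComplexPose], model: PotentialModel
) -> dict[frozenset, float]:
    """Nonbonded pair weights within the ligand (1-2/1-3 -> 0, 1-4 -> scale)."""
    mol = (
        configuration.ligand_conformer.molecule
        if isinstance(configuration, ComplexPose)
        else configuration.molecule
    )
    excluded, pairs14 = mol.exclusion_sets()
    out = {k: 0.0 for k in excluded}
    out.update({k: model.scale_14 for k in pairs14})
    return out


def local_log_partition(
    configuration: Union[Conformer, ComplexPose],
    movable_atoms: Optional[Sequence[int]] = None,
    config: Optional[MTSamplingConfig] = None,
    model: Optional[PotentialModel] = None,
    thermo: Optional[ThermoContext] = None,
) -> LogPartition:
    """Local partition function of one configuration.

    log Z_M = sum_A log Z_A - E_config/RT over the movable atoms (product of
    per-atom partition functions under the independence approximation, each
    computed with all other atoms held at the input coordinates), with the
    configuration's own Boltzmann weight folded in so ensembles of
    configurations are weighted correctly. ``movable_atoms`` indexes the
    ligand atoms; default: all of them. A clashed configuration yields
    log Z = -inf, flagged, rather than an exception.
    """
    config = config or MTSamplingConfig()
    model = model or PotentialModel()
    thermo = thermo or ThermoContext()
    atoms = gather_atoms(configuration)
    n_lig = (
        len(configuration.ligand_conformer.molecule.atoms)
        if isinstance(configuration, ComplexPose)
        else len(configuration.molecule.atoms)
    )
    movable = list(range(n_lig)) if movable_atoms is None else sorted(movable_atoms)
    if not movable:
        raise ValueError("movable_atoms must be nonempty")
    pair_w = neighbor_weights(configuration, model)
    try:
        e_conf = configuration_energy(configuration, model)
    except ClashError:
        return LogPartition(-math.inf, 0, thermo, clashed=True)
    total = -e_conf / thermo.rt
    n_states = 0
    positions = np.array([a.position for a in atoms])
    from scipy.spatial import cKDTree

    tree = cKDTree(positions)
    for ai in movable:
        a = atoms[ai]
        idx = [j for j in tree.query_ball_point(a.position, model.cutoff) if j != ai]
        nbrs, wts = [], []
        for j in idx:
            # intra-ligand pairs follow the exclusion rules; cross pairs weight 1
            w = 1.0
            if j < n_lig:
                w = pair_w.get(frozenset((ai, j)), 1.0)
            if w == 0.0:
                continue
            nbrs.append(atoms[j])
            wts.append(w)
        try:
            grid = atom_state_grid(a.position, a, nbrs, config, model, wts)
            lp = atom_log_partition(grid, thermo)
        except ClashError:
            return LogPartition(-math.inf, 0, thermo, clashed=True)
        total += lp.log_z
        n_states = max(n_states, lp.n_states)
    return LogPartition(total, n_states, thermo)
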