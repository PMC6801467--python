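"""Ensemble partition assembly, binding free energy, affinity conversions.

The binding free energy is the log-ratio of bound- and free-state ensemble
partition functions,

    dG = -RT log(Z_bound / Z_free),

with each ensemble's Z the sum of its members' local partition functions
(log-sum-exp in the log domain). Ensemble energies are reported as
-RT log Z, the free-energy-like scalar whose difference is dG directly.

Affinity conversions treat IC50 as molar and approximate dG = RT ln IC50 =
-RT ln(10) pIC50, valid in the low-substrate-concentration limit where IC50
tracks the dissociation constant.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .engine import LogPartition, MTSamplingConfig, local_log_partition
from .potential import PotentialModel, ThermoContext
from .sampler import SamplerParams, sample_conformers, sample_poses
from .system import BindingSite, Molecule, ProteinTarget

__all__ = [
    "EnsembleRecord",
    "AffinityRecord",
    "BindingReport",
    "ensemble_log_partition",
    "binding_dg",
    "pic50_to_dg",
    "ddg_from_ic50",
    "compute_binding",
]

LN10 = math.log(10.0)


@dataclass
class EnsembleRecord:
    """A free- or bound-state ensemble: members and their total log Z."""

    members: list[LogPartition]
    total_log_z: float
    state_label: str
    thermo: ThermoContext

    @property
    def ensemble_energy(self) -> float:
        return -self.thermo.rt * self.total_log_z


@dataclass
class AffinityRecord:
    """One benchmark row: a complex with experimental and calculated dG."""

    pdb_id: str
    experimental_dg: float
    calculated_dg: float
    ligand_mass: Optional[float] = None
    ligand: Optional[str] = None
    target: Optional[str] = None
    subgroup: Optional[str] = None
    source: Optional[str] = None


def ensemble_log_partition(
    members: Sequence[LogPartition],
    state_label: str = "free",
    thermo: Optional[ThermoContext] = None,
) -> EnsembleRecord:
    """Total log Z of an ensemble via numerically stable log-sum-exp."""
    if not members:
        raise ValueError("ensemble needs at least one member")
    thermo = thermo or members[0].thermo
    for m in members:
        if m.thermo != thermo:
            raise ValueError("all members must share a thermodynamic context")
    logs = np.array([m.log_z for m in members], dtype=float)
    if np.all(np.isneginf(logs)):
        raise ValueError("all ensemble members are clashed (log Z = -inf)")
    return EnsembleRecord(list(members), float(logsumexp(logs)), state_label, thermo)


def binding_dg(
    bound: EnsembleRecord, free: EnsembleRecord, thermo: Optional[ThermoContext] = None
) -> float:
    """dG = -RT (log Z_bound - log Z_free), kcal/mol; negative = favorable."""
    if bound.state_label != "bound" or free.state_label != "free":
        raise ValueError("pass (bound, free) ensembles in that order")
    if bound.thermo != free.thermo:
        raise ValueError("bound and free ensembles use different thermodynamic contexts")
    if thermo is not None and thermo != bound.thermo:
        raise ValueError("explicit thermo context conflicts with the ensembles'")
    t = bound.thermo
    return -t.rt * (bound.total_log_z - free.total_log_z)


def pic50_to_dg(pic50: float, thermo: Optional[ThermoContext] = None) -> float:
    """dG ~= RT ln IC50 = -RT ln(10) pIC50 (IC50 in molar), kcal/mol."""
    if not math.isfinite(pic50):
        raise ValueError("pIC50 must be finite")
    thermo = thermo or ThermoContext()
    return -thermo.rt * LN10 * pic50


def ddg_from_ic50(
    ic50_1: float, ic50_2: float, thermo: Optional[ThermoContext] = None
) -> float:
    """Relative affinity ddG = -RT ln(IC50_1/IC50_2); antisymmetric in its args.

    Concentration-dependent terms common to both measurements cancel in the
    ratio, so this is meaningful even when the absolute IC50-to-Kd mapping
    is not.
    """
    if ic50_1 <= 0 or ic50_2 <= 0:
        raise ValueError("IC50 values must be positive")
    thermo = thermo or ThermoContext()
    return -thermo.rt * math.log(ic50_1 / ic50_2)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class BindingReport:
    """Everything one binding calculation produced, JSON-serializable."""

    delta_g: Optional[float]
    free_ensemble_energy: float
    bound_ensemble_energy: Optional[float]
    n_conformers: int
    n_poses: int
    free_members: list[dict] = field(default_factory=list)
    bound_members: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "delta_g_kcal_mol": self.delta_g,
            "free_ensemble_energy_kcal_mol": self.free_ensemble_energy,
            "bound_ensemble_energy_kcal_mol": self.bound_ensemble_energy,
            "n_conformers": self.n_conformers,
            "n_poses": self.n_poses,
            "free_members": self.free_members,
            "bound_members": self.bound_members,
            "provenance": self.provenance,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _config_hash(*objs) -> str:
    payload = json.dumps([repr(o) for o in objs], sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def compute_binding(
    target: ProteinTarget,
    ligand: Molecule,
    site: BindingSite,
    seed: int = 0,
    mt_config: Optional[MTSamplingConfig] = None,
    model: Optional[PotentialModel] = None,
    thermo: Optional[ThermoContext] = None,
    sampler_params: Optional[SamplerParams] = None,
) -> BindingReport:
    """Full pipeline: conformers -> Z_free; poses -> Z_bound; dG by ratio.

    Every free-state conformer and every bound-state pose contributes its
    local partition function; the two ensemble log-sums give the ensemble
    energies whose difference is the binding free energy. An empty pose
    ensemble yields a report with dG undefined plus a diagnostic.
    """
    mt_config = mt_config or MTSamplingConfig()
    model = model or PotentialModel()
    thermo = thermo or ThermoContext()
    sampler_params = sampler_params or SamplerParams()

    conf_ens = sample_conformers(ligand, sampler_params, seed=seed, model=model)
    free_parts = [
        local_log_partition(c, None, mt_config, model, thermo) for c in conf_ens.conformers
    ]
    free = ensemble_log_partition(free_parts, "free", thermo)

    pose_ens = sample_poses(target, conf_ens, site, sampler_params, seed=seed, model=model)
    diagnostics: list[str] = []
    bound = None
    bound_parts: list[LogPartition] = []
    if len(pose_ens):
        bound_parts = [
            local_log_partition(p, None, mt_config, model, thermo) for p in pose_ens.poses
        ]
        try:
            bound = ensemble_log_partition(bound_parts, "bound", thermo)
        except ValueError as exc:
            diagnostics.append(str(exc))
    else:
        diagnostics.append("empty pose ensemble: no clash-free binding mode found")

    report = BindingReport(
        delta_g=None if bound is None else binding_dg(bound, free),
        free_ensemble_energy=free.ensemble_energy,
        bound_ensemble_energy=None if bound is None else bound.ensemble_energy,
        n_conformers=conf_ens.n_distinct,
        n_poses=len(pose_ens),
        free_members=[
            {"rank": i, "internal_energy": c.internal_energy,
             "log_z": lp.log_z, "ensemble_energy": lp.ensemble_energy}
            for i, (c, lp) in enumerate(zip(conf_ens.conformers, free_parts))
        ],
        bound_members=[
            {"rank": i, "interaction_energy": p.interaction_energy,
             "log_z": lp.log_z, "ensemble_energy": lp.ensemble_energy}
            for i, (p, lp) in enumerate(zip(pose_ens.poses, bound_parts))
        ],
        provenance={
            "seed": seed,
            "temperature_K": thermo.temperature,
            **mt_config.provenance(),
            "sampler": repr(sampler_params),
            "potential": repr(model),
            "config_hash": _config_hash(mt_config, model, thermo, sampler_params, seed),
        },
        diagnostics=diagnostics,
    )
    return report
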