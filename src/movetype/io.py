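"""Standard-format I/O: PDB targets, SDF/MOL2 ligands, pose/conformer writers.

Reading leans on Biopython (PDB) and RDKit (SDF V2000, MOL2); the package's
own types are built from those parses. Missing partial charges are assigned
with RDKit's Gasteiger scheme (iterative partial equalization of orbital
electronegativity); when even that fails for an exotic atom the charge
falls back to zero with a warning.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Optional

import numpy as np

from .system import Atom, Bond, ComplexPose, Conformer, Molecule, MoleculeError, ProteinTarget

__all__ = [
    "read_pdb",
    "read_ligand",
    "write_sdf",
    "write_pose_pdb",
    "molecule_from_rdkit",
    "molecule_to_rdkit",
]

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SPC"}
_ION_RESNAMES = {"NA", "K", "CL", "MG", "ZN", "CA", "MN", "FE", "CU", "BR", "IOD", "CS", "LI"}


def _validate_pdb_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise MoleculeError(f"{path}:{lineno}: truncated coordinate record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise MoleculeError(
                    f"{path}:{lineno}: unparsable coordinates in {line.rstrip()!r}"
                ) from None


def read_pdb(
    path: str, keep_waters: bool = False, keep_ions: bool = False, name: Optional[str] = None
) -> ProteinTarget:
    """Read a fixed-column PDB file into a :class:`ProteinTarget`.

    altLoc handling keeps 'A' or blank; waters and common ions are dropped
    unless the corresponding flag is set. Raises :class:`MoleculeError` on
    unparsable records (naming the line) and on empty structures.
    """
    from Bio.PDB import PDBParser

    _validate_pdb_lines(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name or "target", path)
    atoms: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                if resname in _WATER_RESNAMES and not keep_waters:
                    continue
                if resname in _ION_RESNAMES and not keep_ions:
                    continue
                het, resseq, icode = residue.get_id()
                tag = f"{resname}:{chain.id}:{resseq}{icode.strip()}"
                for atom in residue:
                    altloc = atom.get_altloc()
                    if altloc not in (" ", "", "A"):
                        continue
                    element = (atom.element or atom.get_name()[0]).strip().capitalize()
                    atoms.append(
                        Atom(
                            element,
                            np.asarray(atom.get_coord(), dtype=float),
                            atom_id=len(atoms),
                            residue_tag=tag,
                        )
                    )
        break  # first model only
    if not atoms:
        raise MoleculeError(f"{path}: no ATOM/HETATM records retained")
    return ProteinTarget(atoms, name=name or structure.id)


# ---------------------------------------------------------------------------
# ligands via RDKit
# ---------------------------------------------------------------------------

def _gasteiger_charges(mol) -> list[float]:
    from rdkit import Chem
    from rdkit.Chem import rdPartialCharges

    work = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(work)
        rdPartialCharges.ComputeGasteigerCharges(work)
        charges = [float(a.GetProp("_GasteigerCharge")) for a in work.GetAtoms()]
        return [0.0 if math.isnan(c) or math.isinf(c) else c for c in charges]
    except Exception as exc:  # pragma: no cover - exotic chemistry
        warnings.warn(f"charge assignment failed ({exc}); using zero charges")
        return [0.0] * mol.GetNumAtoms()


def molecule_from_rdkit(mol, name: str = "ligand") -> Molecule:
    """Convert an RDKit mol (with a 3-D conformer) to a :class:`Molecule`."""
    if mol.GetNumConformers() == 0:
        raise MoleculeError("ligand has no 3-D coordinates")
    conf = mol.GetConformer()
    have_charges = any(a.HasProp("_TriposPartialCharge") for a in mol.GetAtoms())
    charges = (
        [
            float(a.GetProp("_TriposPartialCharge")) if a.HasProp("_TriposPartialCharge") else 0.0
            for a in mol.GetAtoms()
        ]
        if have_charges
        else _gasteiger_charges(mol)
    )
    atoms = [
        Atom(
            a.GetSymbol(),
            np.array(conf.GetAtomPosition(i)),
            partial_charge=charges[i],
            atom_id=i,
        )
        for i, a in enumerate(mol.GetAtoms())
    ]
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()) or 1)
        for b in mol.GetBonds()
    ]
    return Molecule(atoms, bonds, name=name)


def read_ligand(path: str, name: Optional[str] = None) -> Molecule:
    """Read an SDF (V2000) or MOL2 ligand with explicit bonds.

    Rotatable bonds (acyclic heavy-heavy single bonds with a further heavy
    neighbor on each side) are detected on load; valence problems warn
    rather than fail.
    """
    from rdkit import Chem

    path = str(path)
    if path.lower().endswith(".mol2"):
        mol = Chem.MolFromMol2File(path, sanitize=False, removeHs=False)
    else:
        mol = Chem.MolFromMolFile(path, sanitize=False, removeHs=False)
    if mol is None:
        raise MoleculeError(f"{path}: could not parse ligand file")
    if mol.GetNumAtoms() == 0:
        raise MoleculeError(f"{path}: ligand has no atoms")
    if mol.GetNumAtoms() > 1 and mol.GetNumBonds() == 0:
        raise MoleculeError(f"{path}: missing bond block")
    try:
        Chem.SanitizeMol(Chem.Mol(mol))
    except Exception as exc:
        warnings.warn(f"{path}: valence/sanitization issue ignored: {exc}")
    return molecule_from_rdkit(mol, name=name or path.rsplit("/", 1)[-1].rsplit(".", 1)[0])


def molecule_to_rdkit(molecule: Molecule, positions: Optional[np.ndarray] = None):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    em = Chem.RWMol()
    for a in molecule.atoms:
        em.AddAtom(Chem.Atom(a.element.capitalize()))
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for b in molecule.bonds:
        em.AddBond(b.i, b.j, order_map.get(b.order, Chem.BondType.SINGLE))
    mol = em.GetMol()
    conf = Chem.Conformer(len(molecule.atoms))
    pos = molecule.positions if positions is None else np.asarray(positions)
    for i, p in enumerate(pos):
        conf.SetAtomPosition(i, Point3D(*map(float, p)))
    mol.AddConformer(conf)
    mol.SetProp("_Name", molecule.name)
    try:
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    except Exception:  # toy pseudo-molecules need not be valid chemistry
        pass
    return mol


def write_sdf(conformers: Iterable[Conformer], path: str) -> None:
    """Write conformers as a multi-record SDF with an energy tag each."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for k, conf in enumerate(conformers):
        mol = molecule_to_rdkit(conf.molecule, conf.positions)
        mol.SetProp("_Name", f"{conf.molecule.name}_{k}")
        mol.SetProp("energy_kcal_mol", f"{conf.internal_energy:.6f}")
        writer.write(mol)
    writer.close()


def _pdb_atom_line(serial, name, resname, chain, resseq, pos, element, hetatm=False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s}{resname:>4s} {chain}{resseq:>4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00          {element:>2s}\n"
    )


def write_pose_pdb(poses: Iterable[ComplexPose], path: str) -> None:
    """Write poses as a multi-model PDB (protein ATOM + ligand HETATM)."""
    with open(str(path), "w") as fh:
        for m, pose in enumerate(poses, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            serial = 1
            for a in pose.target.atoms:
                resname, chain, resseq = (a.residue_tag or "UNK:A:1").split(":")
                fh.write(
                    _pdb_atom_line(
                        serial, a.element, resname[:3], chain[:1],
                        int("".join(ch for ch in resseq if ch.isdigit()) or 1),
                        a.position, a.element.upper(),
                    )
                )
                serial += 1
            lig = pose.ligand_conformer
            for i, a in enumerate(lig.molecule.atoms):
                fh.write(
                    _pdb_atom_line(
                        serial, f"{a.element}{i + 1}", "LIG", "L", 1,
                        lig.positions[i], a.element.upper(), hetatm=True,
                    )
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
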