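"""Molecule container and PDB input/output.

A :class:`Molecule` is a flat, array-backed list of atoms: element, residue
index/name, atom name, chain id and Cartesian coordinates (Å), plus
annotations used by the samplers (rigid-group id, linker/terminus flags).
Atoms with ``rigid_group >= 0`` belong to exactly one rigid body; atoms with
``rigid_group == -1`` form the flexible set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Molecule", "read_pdb", "write_pdb", "ELEMENT_VDW_RADII"]


class MoleculeError(ValueError):
    """Invalid molecule content."""


# Bondi van der Waals radii (Å); BEAD is the coarse-grained pseudo-atom used
# by the synthetic fixtures (one scatterer per residue-sized bead).
ELEMENT_VDW_RADII = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "BEAD": 2.5,
}


@dataclass
class Molecule:
    element: np.ndarray  # (N,) str
    resid: np.ndarray  # (N,) int
    resname: np.ndarray  # (N,) str
    atom_name: np.ndarray  # (N,) str
    coords: np.ndarray  # (N, 3) float, Å
    chain: str = "A"
    rigid_group: np.ndarray | None = None  # (N,) int; -1 = flexible
    is_linker: np.ndarray | None = None  # (N,) bool
    is_terminus: np.ndarray | None = None  # (N,) bool

    def __post_init__(self) -> None:
        self.element = np.asarray(self.element, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if not (self.element.size == self.resid.size == self.resname.size == self.atom_name.size == n):
            raise MoleculeError("per-atom arrays must have equal lengths")
        if n and not np.all(np.isfinite(self.coords)):
            raise MoleculeError("non-finite coordinates")
        if self.rigid_group is None:
            self.rigid_group = np.full(n, -1, dtype=int)
        else:
            self.rigid_group = np.asarray(self.rigid_group, dtype=int)
        if self.is_linker is None:
            self.is_linker = np.zeros(n, dtype=bool)
        else:
            self.is_linker = np.asarray(self.is_linker, dtype=bool)
        if self.is_terminus is None:
            self.is_terminus = np.zeros(n, dtype=bool)
        else:
            self.is_terminus = np.asarray(self.is_terminus, dtype=bool)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def com(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Unweighted centroid of the selected atoms (all atoms by default)."""
        xyz = self.coords if indices is None else self.coords[indices]
        return xyz.mean(axis=0)

    def subset(self, indices: np.ndarray) -> "Molecule":
        indices = np.asarray(indices)
        return Molecule(
            element=self.element[indices],
            resid=self.resid[indices],
            resname=self.resname[indices],
            atom_name=self.atom_name[indices],
            coords=self.coords[indices].copy(),
            chain=self.chain,
            rigid_group=self.rigid_group[indices].copy(),
            is_linker=self.is_linker[indices].copy(),
            is_terminus=self.is_terminus[indices].copy(),
        )

    def copy(self) -> "Molecule":
        return self.subset(np.arange(len(self)))

    def vdw_radii(self) -> np.ndarray:
        return np.array([ELEMENT_VDW_RADII.get(e, 1.7) for e in self.element])


def concatenate(molecules: list[Molecule], chain: str | None = None) -> Molecule:
    """Stack molecules into one, keeping per-atom annotations."""
    return Molecule(
        element=np.concatenate([m.element for m in molecules]),
        resid=np.concatenate([m.resid for m in molecules]),
        resname=np.concatenate([m.resname for m in molecules]),
        atom_name=np.concatenate([m.atom_name for m in molecules]),
        coords=np.concatenate([m.coords for m in molecules]),
        chain=chain if chain is not None else molecules[0].chain,
        rigid_group=np.concatenate([m.rigid_group for m in molecules]),
        is_linker=np.concatenate([m.is_linker for m in molecules]),
        is_terminus=np.concatenate([m.is_terminus for m in molecules]),
    )


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA"):
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_pdb(path: str | Path, *, model: int = 0) -> Molecule:
    """Read ATOM/HETATM records of a PDB file into a Molecule.

    Only the first altloc of each atom is kept; a missing element field is
    inferred from the atom name.  Parsing is delegated to Bio.PDB.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Bio.PDB is chatty about nonstandard files
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise MoleculeError(f"{path}: no ATOM records")
    mdl = models[model]
    elements, resids, resnames, names, xyz = [], [], [], [], []
    chain_id = "A"
    for chain_obj in mdl:
        chain_id = chain_obj.id if chain_obj.id.strip() else "A"
        for residue in chain_obj:
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]  # keep first altloc
                elem = (atom.element or "").strip()
                if elem.upper() in ("Q", "X") or atom.get_name().strip() == "Q":
                    elem = "BEAD"  # pseudo-atom alias used for coarse beads
                elements.append(elem if elem else _infer_element(atom.get_name()))
                resids.append(residue.id[1])
                resnames.append(residue.get_resname())
                names.append(atom.get_name())
                xyz.append(atom.get_coord())
        break  # single-chain molecules; multi-chain files are flattened per chain 1
    if not xyz:
        raise MoleculeError(f"{path}: no ATOM records")
    return Molecule(
        element=np.array(elements, dtype=object),
        resid=np.array(resids, dtype=int),
        resname=np.array(resnames, dtype=object),
        atom_name=np.array(names, dtype=object),
        coords=np.array(xyz, dtype=float),
        chain=chain_id,
    )


def _format_atom(serial: int, mol: Molecule, i: int) -> str:
    name = str(mol.atom_name[i])
    elem = str(mol.element[i])
    if elem == "BEAD":
        # PDB element column is 2 chars; beads are serialized as pseudo-atom Q
        elem = "Q"
        name = "Q"
    # PDB column rules: 1/2-char element names start at column 13/14.
    name_field = f" {name:<3s}" if len(name) < 4 and len(elem) == 1 else f"{name:<4s}"
    x, y, z = mol.coords[i]
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{str(mol.resname[i])[:3]:>3s} "
        f"{mol.chain[:1]}{int(mol.resid[i]):>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem[:2]:>2s}\n"
    )


def write_pdb(mol: Molecule, path: str | Path, *, append_model: bool = False, model_number: int = 1) -> None:
    """Write a Molecule as PDB ATOM records (coordinates to 3 decimals)."""
    mode = "a" if append_model else "w"
    with open(path, mode) as fh:
        if append_model:
            fh.write(f"MODEL     {model_number:>4d}\n")
        for i in range(len(mol)):
            fh.write(_format_atom(i + 1, mol, i))
        if append_model:
            fh.write("ENDMDL\n")
        else:
            fh.write("END\n")
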