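"""Atomic X-ray form factors for solution scattering.

Vacuum form factors use the standard international-tables sum-of-Gaussians
parameterization f(q) = Σₖ aₖ exp(−bₖ (q/4π)²) + c.  The solvent-displacement
("dummy atom") factor follows the Fraser/Svergun Gaussian-sphere convention
f_dummy(q) = ρ_w V exp(−q² V^{2/3} / 4π) with bulk water density
ρ_w = 0.334 e/Å³.  Hydrogens are folded into their bonded heavy atom (both
electrons and displaced volume) for standard protein atom names.

``BEAD`` is the coarse-grained pseudo-element used by the synthetic fixtures:
a flat 10-electron scatterer displacing 15 Å³, sized so that the excluded-
volume (c1) and hydration (c2) corrections keep leverage on a bead model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FormFactorTable", "default_table", "WATER_DENSITY"]

WATER_DENSITY = 0.334  # bulk water electron density, e/Å³

# element: (a1..a4, b1..b4, c) — 4-Gaussian vacuum coefficients
_VACUUM = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879), (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000), (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630), (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000), (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630), (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080), (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    # flat coarse-grained bead: 10 electrons, no q falloff
    "BEAD": ((10.0, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0), 0.0),
}

# solvent-displaced volumes, Å³ (Fraser et al. convention)
_DISPLACED_VOLUME = {
    "H": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.73,
    "BEAD": 15.0,
}

_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "BEAD": 10}


def _implicit_hydrogens(resname: str, atom_name: str) -> int:
    """Bonded-hydrogen count for standard protein heavy atoms (heuristic)."""
    res = resname.upper()
    name = atom_name.upper()
    if name == "N":
        return 0 if res == "PRO" else 1
    if name == "CA":
        return 2 if res == "GLY" else 1
    if name in ("C", "O", "OXT"):
        return 0
    if name == "CB":
        return 3 if res == "ALA" else (1 if res in ("ILE", "THR", "VAL") else 2)
    if name == "CG":
        if res in ("ARG", "GLN", "GLU", "LYS", "MET", "PRO"):
            return 2
        if res == "LEU":
            return 1
        return 0  # aromatic / carbonyl CG
    if name == "CG1":
        return 2 if res == "ILE" else 3
    if name == "CG2":
        return 3
    if name == "CD":
        return 2 if res in ("ARG", "LYS", "PRO") else 0
    if name in ("CD1", "CD2"):
        if res in ("LEU", "ILE"):
            return 3
        return 0 if (res == "TRP" and name == "CD2") else 1
    if name == "CE":
        return 3 if res == "MET" else 2
    if name in ("CE1", "CE3", "CZ2", "CZ3", "CH2"):
        return 1
    if name == "CE2":
        return 0 if res == "TRP" else 1
    if name == "CZ":
        return 1 if res == "PHE" else 0
    if name in ("ND2", "NE2") and res in ("ASN", "GLN"):
        return 2
    if name in ("NE", "ND1", "NE1") or (name == "NE2" and res == "HIS"):
        return 1
    if name in ("NH1", "NH2"):
        return 2
    if name == "NZ":
        return 3
    if name in ("OG", "OG1", "OH"):
        return 1
    if name == "SG":
        return 1
    return 0


@dataclass(frozen=True)
class FormFactorTable:
    """Vacuum and dummy-solvent form factors with implicit-hydrogen folding."""

    fold_hydrogens: bool = True
    water_density: float = WATER_DENSITY

    def electrons(self, element: str) -> float:
        try:
            return float(_ELECTRONS[element.upper() if element != "BEAD" else element])
        except KeyError:
            raise KeyError(f"no form factor for element {element!r}") from None

    def _coeffs(self, element: str):
        key = element if element == "BEAD" else element.upper()
        if key not in _VACUUM:
            raise KeyError(f"no form factor for element {element!r}")
        return _VACUUM[key]

    def vacuum_factor(self, element: str, q: np.ndarray, n_hydrogens: int = 0) -> np.ndarray:
        """f_vac(q) of the heavy atom plus ``n_hydrogens`` folded hydrogens."""
        q = np.asarray(q, dtype=float)
        a, b, c = self._coeffs(element)
        s2 = (q / (4.0 * np.pi)) ** 2
        f = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
        if n_hydrogens:
            ah, bh, ch = self._coeffs("H")
            f = f + n_hydrogens * (ch + sum(ai * np.exp(-bi * s2) for ai, bi in zip(ah, bh)))
        return f

    def displaced_volume(self, element: str, n_hydrogens: int = 0) -> float:
        key = element if element == "BEAD" else element.upper()
        if key not in _DISPLACED_VOLUME:
            raise KeyError(f"no displaced volume for element {element!r}")
        return _DISPLACED_VOLUME[key] + n_hydrogens * _DISPLACED_VOLUME["H"]

    def dummy_factor(self, element: str, q: np.ndarray, n_hydrogens: int = 0) -> np.ndarray:
        """Gaussian-sphere dummy-atom factor ρ_w V exp(−q² V^{2/3}/4π)."""
        q = np.asarray(q, dtype=float)
        v = self.displaced_volume(element, n_hydrogens)
        return self.water_density * v * np.exp(-(q ** 2) * v ** (2.0 / 3.0) / (4.0 * np.pi))

    def dummy_radius(self, element: str, n_hydrogens: int = 0) -> float:
        """Radius of the sphere with the atom's displaced volume, Å."""
        v = self.displaced_volume(element, n_hydrogens)
        return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)

    def water_factor(self, q: np.ndarray) -> np.ndarray:
        """Vacuum form factor of one water molecule (O + 2H)."""
        return self.vacuum_factor("O", q, n_hydrogens=2)

    def hydrogens_for(self, resname: str, atom_name: str, element: str) -> int:
        if not self.fold_hydrogens or element == "BEAD":
            return 0
        return _implicit_hydrogens(resname, atom_name)


def default_table() -> FormFactorTable:
    return FormFactorTable()
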