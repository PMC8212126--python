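"""Synthetic two-domain systems and noisy SAXS profiles.

These generators stand in for a real two-domain protein: two compact bead
clusters of distinct sizes (so the relative pose is identifiable from the
scattering curve) joined by an optional flexible bead linker, plus simulated
noisy profiles with the error model s(q) = a·I(q) + b.  Everything is seeded;
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import compute_profile
from .molecule import Molecule
from .profiles import SAXSProfile
from .sampling import Dihedral, RigidBodySystem

__all__ = [
    "SyntheticSystemSpec",
    "NoiseSpec",
    "make_two_domain_system",
    "to_rigid_system",
    "simulate_profile",
    "ProfilePool",
    "make_profile_pool",
    "default_q_grid",
]


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Toy two-domain system: bead counts, radii, linker length, separation."""

    beads_large: int = 16
    beads_small: int = 10
    radius_large: float = 9.0
    radius_small: float = 6.5
    linker_length: int = 6
    separation: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.beads_large, self.beads_small) < 1 or self.separation <= 0:
            raise ValueError("bead counts and separation must be positive")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Error model s(q) = a·I(q) + b with Gaussian noise of sd s(q).

    Default a = 0.01 with a floor b = 1e-4·I(0) keeps χ² ≈ 1 scale so that
    σ̂ ≈ 1 is the recovery target; ``relative = 0`` gives noise-free data with
    the same (positive) error bars.
    """

    relative: float = 0.01
    floor_frac: float = 1e-4
    seed: int = 0
    add_noise: bool = True


def _packed_cluster(rng: np.random.Generator, n: int, radius: float, min_sep: float = 3.8) -> np.ndarray:
    """Beads packed in a sphere with a minimum separation (rejection sampling)."""
    pts: list[np.ndarray] = [np.zeros(3)]
    attempts = 0
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        attempts += 1
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
        elif attempts > 20_000:
            min_sep *= 0.95  # ease packing instead of failing
            attempts = 0
    arr = np.array(pts[:n])
    return arr - arr.mean(axis=0)


def make_two_domain_system(spec: SyntheticSystemSpec) -> Molecule:
    """Two bead domains at the given center separation plus a linker chain.

    Domain A (large) carries rigid group 0 centered at the origin, domain B
    rigid group 1 at (separation, 0, 0); linker beads are flagged flexible.
    Anchor beads sit on the facing surfaces so a linker path exists.
    """
    rng = np.random.default_rng(spec.seed)
    a = _packed_cluster(rng, spec.beads_large - 1, spec.radius_large)
    a = np.vstack([a, [spec.radius_large, 0.0, 0.0]])  # anchor bead toward B
    a = a - a.mean(axis=0)  # COM exactly at the origin
    b = _packed_cluster(rng, spec.beads_small - 1, spec.radius_small)
    b = np.vstack([[-spec.radius_small, 0.0, 0.0], b])  # anchor bead toward A
    b = b - b.mean(axis=0) + np.array([spec.separation, 0.0, 0.0])  # COM at separation
    start = a[-1]
    end = b[0]
    nl = spec.linker_length
    linker = np.array(
        [start + (end - start) * (i + 1) / (nl + 1) for i in range(nl)]
    ).reshape(nl, 3)
    coords = np.vstack([a, linker, b])
    n = coords.shape[0]
    na, nb = a.shape[0], b.shape[0]
    rigid = np.concatenate([np.zeros(na, int), -np.ones(nl, int), np.ones(nb, int)])
    is_linker = np.concatenate([np.zeros(na, bool), np.ones(nl, bool), np.zeros(nb, bool)])
    return Molecule(
        element=np.array(["BEAD"] * n, dtype=object),
        resid=np.arange(1, n + 1),
        resname=np.array(["GLY"] * n, dtype=object),
        atom_name=np.array(["CA"] * n, dtype=object),
        coords=coords,
        rigid_group=rigid,
        is_linker=is_linker,
    )


def to_rigid_system(molecule: Molecule, *, with_linker_dihedrals: bool = False) -> RigidBodySystem:
    """Wrap a labeled molecule as a RigidBodySystem.

    With ``with_linker_dihedrals`` the serial chain anchorA → linker → B gets
    one pseudo-dihedral per consecutive linker bond; everything downstream of
    the axis (remaining linker beads plus domain B) moves with it.
    """
    fixed = np.where(molecule.rigid_group == 0)[0]
    mobile = np.where(molecule.rigid_group == 1)[0]
    flexible = np.where(molecule.rigid_group == -1)[0]
    dihedrals: list[Dihedral] = []
    bonds: list[tuple[int, int]] = []
    if flexible.size:
        # chain order: anchor of fixed body, linker beads, anchor of mobile body
        chain = [int(fixed[-1]), *map(int, flexible), int(mobile[0])]
        bonds = [(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]
        if with_linker_dihedrals:
            for i in range(len(chain) - 2):
                moved = np.array(chain[i + 2 :] + list(map(int, mobile[1:])), dtype=int)
                moved = np.unique(np.concatenate([moved, mobile]))
                dihedrals.append(Dihedral(a=chain[i], b=chain[i + 1], moved=moved, kind="linker"))
    return RigidBodySystem(
        molecule=molecule.copy(),
        fixed_idx=fixed,
        mobile_idx=mobile,
        flexible_idx=flexible,
        dihedrals=dihedrals,
        bonds=bonds,
    )


def default_q_grid(m: int = 80, q_min: float = 0.01, q_max: float = 0.37) -> np.ndarray:
    return np.linspace(q_min, q_max, m)


def make_atom_cluster(
    n: int = 150,
    radius: float = 11.0,
    seed: int = 0,
    *,
    min_sep: float = 2.2,
    elements=("C", "N", "O", "S"),
    element_probs=(0.55, 0.2, 0.2, 0.05),
) -> Molecule:
    """Dense random atomistic globule with both buried and surface atoms.

    Used to exercise the excluded-volume (c1) and hydration (c2) corrections:
    a dense cluster has genuinely buried atoms, which decorrelates the two
    responses (a loose bead cloud leaves them nearly collinear).
    """
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    sep = min_sep
    attempts = 0
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        attempts += 1
        if all(np.linalg.norm(p - q) >= sep for q in pts):
            pts.append(p)
        elif attempts > 20_000:
            sep *= 0.95
            attempts = 0
    coords = np.array(pts)
    elems = rng.choice(list(elements), size=n, p=list(element_probs))
    return Molecule(
        element=np.array(elems, dtype=object),
        resid=np.arange(1, n + 1),
        resname=np.array(["ALA"] * n, dtype=object),
        atom_name=np.array(["CA"] * n, dtype=object),
        coords=coords,
    )


def simulate_profile(
    molecule: Molecule,
    q_grid: np.ndarray,
    gamma_true: float = 1.0,
    c1: float = 1.0,
    c2: float = 0.0,
    noise: NoiseSpec | None = None,
    *,
    table=None,
) -> SAXSProfile:
    """Noisy synthetic profile I = γ·m(X, q, c1, c2) + N(0, s(q))."""
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    calc = compute_profile(molecule, q_grid, c1, c2, table=table).intensity
    ideal = gamma_true * calc
    s = noise.relative * np.abs(ideal) + noise.floor_frac * np.abs(ideal[0])
    s = np.maximum(s, 1e-12 * max(np.abs(ideal[0]), 1.0))
    intensity = ideal + (rng.normal(0.0, 1.0, size=ideal.shape) * s if noise.add_noise else 0.0)
    return SAXSProfile(q=np.asarray(q_grid, float), intensity=intensity, error=s, label="synthetic")


@dataclass
class ProfilePool:
    """Per-conformer theoretical profiles plus the experimental mixture."""

    ids: list
    intensities: np.ndarray  # (P, M)
    experiment: SAXSProfile
    true_weights: np.ndarray | None = None  # ground truth, recorded for tests

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("pool ids must be unique")
        if self.intensities.shape != (len(self.ids), self.experiment.M):
            raise ValueError("pool intensities must be (n_ids, M)")

    @property
    def size(self) -> int:
        return len(self.ids)


def make_profile_pool(
    base_molecules: list[Molecule],
    mixture_weights: np.ndarray,
    noise: NoiseSpec | None = None,
    q_grid: np.ndarray | None = None,
    *,
    table=None,
) -> ProfilePool:
    """Pool of per-conformer profiles; the experiment is the weighted mixture."""
    mixture_weights = np.asarray(mixture_weights, dtype=float)
    if len(base_molecules) != mixture_weights.size:
        raise ValueError("one weight per molecule required")
    if abs(mixture_weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    profiles = np.array(
        [compute_profile(m, q_grid, table=table).intensity for m in base_molecules]
    )
    ideal = mixture_weights @ profiles
    s = noise.relative * np.abs(ideal) + noise.floor_frac * np.abs(ideal[0])
    s = np.maximum(s, 1e-12 * max(np.abs(ideal[0]), 1.0))
    intensity = ideal + (rng.normal(0.0, 1.0, size=ideal.shape) * s if noise.add_noise else 0.0)
    exp = SAXSProfile(q=q_grid, intensity=intensity, error=s, label="mixture")
    return ProfilePool(
        ids=list(range(len(base_molecules))),
        intensities=profiles,
        experiment=exp,
        true_weights=mixture_weights.copy(),
    )
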