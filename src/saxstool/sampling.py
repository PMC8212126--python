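"""Score-driven Monte Carlo: rigid-body docking and dihedral refinement.

The samplers minimize  E = w·χ²(γ) + E_ev  by Metropolis at temperature 1,
where w is either the automatic Bayesian weight M/2σ² (with γ and σ refreshed
to their maximum-posterior values after every step block) or a fixed value,
and E_ev is a quadratic volume-exclusion penalty.  Rigid bodies are moved by
rotation/translation proposals; flexible segments by Gaussian perturbations
of individual backbone dihedrals, rebuilding downstream atoms by rigid
rotation about the dihedral axis (bond lengths and angles never change).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import bayes
from .forward import atom_amplitudes, debye_intensity, hydration_surface_weights
from .geometry import matrix_to_quat, quat_to_matrix, random_quat, rotation_about_axis
from .molecule import Molecule
from .profiles import SAXSProfile

logger = logging.getLogger(__name__)

__all__ = [
    "Dihedral",
    "RigidBodySystem",
    "MCConfig",
    "TrajectoryRecord",
    "excluded_volume",
    "randomize_start",
    "rigid_dock",
    "dihedral_refine",
    "fixed_weight_run",
]


class SamplingError(ValueError):
    pass


@dataclass
class Dihedral:
    """Rotatable axis a→b; ``moved`` are the downstream atom indices."""

    a: int
    b: int
    moved: np.ndarray
    kind: str = "linker"  # "linker" or "terminus"


@dataclass
class RigidBodySystem:
    """A molecule partitioned into a fixed body, a mobile body and a flexible set."""

    molecule: Molecule
    fixed_idx: np.ndarray
    mobile_idx: np.ndarray
    flexible_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    dihedrals: list[Dihedral] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)  # EV exclusions (chain topology)

    def __post_init__(self) -> None:
        self.fixed_idx = np.asarray(self.fixed_idx, dtype=int)
        self.mobile_idx = np.asarray(self.mobile_idx, dtype=int)
        self.flexible_idx = np.asarray(self.flexible_idx, dtype=int)
        if np.intersect1d(self.fixed_idx, self.mobile_idx).size:
            raise SamplingError("fixed and mobile bodies overlap")

    def copy(self) -> "RigidBodySystem":
        return RigidBodySystem(
            molecule=self.molecule.copy(),
            fixed_idx=self.fixed_idx.copy(),
            mobile_idx=self.mobile_idx.copy(),
            flexible_idx=self.flexible_idx.copy(),
            dihedrals=[Dihedral(d.a, d.b, d.moved.copy(), d.kind) for d in self.dihedrals],
            bonds=list(self.bonds),
        )

    def body_group(self) -> np.ndarray:
        """Per-atom rigid-group id (0 fixed, 1 mobile, -1 flexible)."""
        g = np.full(len(self.molecule), -1, dtype=int)
        g[self.fixed_idx] = 0
        g[self.mobile_idx] = 1
        return g


def excluded_volume(
    molecule_or_coords,
    *,
    radii: np.ndarray | None = None,
    k: float = 1.0,
    group: np.ndarray | None = None,
    exclude_pairs: set[tuple[int, int]] | None = None,
) -> float:
    """Quadratic clash penalty Σ k·(rᵢ+rⱼ−dᵢⱼ)² over overlapping pairs.

    Pairs within the same rigid group (``group[i] == group[j] >= 0``) and
    explicitly excluded (bonded) pairs do not contribute.
    """
    if isinstance(molecule_or_coords, Molecule):
        coords = molecule_or_coords.coords
        if radii is None:
            radii = molecule_or_coords.vdw_radii()
    else:
        coords = np.asarray(molecule_or_coords, dtype=float)
        if radii is None:
            raise SamplingError("radii required for bare coordinates")
    n = coords.shape[0]
    if n < 2:
        return 0.0
    d = cdist(coords, coords)
    rsum = radii[:, None] + radii[None, :]
    overlap = rsum - d
    mask = np.triu(overlap > 0, k=1)
    if group is not None:
        same = (group[:, None] == group[None, :]) & (group[:, None] >= 0)
        mask &= ~same
    if exclude_pairs:
        for i, j in exclude_pairs:
            mask[min(i, j), max(i, j)] = False
    return float(k * np.sum(overlap[mask] ** 2))


@dataclass
class MCConfig:
    """Monte Carlo run settings; ``seed`` is recorded in the trajectory."""

    n_steps: int = 500
    moves_per_step: int = 100
    rotation_step: float = 5e-2  # rad
    translation_step: float = 5e-2  # Å
    dihedral_std_terminus: float = 5e-2  # rad
    dihedral_std_linker: float = 5e-3  # rad
    temperature: float = 1.0
    seed: int = 0
    weight_mode: str = "bayesian"  # "bayesian" or "fixed"
    fixed_weight: float = 1.0
    optimize_c1c2_every: int = 0  # 0 = never; docking workflows set 1
    snapshot_every: int = 1
    stall_window: int = 100
    ev_k: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rotation_step", "translation_step", "dihedral_std_terminus", "dihedral_std_linker"):
            if getattr(self, name) < 0:
                raise SamplingError(f"{name} must be >= 0")
        if self.weight_mode not in ("bayesian", "fixed"):
            raise SamplingError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class TrajectoryRecord:
    """Per-step traces of a Monte Carlo run plus pose/coordinate snapshots."""

    chi2: np.ndarray
    score: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray
    weight: np.ndarray
    acceptance: np.ndarray  # accepted moves per step
    moves_per_step: int
    seed: int
    poses: list = field(default_factory=list)  # (quat, com) of mobile body per snapshot
    snapshots: list = field(default_factory=list)  # full coordinate snapshots
    final_system: RigidBodySystem | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(len(self.chi2)),
                "chi2": self.chi2,
                "score": self.score,
                "gamma": self.gamma,
                "sigma": self.sigma,
                "weight": self.weight,
                "acceptance_rate": self.acceptance / max(self.moves_per_step, 1),
            }
        )


class _Restraint:
    """Forward model + Bayesian nuisance state shared by the samplers.

    Per-atom amplitudes (which depend on c1, c2 and the frozen hydration
    weights) are cached and refreshed only when c1/c2 are re-optimized.
    """

    def __init__(self, system: RigidBodySystem, exp: SAXSProfile, config: MCConfig, table=None):
        self.system = system
        self.exp = exp
        self.config = config
        self.table = table
        self.nuisance = bayes.NuisanceParams()
        self.radii = system.molecule.vdw_radii()
        self.group = system.body_group()
        self.exclude = self._bond_exclusions(system.bonds)
        self._refresh_amplitudes()

    def _bond_exclusions(self, bonds) -> set[tuple[int, int]]:
        """1-2 and 1-3 pairs along the declared bond topology."""
        adj: dict[int, set[int]] = {}
        for i, j in bonds:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        pairs: set[tuple[int, int]] = set()
        for i, j in bonds:
            pairs.add((min(i, j), max(i, j)))
            for k in adj.get(j, ()):  # 1-3 via j
                if k != i:
                    pairs.add((min(i, k), max(i, k)))
            for k in adj.get(i, ()):
                if k != j:
                    pairs.add((min(j, k), max(j, k)))
        return pairs

    def _refresh_amplitudes(self) -> None:
        mol = self.system.molecule
        sw = None
        if self.nuisance.c2 != 0.0:
            sw = hydration_surface_weights(mol)
        self.F = atom_amplitudes(
            mol, self.exp.q, self.nuisance.c1, self.nuisance.c2, table=self.table, surface_weights=sw
        )

    def calc_intensity(self, coords: np.ndarray) -> np.ndarray:
        return debye_intensity(coords, self.F, self.exp.q)

    def chi2(self, coords: np.ndarray) -> float:
        return bayes.chi_square(self.exp, self.calc_intensity(coords), self.nuisance.gamma)

    def ev(self, coords: np.ndarray) -> float:
        return excluded_volume(
            coords, radii=self.radii, k=self.config.ev_k, group=self.group, exclude_pairs=self.exclude
        )

    def weight(self) -> float:
        if self.config.weight_mode == "fixed":
            return self.config.fixed_weight
        return self.exp.M / (2.0 * self.nuisance.sigma ** 2)

    def energy(self, coords: np.ndarray) -> tuple[float, float]:
        chi2 = self.chi2(coords)
        return self.weight() * chi2 + self.ev(coords), chi2

    def update_nuisance(self, coords: np.ndarray, step: int) -> None:
        """Refresh γ (always) and σ (Bayesian mode) to maximum posterior;
        re-run the c1/c2 grid when scheduled."""
        every = self.config.optimize_c1c2_every
        if every > 0 and step % every == 0:
            mol = replace_coords(self.system.molecule, coords)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nuis = bayes.optimize_c1_c2(self.exp, mol, table=self.table)
            if self.config.weight_mode == "fixed":
                nuis = bayes.NuisanceParams(
                    gamma=nuis.gamma, c1=nuis.c1, c2=nuis.c2, sigma=self.nuisance.sigma
                )
            self.nuisance = nuis
            self._refresh_amplitudes()
            return
        calc = self.calc_intensity(coords)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gamma = bayes.map_gamma(self.exp, calc)
            if gamma <= 0:
                gamma = np.finfo(float).tiny
            chi2 = bayes.chi_square(self.exp, calc, gamma)
            sigma = self.nuisance.sigma if self.config.weight_mode == "fixed" else bayes.map_sigma(chi2)
        self.nuisance = bayes.NuisanceParams(
            gamma=gamma, c1=self.nuisance.c1, c2=self.nuisance.c2, sigma=sigma
        )


def replace_coords(mol: Molecule, coords: np.ndarray) -> Molecule:
    out = mol.copy()
    out.coords = np.asarray(coords, dtype=float).copy()
    return out


def randomize_start(system: RigidBodySystem, seed: int, *, margin: float = 2.0) -> RigidBodySystem:
    """Place the mobile body at a uniform random orientation and a random
    clash-free position on an enlarged bounding sphere around the fixed body."""
    rng = np.random.default_rng(seed)
    out = system.copy()
    coords = out.molecule.coords
    fixed = coords[out.fixed_idx]
    mobile = coords[out.mobile_idx]
    radii = out.molecule.vdw_radii()
    group = out.body_group()
    fc = fixed.mean(axis=0)
    r_fixed = np.linalg.norm(fixed - fc, axis=1).max()
    r_mobile = np.linalg.norm(mobile - mobile.mean(axis=0), axis=1).max()
    base = r_fixed + r_mobile + margin
    for attempt in range(10_000):
        q = random_quat(rng)
        R = quat_to_matrix(q)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = base * (1.0 + 0.5 * rng.random())
        com = fc + dist * direction
        new_mobile = (mobile - mobile.mean(axis=0)) @ R.T + com
        trial = coords.copy()
        trial[out.mobile_idx] = new_mobile
        if excluded_volume(trial, radii=radii, k=1.0, group=group) == 0.0:
            out.molecule.coords = trial
            return out
    raise SamplingError("could not place mobile body clash-free in 10^4 attempts")


def _metropolis(rng: np.random.Generator, delta_e: float, temperature: float) -> bool:
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / temperature)


def _run_mc(system: RigidBodySystem, exp: SAXSProfile, config: MCConfig, propose, table=None) -> TrajectoryRecord:
    """Shared Metropolis driver: blocks of moves alternating with nuisance updates."""
    rng = np.random.default_rng(config.seed)
    sys_ = system.copy()
    restraint = _Restraint(sys_, exp, config, table=table)
    coords = sys_.molecule.coords.copy()
    restraint.update_nuisance(coords, step=0)
    energy, chi2 = restraint.energy(coords)

    n = config.n_steps
    tr_chi2 = np.empty(n)
    tr_score = np.empty(n)
    tr_gamma = np.empty(n)
    tr_sigma = np.empty(n)
    tr_weight = np.empty(n)
    tr_acc = np.zeros(n, dtype=int)
    poses, snapshots = [], []
    stall = 0
    for step in range(n):
        accepted = 0
        for _ in range(config.moves_per_step):
            new_coords = propose(coords, rng)
            if new_coords is None:
                accepted += 1  # identity proposal: ΔE = 0 always accepts
                continue
            new_energy, new_chi2 = restraint.energy(new_coords)
            if _metropolis(rng, new_energy - energy, config.temperature):
                coords, energy, chi2 = new_coords, new_energy, new_chi2
                accepted += 1
        restraint.update_nuisance(coords, step=step + 1)
        energy, chi2 = restraint.energy(coords)
        tr_chi2[step] = chi2
        nuis = restraint.nuisance
        tr_gamma[step] = nuis.gamma
        tr_sigma[step] = nuis.sigma
        tr_weight[step] = restraint.weight()
        tr_score[step] = energy + (exp.M * np.log(nuis.sigma) if config.weight_mode == "bayesian" else 0.0)
        tr_acc[step] = accepted
        stall = stall + 1 if accepted == 0 else 0
        if stall == config.stall_window:
            logger.warning("no accepted moves in %d consecutive steps (step %d)", stall, step)
        if (step + 1) % max(config.snapshot_every, 1) == 0:
            mob = coords[sys_.mobile_idx]
            ref = system.molecule.coords[sys_.mobile_idx]
            from .geometry import kabsch

            R, _, _ = kabsch(ref - ref.mean(axis=0), mob - mob.mean(axis=0))
            poses.append((matrix_to_quat(R), mob.mean(axis=0).copy()))
            snapshots.append(coords.copy())
    sys_.molecule.coords = coords
    return TrajectoryRecord(
        chi2=tr_chi2,
        score=tr_score,
        gamma=tr_gamma,
        sigma=tr_sigma,
        weight=tr_weight,
        acceptance=tr_acc,
        moves_per_step=config.moves_per_step,
        seed=config.seed,
        poses=poses,
        snapshots=snapshots,
        final_system=sys_,
    )


def rigid_dock(system: RigidBodySystem, exp: SAXSProfile, config: MCConfig, table=None) -> TrajectoryRecord:
    """Rigid-body docking of the mobile body around the fixed body.

    Each step performs ``moves_per_step`` Metropolis rotation/translation
    proposals of the mobile body, then refreshes γ and σ (and, when
    scheduled, c1/c2) to their maximum-posterior values.
    """
    mobile_idx = system.mobile_idx

    def propose(coords: np.ndarray, rng: np.random.Generator):
        new = coords.copy()
        mob = new[mobile_idx]
        com = mob.mean(axis=0)
        axis = rng.normal(size=3)
        angle = rng.normal(0.0, config.rotation_step)
        shift = rng.normal(0.0, config.translation_step, size=3)
        if config.rotation_step > 0 and np.linalg.norm(axis) > 0:
            R = rotation_about_axis(axis, angle)
            mob = (mob - com) @ R.T + com
        new[mobile_idx] = mob + shift
        return new

    return _run_mc(system, exp, config, propose, table=table)


def dihedral_refine(system: RigidBodySystem, exp: SAXSProfile, config: MCConfig, table=None) -> TrajectoryRecord:
    """Internal-coordinate refinement of the flexible segments.

    Each move Gaussian-perturbs one randomly chosen rotatable dihedral
    (std per segment kind) and rigidly rotates the downstream atoms about the
    dihedral axis, so covalent geometry is preserved by construction.
    """
    if not system.dihedrals:
        raise SamplingError("no rotatable dihedrals defined on this system")
    dihedrals = system.dihedrals

    def propose(coords: np.ndarray, rng: np.random.Generator):
        d = dihedrals[rng.integers(len(dihedrals))]
        std = config.dihedral_std_terminus if d.kind == "terminus" else config.dihedral_std_linker
        angle = rng.normal(0.0, std)
        if std == 0.0:
            return None  # identity move
        axis = coords[d.b] - coords[d.a]
        if np.linalg.norm(axis) == 0:
            return None
        R = rotation_about_axis(axis, angle)
        new = coords.copy()
        new[d.moved] = (coords[d.moved] - coords[d.b]) @ R.T + coords[d.b]
        return new

    return _run_mc(system, exp, config, propose, table=table)


def fixed_weight_run(
    system: RigidBodySystem,
    exp: SAXSProfile,
    weight: float,
    config: MCConfig,
    *,
    mover: str = "rigid",
    table=None,
) -> TrajectoryRecord:
    """Same samplers with energy = weight·χ² + excluded volume; σ never updated."""
    if weight < 0:
        raise SamplingError("weight must be >= 0")
    cfg = replace(config, weight_mode="fixed", fixed_weight=weight)
    if mover == "rigid":
        return rigid_dock(system, exp, cfg, table=table)
    return dihedral_refine(system, exp, cfg, table=table)
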