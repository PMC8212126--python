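"""Construction of missing linker and terminal residues between fixed domains.

The build is staged the way coarse structure-completion protocols do it:

1. a Cα path from the start anchor to the end anchor that avoids the fixed
   domains (grow-and-repel heuristic: straight line, then pushed out of
   obstacle exclusion spheres),
2. Cα-level minimization with a harmonic restraint between consecutive Cα
   atoms (target D = 3.86 Å, the trans peptide Cα–Cα distance) plus volume
   exclusion in which linker Cα atoms have diameter D and all other atoms
   diameter 2D (pushing the linker outside the protein), steepest descent
   followed by conjugate gradient,
3. all-atom placement: backbone (+Cβ) atoms seeded uniformly in a sphere of
   diameter D around each Cα, then minimized first under bonded (distance-
   network) restraints alone, then with volume exclusion switched on.

Bonded ideal values come from standard residue topology (harmonic distance
restraints stand in for the full bonded parameter set, including 1-3
surrogates for angles and a Cα(i)–Cα(i+1) surrogate for the trans ω).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.distance import cdist

from .geometry import place_atom_nerf
from .molecule import Molecule, concatenate

__all__ = [
    "LinkerSpec",
    "MinimizationSchedule",
    "build_ca_path",
    "minimize_ca",
    "place_all_atoms",
    "attach_termini",
    "build_linker",
    "linker_geometry_ok",
]

CA_CA = 3.86  # trans peptide Cα–Cα target distance, Å

# ideal backbone distances, Å (bond + 1-3 angle surrogates + ω surrogate)
_BOND = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.521,
    ("C", "N+"): 1.329,  # peptide bond to next residue
}
_ANGLE13 = {
    ("N", "C"): 2.46,
    ("CA", "O"): 2.40,
    ("N", "CB"): 2.46,
    ("C", "CB"): 2.50,
    ("CA", "N+"): 2.43,
    ("O", "N+"): 2.25,
    ("C", "CA+"): 2.44,
}
_OMEGA14 = {("CA", "CA+"): CA_CA}

_CLASH_RADII = {"N": 1.55, "C": 1.7, "O": 1.52, "S": 1.8, "BEAD": 2.5}

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


class LinkerError(ValueError):
    pass


@dataclass
class LinkerSpec:
    """Linker description: sequence, anchor Cα positions, obstacle domains."""

    sequence: str
    start_anchor: np.ndarray
    end_anchor: np.ndarray
    obstacle: Molecule | None = None
    target_distance: float = CA_CA
    anchor_exclude_indices: np.ndarray | None = None  # obstacle atoms bonded to the chain
    anchor_free_radius: float = 4.5  # obstacle atoms this close to an anchor are
    # treated as the anchor's covalent/sequence neighbors: no exclusion with them

    def __post_init__(self) -> None:
        self.start_anchor = np.asarray(self.start_anchor, dtype=float).reshape(3)
        self.end_anchor = np.asarray(self.end_anchor, dtype=float).reshape(3)
        if self.target_distance <= 0:
            raise LinkerError("target distance must be positive")
        for ch in self.sequence:
            if ch.upper() not in _THREE:
                raise LinkerError(f"unknown residue letter {ch!r}")


@dataclass
class MinimizationSchedule:
    """Ordered minimization phases: (method, steps)."""

    phases: list[tuple[str, int]] = field(
        default_factory=lambda: [("steepest-descent", 1000), ("conjugate-gradient", 1000)]
    )

    def __post_init__(self) -> None:
        for method, steps in self.phases:
            if method not in ("steepest-descent", "conjugate-gradient"):
                raise LinkerError(f"unknown minimization method {method!r}")
            if steps <= 0:
                raise LinkerError("phase steps must be positive")


def _run_schedule(fg, x0: np.ndarray, schedule: MinimizationSchedule) -> np.ndarray:
    x = x0.copy()
    for method, steps in schedule.phases:
        if method == "steepest-descent":
            x = _steepest_descent(fg, x, steps)
        else:
            res = _scipy_minimize(fg, x, jac=True, method="CG", options={"maxiter": steps, "gtol": 1e-10})
            if res.fun <= fg(x)[0]:
                x = res.x
    return x


def _steepest_descent(fg, x: np.ndarray, steps: int, step0: float = 1e-2) -> np.ndarray:
    e, g = fg(x)
    step = step0
    for _ in range(steps):
        gn = np.linalg.norm(g)
        if gn < 1e-12:
            break
        trial = x - step * g
        e_t, g_t = fg(trial)
        if e_t <= e:
            x, e, g = trial, e_t, g_t
            step *= 1.2
        else:
            step *= 0.5
    return x


def build_ca_path(spec: LinkerSpec, seed: int = 0, *, exclusion: float | None = None) -> np.ndarray:
    """Initial Cα positions connecting the anchors around the obstacles.

    Points start on the straight anchor-to-anchor line and are iteratively
    pushed out of each obstacle atom's exclusion sphere along the repulsion
    gradient (a random perpendicular kick breaks exact alignment).  Returns
    an (n_res, 3) array; empty sequence validates anchors and returns (0, 3).
    """
    n = len(spec.sequence)
    D = spec.target_distance
    rng = np.random.default_rng(seed)
    if n == 0:
        if not np.all(np.isfinite(spec.start_anchor)) or not np.all(np.isfinite(spec.end_anchor)):
            raise LinkerError("non-finite anchors")
        return np.zeros((0, 3))
    ts = np.arange(1, n + 1) / (n + 1)
    path = spec.start_anchor[None, :] + ts[:, None] * (spec.end_anchor - spec.start_anchor)[None, :]
    if spec.obstacle is None or len(spec.obstacle) == 0:
        return path
    excl = exclusion if exclusion is not None else 1.5 * D  # linker radius D/2 + obstacle radius D
    obs = spec.obstacle.coords
    for _iteration in range(200):
        d = cdist(path, obs)
        worst = d.min(axis=1)
        if np.all(worst >= excl):
            return path
        for i in range(n):
            j = int(np.argmin(d[i]))
            if d[i, j] >= excl:
                continue
            away = path[i] - obs[j]
            norm = np.linalg.norm(away)
            if norm < 1e-9:
                away = rng.normal(size=3)
                norm = np.linalg.norm(away)
            path[i] = obs[j] + away / norm * (excl + 0.1 + 0.2 * rng.random())
    raise LinkerError("could not construct a clash-free Cα path (anchors buried?)")


def _ca_energy_fn(spec: LinkerSpec):
    """Energy/gradient closure for Cα-level minimization.

    Consecutive-Cα harmonic (k = 10 per Å²) including the anchor bonds, plus
    one-sided quadratic volume exclusion: linker–linker contact D
    (non-consecutive pairs), linker–obstacle contact 1.5·D.
    """
    D = spec.target_distance
    k_bond, k_clash = 10.0, 10.0
    start, end = spec.start_anchor, spec.end_anchor
    obs = None
    if spec.obstacle is not None and len(spec.obstacle):
        # anchor atoms are covalent neighbors of the chain: no exclusion with them
        keep = np.ones(len(spec.obstacle), dtype=bool)
        if spec.anchor_exclude_indices is not None:
            keep[np.asarray(spec.anchor_exclude_indices, int)] = False
        d_start = np.linalg.norm(spec.obstacle.coords - start, axis=1)
        d_end = np.linalg.norm(spec.obstacle.coords - end, axis=1)
        keep &= (d_start > spec.anchor_free_radius) & (d_end > spec.anchor_free_radius)
        obs = spec.obstacle.coords[keep]

    def fg(x: np.ndarray):
        P = x.reshape(-1, 3)
        n = P.shape[0]
        chain = np.vstack([start, P, end])
        diffs = chain[1:] - chain[:-1]
        dists = np.linalg.norm(diffs, axis=1)
        dev = dists - D
        e = k_bond * float(np.sum(dev ** 2))
        g_chain = np.zeros_like(chain)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dists[:, None] > 1e-12, diffs / dists[:, None], 0.0)
        f = 2.0 * k_bond * dev[:, None] * unit
        g_chain[1:] += f
        g_chain[:-1] -= f
        g = g_chain[1:-1].copy()
        # linker-linker exclusion (skip consecutive)
        if n > 2:
            dmat = cdist(P, P)
            iu, ju = np.triu_indices(n, k=2)
            ov = D - dmat[iu, ju]
            hit = ov > 0
            if np.any(hit):
                i_h, j_h, ov_h = iu[hit], ju[hit], ov[hit]
                e += k_clash * float(np.sum(ov_h ** 2))
                dvec = P[i_h] - P[j_h]
                dn = dmat[i_h, j_h][:, None]
                grad_pair = -2.0 * k_clash * ov_h[:, None] * dvec / np.maximum(dn, 1e-12)
                np.add.at(g, i_h, grad_pair)
                np.add.at(g, j_h, -grad_pair)
        if obs is not None:
            dmat = cdist(P, obs)
            contact = 1.5 * D
            ov = contact - dmat
            hit = ov > 0
            if np.any(hit):
                i_h, j_h = np.nonzero(hit)
                ov_h = ov[hit]
                e += k_clash * float(np.sum(ov_h ** 2))
                dvec = P[i_h] - obs[j_h]
                dn = dmat[i_h, j_h][:, None]
                grad_pair = -2.0 * k_clash * ov_h[:, None] * dvec / np.maximum(dn, 1e-12)
                np.add.at(g, i_h, grad_pair)
        return e, g.ravel()

    return fg


def minimize_ca(
    path: np.ndarray,
    spec: LinkerSpec,
    schedule: MinimizationSchedule | None = None,
) -> np.ndarray:
    """Relax a Cα path under the harmonic-spacing + exclusion energy.

    Anchors stay fixed; returns the minimized (n_res, 3) path.  The default
    schedule is 1,000 steepest-descent then 1,000 conjugate-gradient steps.
    """
    path = np.asarray(path, dtype=float).reshape(-1, 3)
    if path.shape[0] == 0:
        return path
    schedule = schedule or MinimizationSchedule()
    fg = _ca_energy_fn(spec)
    x = _run_schedule(fg, path.ravel(), schedule)
    return x.reshape(-1, 3)


def _residue_atoms(letter: str, with_cb: bool) -> list[str]:
    atoms = ["N", "CA", "C", "O"]
    if with_cb and letter.upper() != "G":
        atoms.append("CB")
    return atoms


def _linker_restraints(spec: LinkerSpec, atom_index: dict, n_res: int):
    """(i, j, d0) harmonic distance restraints for the all-atom network."""
    terms: list[tuple[int, int, float]] = []

    def add(i_res, a, j_res, b, d0):
        ia, ib = atom_index.get((i_res, a)), atom_index.get((j_res, b))
        if ia is not None and ib is not None:
            terms.append((ia, ib, d0))

    for r in range(n_res):
        for (a, b), d0 in _BOND.items():
            if b == "N+":
                continue
            add(r, a, r, b, d0)
        for (a, b), d0 in _ANGLE13.items():
            if b.endswith("+"):
                continue
            add(r, a, r, b, d0)
        if r + 1 < n_res:
            add(r, "C", r + 1, "N", _BOND[("C", "N+")])
            add(r, "CA", r + 1, "N", _ANGLE13[("CA", "N+")])
            add(r, "O", r + 1, "N", _ANGLE13[("O", "N+")])
            add(r, "C", r + 1, "CA", _ANGLE13[("C", "CA+")])
            add(r, "CA", r + 1, "CA", _OMEGA14[("CA", "CA+")])
    return terms


def place_all_atoms(
    ca_path: np.ndarray,
    spec: LinkerSpec,
    seed: int = 0,
    *,
    with_cb: bool = True,
    clash_tol: float = 0.01,
    clash_scale: float = 0.8,
) -> Molecule:
    """Build backbone (+Cβ) atoms around a minimized Cα path.

    Atoms are initialized uniformly in a sphere of diameter D around their
    Cα; phase 1 minimizes the bonded distance network (250 steepest descent +
    1,000 conjugate gradient), phase 2 adds volume exclusion and repeats the
    same schedule.  A residual clash above ``clash_tol`` raises (the caller
    retries with a fresh seed).
    """
    ca_path = np.asarray(ca_path, dtype=float).reshape(-1, 3)
    n_res = len(spec.sequence)
    if ca_path.shape[0] != n_res:
        raise LinkerError("Cα path length must match the sequence")
    if n_res == 0:
        return Molecule(
            element=np.array([], dtype=object),
            resid=np.array([], dtype=int),
            resname=np.array([], dtype=object),
            atom_name=np.array([], dtype=object),
            coords=np.zeros((0, 3)),
        )
    rng = np.random.default_rng(seed)
    D = spec.target_distance
    names, elements, res_ids, res_names, init = [], [], [], [], []
    atom_index: dict[tuple[int, str], int] = {}
    ca_indices = []
    for r, letter in enumerate(spec.sequence):
        for name in _residue_atoms(letter, with_cb):
            atom_index[(r, name)] = len(names)
            names.append(name)
            elements.append(name[0])
            res_ids.append(r + 1)
            res_names.append(_THREE[letter.upper()])
            if name == "CA":
                ca_indices.append(len(init))
                init.append(ca_path[r].copy())
            else:
                while True:  # uniform in sphere of diameter D
                    p = rng.uniform(-D / 2, D / 2, size=3)
                    if np.linalg.norm(p) <= D / 2:
                        break
                init.append(ca_path[r] + p)
    init = np.array(init)
    n_atoms = init.shape[0]
    terms = _linker_restraints(spec, atom_index, n_res)
    ti = np.array([t[0] for t in terms])
    tj = np.array([t[1] for t in terms])
    td = np.array([t[2] for t in terms])
    k_bond = 100.0
    # anchor pseudo-bonds: previous-domain Cα to first N, last C to next-domain Cα
    anchors = [
        (atom_index[(0, "N")], spec.start_anchor, _ANGLE13[("CA", "N+")]),
        (atom_index[(n_res - 1, "C")], spec.end_anchor, _ANGLE13[("C", "CA+")]),
        # ω surrogates across the anchor peptide bonds
        (atom_index[(0, "CA")], spec.start_anchor, CA_CA),
        (atom_index[(n_res - 1, "CA")], spec.end_anchor, CA_CA),
    ]
    # weak positional tether keeping each Cα near its path position
    k_pos = 2.0
    ca_idx = np.array(ca_indices)
    ca_targets = ca_path.copy()

    radii = clash_scale * np.array([_CLASH_RADII.get(e, 1.7) for e in elements])
    same_or_adjacent = np.zeros((n_atoms, n_atoms), dtype=bool)
    rid = np.array(res_ids)
    for i in range(n_atoms):
        same_or_adjacent[i] = np.abs(rid - rid[i]) <= 1
    iu, ju = np.triu_indices(n_atoms, k=1)
    clash_pairs = (iu[~same_or_adjacent[iu, ju]], ju[~same_or_adjacent[iu, ju]])
    obs = None
    obs_radii = None
    if spec.obstacle is not None and len(spec.obstacle):
        keep = np.ones(len(spec.obstacle), dtype=bool)
        if spec.anchor_exclude_indices is not None:
            keep[np.asarray(spec.anchor_exclude_indices, int)] = False
        d_start = np.linalg.norm(spec.obstacle.coords - spec.start_anchor, axis=1)
        d_end = np.linalg.norm(spec.obstacle.coords - spec.end_anchor, axis=1)
        keep &= (d_start > spec.anchor_free_radius) & (d_end > spec.anchor_free_radius)
        obs = spec.obstacle.coords[keep]
        obs_radii = clash_scale * spec.obstacle.vdw_radii()[keep]

    def fg(x: np.ndarray, with_clash: bool):
        P = x.reshape(-1, 3)
        g = np.zeros_like(P)
        diffs = P[ti] - P[tj]
        dists = np.linalg.norm(diffs, axis=1)
        dev = dists - td
        e = k_bond * float(np.sum(dev ** 2))
        grad_pair = 2.0 * k_bond * dev[:, None] * diffs / np.maximum(dists[:, None], 1e-12)
        np.add.at(g, ti, grad_pair)
        np.add.at(g, tj, -grad_pair)
        for idx, target, d0 in anchors:
            diff = P[idx] - target
            dist = np.linalg.norm(diff)
            e += k_bond * (dist - d0) ** 2
            g[idx] += 2.0 * k_bond * (dist - d0) * diff / max(dist, 1e-12)
        diff = P[ca_idx] - ca_targets
        e += k_pos * float(np.sum(diff ** 2))
        g[ca_idx] += 2.0 * k_pos * diff
        if with_clash:
            k_clash = 10.0
            i_c, j_c = clash_pairs
            if i_c.size:
                dvec = P[i_c] - P[j_c]
                dd = np.linalg.norm(dvec, axis=1)
                ov = radii[i_c] + radii[j_c] - dd
                hit = ov > 0
                if np.any(hit):
                    e += k_clash * float(np.sum(ov[hit] ** 2))
                    gp = -2.0 * k_clash * ov[hit, None] * dvec[hit] / np.maximum(dd[hit, None], 1e-12)
                    np.add.at(g, i_c[hit], gp)
                    np.add.at(g, j_c[hit], -gp)
            if obs is not None and obs.shape[0]:
                dmat = cdist(P, obs)
                ov = radii[:, None] + obs_radii[None, :] - dmat
                hit = ov > 0
                if np.any(hit):
                    i_h, j_h = np.nonzero(hit)
                    ov_h = ov[hit]
                    e += k_clash * float(np.sum(ov_h ** 2))
                    gp = -2.0 * k_clash * ov_h[:, None] * (P[i_h] - obs[j_h]) / np.maximum(dmat[i_h, j_h][:, None], 1e-12)
                    np.add.at(g, i_h, gp)
        return e, g.ravel()

    schedule = MinimizationSchedule([("steepest-descent", 250), ("conjugate-gradient", 1000)])
    x = _run_schedule(lambda x: fg(x, False), init.ravel(), schedule)
    x = _run_schedule(lambda x: fg(x, True), x, schedule)
    P = x.reshape(-1, 3)

    # residual clash check on the final structure
    def clash_penalty(P):
        e = 0.0
        i_c, j_c = clash_pairs
        if i_c.size:
            dd = np.linalg.norm(P[i_c] - P[j_c], axis=1)
            ov = radii[i_c] + radii[j_c] - dd
            e += float(np.sum(ov[ov > 0] ** 2))
        if obs is not None and obs.shape[0]:
            ov = radii[:, None] + obs_radii[None, :] - cdist(P, obs)
            e += float(np.sum(ov[ov > 0] ** 2))
        return e

    if clash_penalty(P) > clash_tol:
        raise LinkerError("unresolved clash after phase 2; retry with a new seed")
    return Molecule(
        element=np.array(elements, dtype=object),
        resid=np.array(res_ids, dtype=int),
        resname=np.array(res_names, dtype=object),
        atom_name=np.array(names, dtype=object),
        coords=P,
        is_linker=np.ones(n_atoms, dtype=bool),
    )


def linker_geometry_ok(frag: Molecule, spec: LinkerSpec, *, band: float = 0.1) -> bool:
    """Quality gate for a built linker: Cα spacing within D ± band (anchor
    bonds included) and intact peptide connectivity (C–N < 1.5 Å)."""
    n_res = len(spec.sequence)
    cas = np.array(
        [frag.coords[(frag.resid == r) & (frag.atom_name == "CA")][0] for r in range(1, n_res + 1)]
    )
    chain = np.vstack([spec.start_anchor, cas, spec.end_anchor])
    spacings = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    if np.any(np.abs(spacings - spec.target_distance) > band):
        return False
    for r in range(1, n_res):
        c = frag.coords[(frag.resid == r) & (frag.atom_name == "C")][0]
        n_next = frag.coords[(frag.resid == r + 1) & (frag.atom_name == "N")][0]
        if np.linalg.norm(c - n_next) >= 1.5:
            return False
    return True


def build_linker(spec: LinkerSpec, seed: int = 0, *, max_retries: int = 20, with_cb: bool = True) -> Molecule:
    """Full pipeline with acceptance QC: Cα path → minimization → all-atom
    placement; models failing the clash or geometry gates are rejected and
    rebuilt with a fresh seed."""
    last_err: Exception | str | None = None
    for attempt in range(max_retries):
        s = seed + 7919 * attempt
        try:
            path = build_ca_path(spec, s)
            path = minimize_ca(path, spec)
            frag = place_all_atoms(path, spec, s, with_cb=with_cb)
        except LinkerError as err:
            last_err = err
            continue
        if len(spec.sequence) == 0 or linker_geometry_ok(frag, spec):
            return frag
        last_err = "geometry QC failed (Cα spacing or connectivity)"
    raise LinkerError(f"no acceptable linker in {max_retries} retries: {last_err}")


_GROW_GEOM = {
    # bond, angle (rad) for NeRF extension along the backbone
    "N": (1.329, np.deg2rad(116.2)),  # C(i-1)-N(i), angle CA-C-N
    "CA": (1.458, np.deg2rad(121.7)),  # N-CA, angle C-N-CA
    "C": (1.525, np.deg2rad(111.0)),  # CA-C, angle N-CA-C
}


def attach_termini(
    molecule: Molecule,
    n_term_seq: str,
    c_term_seq: str,
    seed: int = 0,
    *,
    max_resample: int = 1000,
    clash_scale: float = 0.8,
) -> Molecule:
    """Grow terminal residues with random φ/ψ, resampling on clash.

    Requires backbone N/CA/C atoms on the chain ends; residues are built
    sequentially with ideal covalent geometry (NeRF) and a trans ω, drawing
    φ/ψ uniformly until the new residue is clash-free against everything
    built so far.  Empty sequences return the input unchanged.
    """
    for ch in (n_term_seq + c_term_seq):
        if ch.upper() not in _THREE:
            raise LinkerError(f"unknown residue letter {ch!r}")
    if not n_term_seq and not c_term_seq:
        return molecule.copy()
    rng = np.random.default_rng(seed)
    out = molecule.copy()
    radii_all = clash_scale * out.vdw_radii()

    def backbone(resid: int):
        sel = {}
        for name in ("N", "CA", "C"):
            idx = np.where((out.resid == resid) & (out.atom_name == name))[0]
            if idx.size != 1:
                raise LinkerError(f"residue {resid} lacks a unique backbone atom {name}")
            sel[name] = out.coords[idx[0]]
        return sel

    def grow(seq: str, direction: str):
        nonlocal out, radii_all
        if not seq:
            return
        resid_min, resid_max = int(out.resid.min()), int(out.resid.max())
        if direction == "C":
            prev = backbone(resid_max)
            frame = (prev["N"], prev["CA"], prev["C"])  # A, B, C of NeRF
            next_id = resid_max + 1
            step_id = 1
        else:
            prev = backbone(resid_min)
            frame = (prev["C"], prev["CA"], prev["N"])  # grow backwards
            next_id = resid_min - 1
            step_id = -1
        for letter in seq:
            placed = None
            for _try in range(max_resample):
                phi = rng.uniform(-np.pi, np.pi)
                psi = rng.uniform(-np.pi, np.pi)
                a, b, c = frame
                if direction == "C":
                    n_new = place_atom_nerf(a, b, c, *_GROW_GEOM["N"], psi)
                    ca_new = place_atom_nerf(b, c, n_new, *_GROW_GEOM["CA"], np.pi)
                    c_new = place_atom_nerf(c, n_new, ca_new, *_GROW_GEOM["C"], phi)
                    o_new = place_atom_nerf(n_new, ca_new, c_new, 1.231, np.deg2rad(120.8), psi + np.pi)
                    atoms = [("N", n_new), ("CA", ca_new), ("C", c_new), ("O", o_new)]
                else:
                    c_new = place_atom_nerf(a, b, c, *_GROW_GEOM["N"], phi)
                    ca_new = place_atom_nerf(b, c, c_new, 1.525, np.deg2rad(116.2), np.pi)
                    n_new = place_atom_nerf(c, c_new, ca_new, 1.458, np.deg2rad(111.0), psi)
                    o_new = place_atom_nerf(n_new, ca_new, c_new, 1.231, np.deg2rad(120.8), phi + np.pi)
                    atoms = [("N", n_new), ("CA", ca_new), ("C", c_new), ("O", o_new)]
                new_xyz = np.array([p for _, p in atoms])
                new_radii = clash_scale * np.array([_CLASH_RADII.get(nm[0], 1.7) for nm, _ in atoms])
                d = cdist(new_xyz, out.coords)
                rsum = new_radii[:, None] + radii_all[None, :]
                # ignore contacts with the bonded previous residue
                bonded = np.abs(out.resid - (next_id - step_id)) == 0
                rsum[:, bonded] = 0.0
                if np.all(d >= rsum):
                    placed = atoms
                    break
            if placed is None:
                raise LinkerError(f"terminus growth stalled after {max_resample} resamples")
            frag = Molecule(
                element=np.array([nm[0] for nm, _ in placed], dtype=object),
                resid=np.full(len(placed), next_id, dtype=int),
                resname=np.array([_THREE[letter.upper()]] * len(placed), dtype=object),
                atom_name=np.array([nm for nm, _ in placed], dtype=object),
                coords=np.array([p for _, p in placed]),
                is_terminus=np.ones(len(placed), dtype=bool),
            )
            out = concatenate([out, frag])
            radii_all = clash_scale * out.vdw_radii()
            frame = (
                (frag.coords[0], frag.coords[1], frag.coords[2])
                if direction == "C"
                else (frag.coords[2], frag.coords[1], frag.coords[0])
            )
            next_id += step_id
    grow(n_term_seq[::-1], "N")  # sequence given N→C; grown outward from the chain start
    grow(c_term_seq, "C")
    return out
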