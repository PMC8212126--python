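"""Self-organizing-map clustering of rigid-body poses.

A pose is summarized by a 7-D descriptor: the mobile body's center of mass in
the fixed body's reference frame (3 Cartesian components, Å) plus the unit
quaternion of the mobile body's rotation relative to its template (4
components; q and −q are the same pose).  Neurons live on a rectangular grid
and are compared to descriptors with a mixed metric

    d(n, m) = ‖com_n − com_m‖ + (2·d_max/π)·arccos|q_n·q_m|

where d_max is the largest space diagonal of the bounding box of the training
descriptors' com coordinates (computed once and frozen).  Neuron updates
interpolate linearly in Cartesian space and by slerp on the unit 4-sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch, matrix_to_quat, quat_to_matrix
from .molecule import Molecule
from .sampling import excluded_volume

__all__ = [
    "Descriptor7",
    "PoseReference",
    "SOMConfig",
    "SOMGrid",
    "make_descriptor",
    "som_distance",
    "train_som",
    "project",
    "reconstruct_pose",
    "cluster_components",
]


class SOMError(ValueError):
    pass


@dataclass
class Descriptor7:
    """COM (Å, fixed-body frame) + unit quaternion of a pose."""

    com: np.ndarray
    quat: np.ndarray

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.quat = np.asarray(self.quat, dtype=float).reshape(4)
        n = np.linalg.norm(self.quat)
        if abs(n - 1.0) > 1e-6:
            raise SOMError(f"quaternion norm {n} != 1")
        self.quat = self.quat / n

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.com, self.quat])


@dataclass
class PoseReference:
    """Templates defining the descriptor frame.

    ``fixed_coords``: the fixed body in its reference orientation (any frame);
    descriptors are expressed after mapping the current fixed body onto it and
    translating its COM to the origin.  ``mobile_coords``: the mobile body
    template whose orientation defines the identity quaternion.
    """

    fixed_coords: np.ndarray
    mobile_coords: np.ndarray

    def __post_init__(self) -> None:
        self.fixed_coords = np.asarray(self.fixed_coords, float)
        self.mobile_coords = np.asarray(self.mobile_coords, float)


def make_descriptor(
    fixed_coords: np.ndarray,
    mobile_coords: np.ndarray,
    reference: PoseReference,
    *,
    rmsd_tol: float = 0.1,
) -> Descriptor7:
    """Descriptor of a pose given current fixed/mobile body coordinates.

    The whole complex is first superposed so the fixed body matches the
    reference template (COM at the origin, constant orientation); the
    descriptor is invariant to any global rigid motion of the complex.
    """
    R, t, rmsd = kabsch(np.asarray(fixed_coords, float), reference.fixed_coords)
    if rmsd > rmsd_tol:
        raise SOMError(f"fixed-body superposition RMSD {rmsd:.3f} > {rmsd_tol}")
    ref_fc = reference.fixed_coords.mean(axis=0)
    mob = np.asarray(mobile_coords, float) @ R.T + t - ref_fc
    com = mob.mean(axis=0)
    ref_mob = reference.mobile_coords - reference.mobile_coords.mean(axis=0)
    Rm, _, _ = kabsch(ref_mob, mob - com)
    return Descriptor7(com=com, quat=matrix_to_quat(Rm))


def _as_matrix(descriptors) -> np.ndarray:
    if isinstance(descriptors, np.ndarray) and descriptors.ndim == 2 and descriptors.shape[1] == 7:
        return np.asarray(descriptors, float)
    return np.array([d.as_array() for d in descriptors])


def som_distance(a, b, dmax: float) -> float:
    """Mixed Euclidean + scaled quaternion-geodesic distance between poses."""
    if dmax <= 0:
        raise SOMError("dmax must be positive")
    av = a.as_array() if isinstance(a, Descriptor7) else np.asarray(a, float)
    bv = b.as_array() if isinstance(b, Descriptor7) else np.asarray(b, float)
    euc = float(np.linalg.norm(av[:3] - bv[:3]))
    dot = min(abs(float(np.dot(av[3:], bv[3:]))), 1.0)
    # identical rotations (up to sign) must give exactly zero: snap the
    # ill-conditioned arccos near 1 to its limit
    geo = 0.0 if dot >= 1.0 - 1e-12 else float(np.arccos(dot))
    return euc + (2.0 * dmax / np.pi) * geo


def _distances_to_neurons(sample: np.ndarray, coms: np.ndarray, quats: np.ndarray, dmax: float) -> np.ndarray:
    euc = np.linalg.norm(coms - sample[:3][None, :], axis=1)
    dots = np.clip(np.abs(quats @ sample[3:]), 0.0, 1.0)
    geo = np.where(dots >= 1.0 - 1e-12, 0.0, np.arccos(np.minimum(dots, 1.0 - 1e-12)))
    return euc + (2.0 * dmax / np.pi) * geo


@dataclass
class SOMConfig:
    epochs: int = 10
    lr_start: float = 0.5
    lr_end: float = 0.01
    radius_start: float | None = None  # default max(shape)/2
    radius_end: float = 1.0
    seed: int = 0


@dataclass
class SOMGrid:
    """Trained map: per-neuron 7-D prototype, hit counts, training config."""

    shape: tuple[int, int]
    coms: np.ndarray  # (K, 3)
    quats: np.ndarray  # (K, 4) unit
    hits: np.ndarray  # (K,)
    dmax: float
    config: SOMConfig

    @property
    def n_neurons(self) -> int:
        return self.shape[0] * self.shape[1]

    def grid_positions(self) -> np.ndarray:
        rows, cols = self.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def bmu(self, descriptor) -> int:
        v = descriptor.as_array() if isinstance(descriptor, Descriptor7) else np.asarray(descriptor, float)
        return int(np.argmin(_distances_to_neurons(v, self.coms, self.quats, self.dmax)))

    def neuron(self, k: int) -> Descriptor7:
        return Descriptor7(com=self.coms[k].copy(), quat=self.quats[k].copy())

    def quantization_error(self, descriptors) -> float:
        X = _as_matrix(descriptors)
        return float(
            np.mean(
                [
                    _distances_to_neurons(x, self.coms, self.quats, self.dmax).min()
                    for x in X
                ]
            )
        )

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "dmax": self.dmax,
            "coms": self.coms.tolist(),
            "quats": self.quats.tolist(),
            "hits": self.hits.tolist(),
            "config": {
                "epochs": self.config.epochs,
                "lr_start": self.config.lr_start,
                "lr_end": self.config.lr_end,
                "radius_start": self.config.radius_start,
                "radius_end": self.config.radius_end,
                "seed": self.config.seed,
            },
        }


def _vector_slerp(quats: np.ndarray, target: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    """Slerp each row of ``quats`` toward ``target`` by per-row fractions."""
    dots = quats @ target
    tgt = np.where(dots[:, None] < 0, -target[None, :], target[None, :])
    dots = np.abs(dots).clip(max=1.0)
    theta = np.arccos(dots)
    small = theta < 1e-6
    out = np.empty_like(quats)
    # linear fallback where the arc is tiny
    out[small] = quats[small] + fracs[small, None] * (tgt[small] - quats[small])
    big = ~small
    if np.any(big):
        st = np.sin(theta[big])
        w0 = np.sin((1.0 - fracs[big]) * theta[big]) / st
        w1 = np.sin(fracs[big] * theta[big]) / st
        out[big] = w0[:, None] * quats[big] + w1[:, None] * tgt[big]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def train_som(descriptors, shape: tuple[int, int], config: SOMConfig | None = None) -> SOMGrid:
    """Classic online SOM with the mixed pose metric.

    BMU search uses :func:`som_distance`; the Gaussian neighborhood lives on
    the grid; COM prototypes move by linear interpolation, quaternion
    prototypes by sign-aligned slerp (renormalized).  d_max is computed once
    from the training set's COM bounding box and frozen.
    """
    X = _as_matrix(descriptors)
    if X.shape[0] == 0:
        raise SOMError("no descriptors to train on")
    config = config or SOMConfig()
    rows, cols = shape
    k = rows * cols
    if X.shape[0] < k / 10:
        import warnings

        warnings.warn(f"only {X.shape[0]} samples for {k} neurons; map may be underdetermined")
    span = X[:, :3].max(axis=0) - X[:, :3].min(axis=0)
    dmax = float(np.linalg.norm(span))
    if dmax <= 0:
        dmax = 1.0  # degenerate cloud: pure quaternion metric with unit scale
    rng = np.random.default_rng(config.seed)
    lo, hi = X[:, :3].min(axis=0), X[:, :3].max(axis=0)
    coms = rng.uniform(lo, hi, size=(k, 3))
    quats = rng.normal(size=(k, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    quats[quats[:, 0] < 0] *= -1

    grid_pos = np.column_stack(
        [np.repeat(np.arange(rows), cols), np.tile(np.arange(cols), rows)]
    ).astype(float)
    radius_start = config.radius_start if config.radius_start is not None else max(rows, cols) / 2.0
    n_samples = X.shape[0]
    total = config.epochs * n_samples
    t = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n_samples)
        for idx in order:
            frac = t / max(total - 1, 1)
            lr = config.lr_start + (config.lr_end - config.lr_start) * frac
            radius = radius_start * (config.radius_end / radius_start) ** frac
            x = X[idx]
            bmu = int(np.argmin(_distances_to_neurons(x, coms, quats, dmax)))
            g2 = np.sum((grid_pos - grid_pos[bmu]) ** 2, axis=1)
            h = lr * np.exp(-g2 / (2.0 * radius ** 2))
            active = h > 1e-4
            coms[active] += h[active, None] * (x[:3][None, :] - coms[active])
            quats[active] = _vector_slerp(quats[active], x[3:], h[active])
            t += 1
    hits = np.zeros(k, dtype=int)
    for x in X:
        hits[int(np.argmin(_distances_to_neurons(x, coms, quats, dmax)))] += 1
    return SOMGrid(shape=(rows, cols), coms=coms, quats=quats, hits=hits, dmax=dmax, config=config)


def project(som: SOMGrid, descriptors, values, reducer: str = "min") -> np.ndarray:
    """Per-neuron aggregate of ``values`` over BMU assignment.

    Returns a (rows, cols) array; neurons with no assigned structure are NaN
    (only neurons with at least one structure carry a value).
    """
    X = _as_matrix(descriptors)
    values = np.asarray(values, dtype=float)
    if values.shape[0] != X.shape[0]:
        raise SOMError("one value per descriptor required")
    if reducer not in ("min", "mean"):
        raise SOMError(f"unknown reducer {reducer!r}")
    buckets: dict[int, list[float]] = {}
    for x, v in zip(X, values):
        buckets.setdefault(int(np.argmin(_distances_to_neurons(x, som.coms, som.quats, som.dmax))), []).append(v)
    out = np.full(som.n_neurons, np.nan)
    for kk, vals in buckets.items():
        out[kk] = min(vals) if reducer == "min" else float(np.mean(vals))
    return out.reshape(som.shape)


def assign(som: SOMGrid, descriptors) -> np.ndarray:
    """BMU index of each descriptor."""
    X = _as_matrix(descriptors)
    return np.array(
        [int(np.argmin(_distances_to_neurons(x, som.coms, som.quats, som.dmax))) for x in X]
    )


def reconstruct_pose(
    neuron: Descriptor7,
    fixed_template: Molecule,
    mobile_template: Molecule,
    *,
    clash_k: float = 1.0,
) -> tuple[Molecule, bool]:
    """Rebuild a two-body structure from a neuron descriptor.

    The mobile template (centered) is rotated by the neuron quaternion and
    translated to the neuron COM; the fixed template stays in the reference
    frame (COM at origin).  Returns the molecule and a clash flag.
    """
    from .molecule import concatenate

    R = quat_to_matrix(neuron.quat)
    fixed = fixed_template.copy()
    fixed.coords = fixed.coords - fixed.coords.mean(axis=0)
    mobile = mobile_template.copy()
    mobile.coords = (mobile.coords - mobile.coords.mean(axis=0)) @ R.T + neuron.com
    fixed.rigid_group = np.zeros(len(fixed), dtype=int)
    mobile.rigid_group = np.ones(len(mobile), dtype=int)
    mol = concatenate([fixed, mobile])
    group = mol.rigid_group
    clash = excluded_volume(mol, k=clash_k, group=group) > 0.0
    return mol, clash


def cluster_components(som: SOMGrid, threshold: float) -> np.ndarray:
    """Group non-empty neurons by connected components.

    Grid-adjacent (4-neighborhood) non-empty neurons are joined when their
    prototype distance is below ``threshold``; returns per-neuron component
    labels (−1 for empty neurons).
    """
    rows, cols = som.shape
    labels = np.full(som.n_neurons, -1, dtype=int)
    nonempty = som.hits > 0
    current = 0
    for start in range(som.n_neurons):
        if not nonempty[start] or labels[start] != -1:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            k = stack.pop()
            r, c = divmod(k, cols)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                j = rr * cols + cc
                if not nonempty[j] or labels[j] != -1:
                    continue
                if som_distance(
                    np.concatenate([som.coms[k], som.quats[k]]),
                    np.concatenate([som.coms[j], som.quats[j]]),
                    som.dmax,
                ) < threshold:
                    labels[j] = current
                    stack.append(j)
        current += 1
    return labels
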