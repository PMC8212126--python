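"""SAXS profile container and 3-column text I/O.

A profile holds an experimental (or simulated) intensity curve I(q) with
per-point uncertainties s(q) on a strictly increasing momentum-transfer grid
q (Å⁻¹).  The text dialect is the common ATSAS-style ``.dat``: whitespace-
separated columns q, I, s; ``#`` starts a comment; extra columns are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SAXSProfile", "read_profile", "write_profile", "resample_to_grid"]


class ProfileError(ValueError):
    """Malformed or invalid SAXS profile."""


@dataclass
class SAXSProfile:
    """Intensity curve with uncertainties on a q grid.

    Attributes
    ----------
    q : (M,) float array, Å⁻¹, strictly increasing
    intensity : (M,) float array, arbitrary units
    error : (M,) float array, same units as intensity, strictly positive
    label : free-text identifier
    """

    q: np.ndarray
    intensity: np.ndarray
    error: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if not (self.q.shape == self.intensity.shape == self.error.shape):
            raise ProfileError("q, intensity and error must have equal lengths")
        if self.q.ndim != 1 or self.q.size < 2:
            raise ProfileError("a profile needs at least 2 points")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)):
            raise ProfileError("non-finite values in profile")
        if np.any(np.diff(self.q) <= 0):
            raise ProfileError("q must be strictly increasing")
        if np.any(self.error <= 0) or not np.all(np.isfinite(self.error)):
            raise ProfileError("errors must be strictly positive and finite")

    @property
    def M(self) -> int:
        """Number of points in the profile."""
        return int(self.q.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SAXSProfile):
            return NotImplemented
        return (
            np.array_equal(self.q, other.q)
            and np.array_equal(self.intensity, other.intensity)
            and np.array_equal(self.error, other.error)
        )


def read_profile(
    path: str | Path,
    *,
    drop_nonpositive_errors: bool = True,
    q_in_inverse_nm: bool = False,
) -> SAXSProfile:
    """Read a 3-column q/I/s text profile.

    Lines starting with ``#`` (and blank lines) are skipped; non-numeric
    header lines are tolerated only before the first data row, matching how
    beamline ``.dat`` headers are usually laid out.  Rows with non-positive
    error are dropped (default) or raise, controlled by
    ``drop_nonpositive_errors``.  ``q_in_inverse_nm`` divides q by 10.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    seen_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                if not seen_data:
                    continue  # trailing header tokens are not expected mid-file
                raise ProfileError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                q, i, s = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                if not seen_data:
                    continue
                raise ProfileError(f"{path}:{lineno}: non-numeric row {stripped!r}") from None
            seen_data = True
            if s <= 0:
                if drop_nonpositive_errors:
                    continue
                raise ProfileError(f"{path}:{lineno}: non-positive error {s}")
            rows.append((q, i, s))
    if len(rows) < 2:
        raise ProfileError(f"{path}: fewer than 2 usable data rows")
    arr = np.array(rows, dtype=float)
    q = arr[:, 0] / 10.0 if q_in_inverse_nm else arr[:, 0]
    return SAXSProfile(q=q, intensity=arr[:, 1], error=arr[:, 2], label=path.stem)


def write_profile(profile: SAXSProfile, path: str | Path) -> None:
    """Write a profile as 3-column text (q I s), full double precision."""
    with open(path, "w") as fh:
        fh.write(f"# {profile.label}\n# q intensity error\n")
        for q, i, s in zip(profile.q, profile.intensity, profile.error):
            fh.write(f"{float(q):.17g} {float(i):.17g} {float(s):.17g}\n")


def resample_to_grid(profile: SAXSProfile, q_grid: np.ndarray) -> SAXSProfile:
    """Linearly interpolate intensity and error onto ``q_grid``.

    Exists for building fixtures; model-vs-experiment comparison evaluates
    the forward model directly on the experimental grid instead.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.min() < profile.q[0] or q_grid.max() > profile.q[-1]:
        raise ProfileError(
            f"resample grid [{q_grid.min()}, {q_grid.max()}] outside profile range "
            f"[{profile.q[0]}, {profile.q[-1]}]"
        )
    return SAXSProfile(
        q=q_grid,
        intensity=np.interp(q_grid, profile.q, profile.intensity),
        error=np.interp(q_grid, profile.q, profile.error),
        label=profile.label,
    )
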