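"""Bayesian SAXS restraint with automatic weighting.

The restraint treats the profile scale γ, the forward-model parameters c1/c2
and the error scale σ as nuisance parameters.  With a Jeffreys prior
p(σ) ∝ 1/σ and flat priors on γ, c1, c2 within bounds, the negative log
likelihood is

    −log p(I | X, γ, c1, c2, σ) = (M / 2σ²)·χ² + M·log σ,
    χ² = (1/M) Σᵢ ((Iᵢ − γ·mᵢ) / sᵢ)²

so the maximum-posterior estimates are closed-form: γ̂ is the weighted
least-squares scale and σ̂² = χ²(γ̂).  The factor M/2σ² is the automatic
weight the data receive; marginalizing σ out yields the equivalent score
(M/2)·log χ², a monotone transform of χ² with no explicit weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .forward import compute_profile
from .profiles import SAXSProfile

__all__ = [
    "NuisanceParams",
    "ScoreResult",
    "chi_square",
    "map_gamma",
    "map_sigma",
    "neg_log_likelihood",
    "marginal_score",
    "restraint_weight",
    "optimize_c1_c2",
    "score_profile",
]

C1_BOUNDS = (0.95, 1.05)
C2_BOUNDS = (-2.0, 4.0)
SIGMA_MIN = 1e-6  # floor for exact fits


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class NuisanceParams:
    """γ (scale), c1 (excluded volume), c2 (hydration), σ (error scale)."""

    gamma: float = 1.0
    c1: float = 1.0
    c2: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ScoreError(f"gamma must be finite and positive, got {self.gamma}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ScoreError(f"sigma must be finite and positive, got {self.sigma}")
        if not (C1_BOUNDS[0] <= self.c1 <= C1_BOUNDS[1]):
            raise ScoreError(f"c1={self.c1} outside {C1_BOUNDS}")
        if not (C2_BOUNDS[0] <= self.c2 <= C2_BOUNDS[1]):
            raise ScoreError(f"c2={self.c2} outside {C2_BOUNDS}")


@dataclass
class ScoreResult:
    chi2: float
    neg_log_like: float
    weight: float  # M / 2σ²
    nuisance: NuisanceParams
    M: int


def _check(exp: SAXSProfile, calc: np.ndarray) -> np.ndarray:
    calc = np.asarray(calc, dtype=float)
    if calc.shape != exp.q.shape:
        raise ScoreError(f"calc length {calc.shape} does not match profile M={exp.M}")
    return calc


def chi_square(exp: SAXSProfile, calc: np.ndarray, gamma: float = 1.0) -> float:
    """(1/M) Σ ((Iᵢ − γ mᵢ)/sᵢ)²; zero iff the scaled fit is exact."""
    calc = _check(exp, calc)
    r = (exp.intensity - gamma * calc) / exp.error
    return float(np.mean(r * r))


def map_gamma(exp: SAXSProfile, calc: np.ndarray) -> float:
    """Closed-form weighted least-squares scale γ̂ = Σ I m/s² / Σ m²/s²."""
    calc = _check(exp, calc)
    w = 1.0 / (exp.error ** 2)
    denom = float(np.sum(w * calc * calc))
    if denom <= 0:
        raise ScoreError("degenerate calc profile (all zero): gamma undefined")
    gamma = float(np.sum(w * exp.intensity * calc) / denom)
    if gamma <= 0:
        warnings.warn(f"maximum-posterior gamma is non-positive ({gamma:.3g}); check data quality")
    return gamma


def map_sigma(chi2: float, sigma_min: float = SIGMA_MIN) -> float:
    """σ̂ = sqrt(χ²), the stationary point of the negative log likelihood.

    An exact fit (χ² = 0) returns the configured floor.
    """
    if chi2 < 0:
        raise ScoreError("chi2 must be non-negative")
    if chi2 <= sigma_min ** 2:
        warnings.warn("chi2 at or below sigma floor; returning sigma_min")
        return sigma_min
    return float(np.sqrt(chi2))


def neg_log_likelihood(exp: SAXSProfile, calc: np.ndarray, nuisance: NuisanceParams) -> float:
    """(M/2σ²)·χ²(γ) + M·log σ."""
    chi2 = chi_square(exp, calc, nuisance.gamma)
    m = exp.M
    return float(m / (2.0 * nuisance.sigma ** 2) * chi2 + m * np.log(nuisance.sigma))


def marginal_score(exp: SAXSProfile, calc: np.ndarray, gamma: float | None = None) -> float:
    """σ-marginalized score (M/2)·log χ²(γ); γ defaults to its MAP value.

    Equals the negative log likelihood at (γ̂, σ̂) minus the constant M/2.
    """
    if gamma is None:
        gamma = map_gamma(exp, calc)
    chi2 = max(chi_square(exp, calc, gamma), SIGMA_MIN ** 2)
    return float(exp.M / 2.0 * np.log(chi2))


def restraint_weight(score: ScoreResult | NuisanceParams, M: int | None = None) -> float:
    """Automatic data weight M/2σ²; at the σ optimum this is M/2χ²."""
    if isinstance(score, ScoreResult):
        return float(score.M / (2.0 * score.nuisance.sigma ** 2))
    if M is None:
        raise ScoreError("M required when passing bare NuisanceParams")
    return float(M / (2.0 * score.sigma ** 2))


def score_profile(exp: SAXSProfile, calc: np.ndarray) -> ScoreResult:
    """Score a computed profile with γ and σ set to maximum posterior."""
    gamma = map_gamma(exp, calc)
    chi2 = chi_square(exp, calc, gamma)
    sigma = map_sigma(chi2)
    nuis = NuisanceParams(gamma=max(gamma, np.finfo(float).tiny), sigma=sigma)
    nll = neg_log_likelihood(exp, calc, nuis)
    return ScoreResult(chi2=chi2, neg_log_like=nll, weight=exp.M / (2 * sigma ** 2), nuisance=nuis, M=exp.M)


def _grid(center: float, half_span: float, bounds: tuple[float, float], n: int) -> np.ndarray:
    lo = max(center - half_span, bounds[0])
    hi = min(center + half_span, bounds[1])
    if hi - lo < 2 * half_span:  # clipped at a boundary: keep full span inside
        if lo == bounds[0]:
            hi = min(lo + 2 * half_span, bounds[1])
        else:
            lo = max(hi - 2 * half_span, bounds[0])
    return np.linspace(lo, hi, n)


def optimize_c1_c2(
    exp: SAXSProfile,
    molecule,
    forward_model=None,
    *,
    n_grid: int = 11,
    c1_bounds: tuple[float, float] = C1_BOUNDS,
    c2_bounds: tuple[float, float] = C2_BOUNDS,
    table=None,
    surface_weights=None,
) -> NuisanceParams:
    """Three-round 11×11 grid search over (c1, c2).

    Round 1 covers the admissible ranges; each refinement round re-centers an
    11×11 grid on the best pair with the grid's total span equal to a 2×2
    block of the previous cells, then half that span, always clipped to the
    bounds.  Before every cell evaluation γ and σ are set to their maximum
    posterior; the score compared is the negative log likelihood at (γ̂, σ̂).
    Ties keep the first cell in row-major (c1-major) order.

    ``forward_model`` defaults to a cached evaluator at the molecule's fixed
    coordinates (the pairwise sinc kernel is reused across the whole grid).
    """
    if forward_model is None:
        from .forward import ProfileEvaluator

        forward_model = ProfileEvaluator(
            molecule, exp.q, table=table, surface_weights=surface_weights
        )

    def cell_score(c1: float, c2: float):
        try:
            calc = forward_model(
                molecule, exp.q, c1, c2, table=table, surface_weights=surface_weights
            ).intensity
            gamma = map_gamma(exp, calc)
            if gamma <= 0:
                gamma = np.finfo(float).tiny
            chi2 = chi_square(exp, calc, gamma)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sigma = map_sigma(chi2)
            score = exp.M / 2.0 * (1.0 + np.log(max(chi2, SIGMA_MIN ** 2)))
        except (FloatingPointError, ValueError):
            return None
        if not np.isfinite(score):
            return None
        return score, gamma, sigma, chi2

    base = ((c1_bounds[1] - c1_bounds[0]) / (n_grid - 1), (c2_bounds[1] - c2_bounds[0]) / (n_grid - 1))
    c1_axis = np.linspace(*c1_bounds, n_grid)
    c2_axis = np.linspace(*c2_bounds, n_grid)
    best = None
    for round_idx in range(3):
        if round_idx > 0:
            # round 2: span = a 2x2 block of round-1 cells (half-span = 1 cell);
            # round 3: half that extent again
            shrink = 1.0 if round_idx == 1 else 0.5
            c1_axis = _grid(best[1], base[0] * shrink, c1_bounds, n_grid)
            c2_axis = _grid(best[2], base[1] * shrink, c2_bounds, n_grid)
        any_finite = False
        for c1 in c1_axis:  # row-major: c1 outer
            for c2 in c2_axis:
                res = cell_score(float(c1), float(c2))
                if res is None:
                    warnings.warn(f"non-finite score at c1={c1:.4g}, c2={c2:.4g}; cell skipped")
                    continue
                any_finite = True
                score, gamma, sigma, chi2 = res
                if best is None or score < best[0]:
                    best = (score, float(c1), float(c2), gamma, sigma, chi2)
        if not any_finite:
            raise ScoreError("all grid cells produced non-finite scores")
    _, c1, c2, gamma, sigma, _ = best
    return NuisanceParams(gamma=max(gamma, np.finfo(float).tiny), c1=c1, c2=c2, sigma=sigma)
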