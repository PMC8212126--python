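"""Genetic-algorithm selection of a minimal weighted conformer ensemble.

Given a pool of per-conformer theoretical profiles and an experimental
profile, the GA searches for a size-k subset whose weighted mixture

    I_calc(q) = scale · Σₖ wₖ·Iₖ(q),   wₖ ≥ 0, Σ wₖ = 1

minimizes χ² = (1/M) Σᵢ ((I_calc(qᵢ) − I_exp(qᵢ)) / σ_exp(qᵢ))².  Weights and
the global scale are fitted jointly by nonnegative least squares inside the
fitness evaluation (``fit_scale=False`` drops the scale and fits weights on
the simplex directly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .fixtures import ProfilePool

__all__ = ["GAConfig", "EnsembleSolution", "ensemble_chi2", "run_ga", "size_scan"]


class EnsembleError(ValueError):
    pass


@dataclass(frozen=True)
class GAConfig:
    """GA settings: 1,000 generations × population 1,000 by default."""

    ensemble_size: int = 3
    generations: int = 1000
    population: int = 1000
    crossover_rate: float = 0.8
    mutation_rate: float = 1.0  # expected member replacements per offspring
    mutation_mode: str = "per_offspring"  # or "per_gene"
    tournament: int = 2
    elitism: int = 1
    repeats: int = 5
    seed: int = 0
    fit_scale: bool = True

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise EnsembleError("ensemble size must be >= 1")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise EnsembleError("crossover rate must be in [0, 1]")
        if self.mutation_mode not in ("per_offspring", "per_gene"):
            raise EnsembleError(f"unknown mutation mode {self.mutation_mode!r}")


@dataclass
class EnsembleSolution:
    members: list
    weights: np.ndarray
    scale: float
    chi2: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != len(self.members):
            raise EnsembleError("one weight per member required")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise EnsembleError("weights must sum to 1")


def ensemble_chi2(
    pool: ProfilePool,
    members,
    weights: np.ndarray | None = None,
    *,
    fit_scale: bool = True,
) -> tuple[float, float, np.ndarray]:
    """χ² of a weighted mixture of pool members against the experiment.

    With ``weights=None`` (the usual GA path) weights and scale are jointly
    fitted by NNLS on unnormalized coefficients vₖ ≥ 0: scale = Σv, w = v/Σv.
    Identical duplicate members make the fit singular; their weight split is
    resolved uniformly with a warning.  Returns (chi2, scale, weights).
    """
    members = list(members)
    if not members:
        raise EnsembleError("empty member set")
    idx = [pool.ids.index(m) for m in members]
    exp = pool.experiment
    A = (pool.intensities[idx] / exp.error[None, :]).T  # (M, k)
    b = exp.intensity / exp.error
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        mix = weights @ pool.intensities[idx]
        if fit_scale:
            col = mix / exp.error
            denom = float(col @ col)
            scale = max(float(col @ b) / denom, 0.0) if denom > 0 else 0.0
        else:
            scale = 1.0
        resid = b - scale * mix / exp.error
        return float(np.mean(resid ** 2)), scale, weights

    # collapse exact duplicates: NNLS weight split among them is arbitrary
    uniq_cols: dict[bytes, list[int]] = {}
    for j in range(len(members)):
        uniq_cols.setdefault(A[:, j].tobytes(), []).append(j)
    rep = [cols[0] for cols in uniq_cols.values()]
    v_u, _ = nnls(A[:, rep], b)
    v = np.zeros(len(members))
    for vr, cols in zip(v_u, uniq_cols.values()):
        if len(cols) > 1:
            warnings.warn("identical ensemble members: weight split uniformly")
        for j in cols:
            v[j] = vr / len(cols)
    total = v.sum()
    if total <= 0:
        # nothing fits with positive coefficient; fall back to uniform weights
        warnings.warn("degenerate NNLS fit; using uniform weights")
        w = np.full(len(members), 1.0 / len(members))
        return ensemble_chi2(pool, members, weights=w, fit_scale=fit_scale)
    w = v / total
    if fit_scale:
        scale = float(total)
        resid = b - A @ v
    else:
        mix = w @ pool.intensities[idx]
        resid = b - mix / exp.error
        scale = 1.0
    return float(np.mean(resid ** 2)), scale, w


def _fitness(pool: ProfilePool, members: tuple, cache: dict, fit_scale: bool):
    key = frozenset(members)
    if key not in cache:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cache[key] = ensemble_chi2(pool, sorted(key), fit_scale=fit_scale)
    return cache[key]


def run_ga(pool: ProfilePool, config: GAConfig, *, initial: list | None = None) -> EnsembleSolution:
    """Evolve size-k member sets by tournament selection, crossover and mutation.

    Elitism keeps the best candidate; crossover (rate 0.8) exchanges member
    ids between two parents; mutation replaces one member per offspring in
    expectation.  Seeded and reproducible; fitness values are cached per
    member set.
    """
    k = config.ensemble_size
    if pool.size < k:
        raise EnsembleError(f"pool size {pool.size} < ensemble size {k}")
    rng = np.random.default_rng(config.seed)
    ids = np.array(pool.ids, dtype=object)
    cache: dict = {}

    def random_individual() -> tuple:
        return tuple(rng.choice(ids, size=k, replace=False))

    population = [random_individual() for _ in range(config.population)]
    if initial:
        for i, ind in enumerate(initial[: len(population)]):
            population[i] = tuple(ind)

    def chi2_of(ind: tuple) -> float:
        return _fitness(pool, ind, cache, config.fit_scale)[0]

    def repair(ind: list) -> tuple:
        seen = set()
        for i, m in enumerate(ind):
            while m in seen:
                m = ids[rng.integers(pool.size)]
            seen.add(m)
            ind[i] = m
        return tuple(ind)

    scores = np.array([chi2_of(ind) for ind in population])
    for _gen in range(config.generations):
        order = np.argsort(scores)
        elite = [population[i] for i in order[: config.elitism]]
        offspring: list[tuple] = list(elite)
        while len(offspring) < config.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                cand = rng.integers(config.population, size=config.tournament)
                parents.append(population[cand[np.argmin(scores[cand])]])
            p1, p2 = parents
            if rng.random() < config.crossover_rate and k > 1:
                mask = rng.random(k) < 0.5
                child = [p1[i] if mask[i] else p2[i] for i in range(k)]
            else:
                child = list(p1)
            if config.mutation_mode == "per_offspring":
                pos = rng.integers(k)
                child[pos] = ids[rng.integers(pool.size)]
            else:
                for i in range(k):
                    if rng.random() < config.mutation_rate / k:
                        child[i] = ids[rng.integers(pool.size)]
            offspring.append(repair(child))
        population = offspring
        scores = np.array([chi2_of(ind) for ind in population])
    best = population[int(np.argmin(scores))]
    chi2, scale, weights = _fitness(pool, best, cache, config.fit_scale)
    members = sorted(frozenset(best))
    return EnsembleSolution(members=members, weights=weights, scale=scale, chi2=chi2)


def size_scan(pool: ProfilePool, sizes, config: GAConfig):
    """Run the GA over ensemble sizes with seeded repeats.

    Returns a DataFrame with per-size mean, sd and best χ² over repeats
    (repeats differ only by seed) plus the best solutions.
    """
    import pandas as pd

    rows = []
    solutions: dict[int, EnsembleSolution] = {}
    for k in sizes:
        if not 1 <= k <= pool.size:
            raise EnsembleError(f"invalid ensemble size {k}")
        chis = []
        best: EnsembleSolution | None = None
        for r in range(config.repeats):
            cfg = GAConfig(
                ensemble_size=k,
                generations=config.generations,
                population=config.population,
                crossover_rate=config.crossover_rate,
                mutation_rate=config.mutation_rate,
                mutation_mode=config.mutation_mode,
                tournament=config.tournament,
                elitism=config.elitism,
                repeats=config.repeats,
                seed=config.seed + 1000 * r,
                fit_scale=config.fit_scale,
            )
            sol = run_ga(pool, cfg)
            chis.append(sol.chi2)
            if best is None or sol.chi2 < best.chi2:
                best = sol
        solutions[k] = best
        rows.append(
            {"k": k, "chi2_mean": float(np.mean(chis)), "chi2_sd": float(np.std(chis, ddof=1)) if len(chis) > 1 else 0.0, "chi2_best": float(np.min(chis))}
        )
    df = pd.DataFrame(rows)
    df.attrs["solutions"] = solutions
    return df


def group_composition(solution: EnsembleSolution, id_to_group: dict) -> dict:
    """Sum ensemble weights per externally supplied group label."""
    out: dict = {}
    for m, w in zip(solution.members, solution.weights):
        g = id_to_group.get(m, None)
        out[g] = out.get(g, 0.0) + float(w)
    return out
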