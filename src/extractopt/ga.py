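"""Real-coded genetic algorithm over the coded factor box.

The optimizer maximizes a surrogate prediction by internally minimizing its
negative (so the recorded fitness decreases over generations).  Operators
follow the classical single-population toolbox setup: stochastic-uniform
selection over rank-based scaled fitness, elitism, scattered (per-gene
uniform) crossover, and gaussian mutation whose scale shrinks linearly over
the run.  Migration settings are accepted for config fidelity but are no-ops
in a single-population run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import DesignMatrix, decode_levels
from .ann import SurrogateModel

__all__ = ["GaConfig", "OptimumResult", "ga_optimize", "optimize_extraction"]


@dataclass
class GaConfig:
    population_size: int = 20
    elite_count: int = 2
    crossover_fraction: float = 0.8
    mutation_scale_start: float = 0.2   # fraction of box width
    mutation_scale_end: float = 0.02
    migration_fraction: float = 0.2     # accepted but inert (one population)
    migration_interval: int = 20
    max_generations: int = 100
    stall_generations: int = 50
    stall_tol: float = 1e-8
    seed: int = 0
    bounds: np.ndarray = field(
        default_factory=lambda: np.array([[-1.0, 1.0]] * 3))

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if not 0.0 < self.crossover_fraction < 1.0:
            raise ValueError("crossover_fraction must be in (0, 1)")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be < population_size")


@dataclass
class OptimumResult:
    coded: np.ndarray
    decoded: np.ndarray | None
    predicted_yield: float
    best_history: np.ndarray     # per-generation best fitness (negative yield)
    mean_history: np.ndarray
    generations_run: int


def _select(rng: np.random.Generator, scores: np.ndarray, k: int) -> np.ndarray:
    """Stochastic-uniform (SUS) sampling of k parent indices proportional to
    rank-based scaled fitness."""
    order = np.argsort(scores)                    # ascending: best first
    expectation = 1.0 / np.sqrt(np.arange(1, len(scores) + 1))
    probs = np.empty(len(scores))
    probs[order] = expectation / expectation.sum()
    cum = np.cumsum(probs)
    start = rng.uniform(0, 1.0 / k)
    picks = start + np.arange(k) / k
    idx = np.searchsorted(cum, picks)
    return rng.permutation(idx)


def ga_optimize(objective, config: GaConfig | None = None) -> OptimumResult:
    """Maximize ``objective(coded_point) -> float`` over the configured box.

    Non-finite objective values are assigned the worst fitness in their
    generation rather than aborting the run; the best-so-far individual is
    protected by elitism, so best fitness is monotone non-increasing.
    """
    cfg = config or GaConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
    dim = len(lo)
    pop = rng.uniform(lo, hi, size=(cfg.population_size, dim))

    def evaluate(P):
        vals = np.array([objective(p) for p in P], dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            worst = vals[~bad].min() if (~bad).any() else 0.0
            vals[bad] = worst - 1.0
        return -vals                                # minimize negative yield

    scores = evaluate(pop)
    best_hist, mean_hist = [], []
    best_score = np.inf
    stall = 0
    gens = 0
    for gen in range(cfg.max_generations):
        gens = gen + 1
        gen_best = float(scores.min())
        best_hist.append(gen_best)
        mean_hist.append(float(scores.mean()))
        if gen_best < best_score - cfg.stall_tol:
            best_score, stall = gen_best, 0
        else:
            stall += 1
        if stall >= cfg.stall_generations:
            break
        if gen == cfg.max_generations - 1:
            break

        n = cfg.population_size
        n_elite = cfg.elite_count
        n_cross = int(round(cfg.crossover_fraction * (n - n_elite)))
        n_mut = n - n_elite - n_cross
        elite_idx = np.argsort(scores)[:n_elite]
        parents = pop[_select(rng, scores, 2 * n_cross + n_mut)]

        children = []
        for i in range(n_cross):                    # scattered crossover
            p1, p2 = parents[2 * i], parents[2 * i + 1]
            mask = rng.integers(0, 2, dim).astype(bool)
            children.append(np.where(mask, p1, p2))
        frac = gen / max(cfg.max_generations - 1, 1)
        scale = (cfg.mutation_scale_start
                 + (cfg.mutation_scale_end - cfg.mutation_scale_start) * frac)
        for i in range(n_mut):                      # gaussian mutation, shrinking
            p = parents[2 * n_cross + i]
            children.append(p + rng.normal(0, scale * (hi - lo), dim))
        offspring = np.clip(np.array(children), lo, hi)
        pop = np.vstack([pop[elite_idx], offspring])
        scores = np.concatenate([scores[elite_idx], evaluate(offspring)])

    k = int(np.argmin(scores))
    return OptimumResult(
        coded=pop[k].copy(),
        decoded=None,
        predicted_yield=float(-scores[k]),
        best_history=np.array(best_hist),
        mean_history=np.array(mean_hist),
        generations_run=gens,
    )


def optimize_extraction(surrogate: SurrogateModel, design: DesignMatrix,
                        config: GaConfig | None = None) -> OptimumResult:
    """GA-maximize a trained surrogate's predicted yield and decode the
    optimum into physical units via the design's factor scales."""
    cfg = config or GaConfig()
    if surrogate.w1.shape[1] != design.n_factors:
        raise ValueError(
            f"surrogate expects {surrogate.w1.shape[1]} factors, "
            f"design has {design.n_factors}"
        )
    result = ga_optimize(lambda p: float(surrogate.predict(p)[0]), cfg)
    result.decoded = decode_levels(design, result.coded)
    return result
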