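"""Manta Ray Foraging Optimization (MRFO) over the unit hypercube.

MRFO is a swarm metaheuristic with three movement rules.  In *chain
foraging* each member steps toward the member ahead of it in the chain (the
leader steps toward the incumbent best), with an extra pull toward the best.
In *cyclone foraging* members spiral either around the incumbent best
(exploitation, late in the run) or around a freshly drawn random point
(exploration, early in the run).  In *somersault foraging* each member flips
around the best-known position with amplitude set by the somersault factor
``S``.

One population update is: sort members by score (descending, stable), then
per member branch on a uniform draw (< 0.5 cyclone, else chain), re-score
everyone with greedy best tracking, somersault everyone, and re-score again.
The weight coefficients follow the original MRFO formulation:

    alpha = 2 * r * sqrt(|ln r|)
    beta  = 2 * exp(r1 * (T_max - t + 1) / T_max) * sin(2 pi r1)

with ``r``/``r1`` uniform draws.  All positions are clipped back into
``[lower, upper]`` after every move, since decoding requires unit-interval
inputs.

Randomness is reproducible: a master seed spawns an independent generator
per (iteration, member, sweep), so results do not depend on evaluation
order.  The draw order within a member's update is: branch draw, phase draw,
random reference vector (cyclone exploration only), then r (and from it
alpha or beta's r1); the somersault sweep draws r2 then r3.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from mrfopt.encoding import clip_solution

logger = logging.getLogger(__name__)

__all__ = [
    "MRFOParams",
    "UpdateDraws",
    "Population",
    "OptimizationHistory",
    "init_population",
    "chain_update",
    "cyclone_update",
    "somersault_update",
    "update_population",
    "run_mrfo",
]

#: score assigned to a member whose fitness evaluation raised
SENTINEL_WORST = -np.inf


@dataclass(frozen=True)
class MRFOParams:
    """Run parameters for the optimizer.

    ``n_max`` is the population size and ``t_max`` the iteration count
    (both default 10, matching the study configuration this package
    reproduces).  ``somersault_factor`` is the amplitude ``S`` of the
    somersault move.
    """

    n_max: int = 10
    t_max: int = 10
    somersault_factor: float = 2.0
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        if self.somersault_factor <= 0:
            raise ValueError("somersault_factor must be > 0")


@dataclass
class UpdateDraws:
    """The random quantities consumed by one member update.

    Exposed so tests can force exact draw sequences; production code builds
    these from seeded per-(iteration, member, sweep) generators.
    """

    r: float = 0.0
    r1: float = 0.0
    r2: float = 0.0
    r3: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    branch_draw: float = 0.0
    phase_draw: float = 0.0
    reference: Optional[np.ndarray] = None  # cyclone exploration anchor


def _alpha_from(r: float) -> float:
    r = max(r, 1e-12)
    return 2.0 * r * math.sqrt(abs(math.log(r)))


def _beta_from(r1: float, t: int, t_max: int) -> float:
    return 2.0 * math.exp(r1 * (t_max - t + 1) / t_max) * math.sin(2.0 * math.pi * r1)


def _member_rng(seed: int, t: int, i: int, sweep: int) -> np.random.Generator:
    return np.random.default_rng([seed, t, i, sweep])


def draws_for(
    params: MRFOParams, t: int, i: int, sweep: int, dimension: int
) -> UpdateDraws:
    """Build the draw bundle for member ``i`` at iteration ``t``."""
    rng = _member_rng(params.seed, t, i, sweep)
    d = UpdateDraws()
    if sweep == 1:
        d.branch_draw = rng.uniform()
        d.phase_draw = rng.uniform()
        if d.branch_draw < 0.5 and d.phase_draw > t / params.t_max:
            d.reference = params.lower_bound + rng.uniform(size=dimension) * (
                params.upper_bound - params.lower_bound
            )
        d.r = rng.uniform()
        if d.branch_draw < 0.5:
            d.r1 = rng.uniform()
            d.beta = _beta_from(d.r1, t, params.t_max)
        else:
            d.alpha = _alpha_from(d.r)
    else:
        d.r2 = rng.uniform()
        d.r3 = rng.uniform()
    return d


@dataclass
class Population:
    """Current solutions, their scores, and the incumbent best."""

    solutions: List[np.ndarray]
    scores: List[float]
    best_solution: Optional[np.ndarray] = None
    best_score: float = SENTINEL_WORST
    iteration: int = 0

    def __post_init__(self):
        if len(self.solutions) != len(self.scores):
            raise ValueError("solutions and scores must be the same length")

    @property
    def n(self) -> int:
        return len(self.solutions)


@dataclass
class OptimizationHistory:
    """Per-evaluation and per-iteration optimization records."""

    records: List[dict] = field(default_factory=list)  # iteration, member, sweep, score
    per_iteration: List[dict] = field(default_factory=list)

    def log_eval(self, iteration: int, member: int, sweep: int, score: float) -> None:
        self.records.append(
            {"iteration": iteration, "member": member, "sweep": sweep, "score": score}
        )

    def log_iteration(self, iteration: int, best_score: float, best_solution, scores):
        self.per_iteration.append(
            {
                "iteration": iteration,
                "best_score": best_score,
                "best_solution": np.array(best_solution, dtype=float),
                "scores": list(scores),
            }
        )

    @property
    def best_scores(self) -> List[float]:
        return [rec["best_score"] for rec in self.per_iteration]

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "member", "sweep", "score"])
            for rec in self.records:
                w.writerow([rec["iteration"], rec["member"], rec["sweep"], rec["score"]])


# -- movement rules --------------------------------------------------------


def init_population(
    params: MRFOParams, dimension: int, rng: Optional[np.random.Generator] = None
) -> Population:
    """Draw ``n_max`` members element-wise uniform on the bounds."""
    if rng is None:
        rng = _member_rng(params.seed, 0, 0, 0)
    sols = [
        params.lower_bound
        + rng.uniform(size=dimension) * (params.upper_bound - params.lower_bound)
        for _ in range(params.n_max)
    ]
    return Population(solutions=sols, scores=[SENTINEL_WORST] * params.n_max)


def _clip(x: np.ndarray, params: MRFOParams) -> np.ndarray:
    return np.clip(x, params.lower_bound, params.upper_bound)


def cyclone_update(
    x_i: np.ndarray,
    x_prev: np.ndarray,
    x_best: np.ndarray,
    draws: UpdateDraws,
    i: int,
    t: int,
    params: MRFOParams,
) -> np.ndarray:
    """Cyclone foraging: spiral around the best or a random reference.

    The exploration branch (phase draw exceeding ``t / t_max``) anchors on a
    fresh uniform reference vector; the exploitation branch anchors on the
    incumbent best.  The leader (i=1) measures its difference terms against
    itself; later members measure against the member ahead of them.
    """
    r, beta = draws.r, draws.beta
    explore = draws.phase_draw > t / params.t_max
    if explore:
        ref = draws.reference
        if ref is None:
            raise ValueError("exploration branch requires a reference vector")
        ref = np.asarray(ref, dtype=float)
        if i == 1:
            new = ref + r * (ref - x_i) + beta * (ref - x_i)
        else:
            new = ref + r * (x_prev - x_i) + beta * (ref - x_i)
    else:
        if i == 1:
            new = x_best + r * (x_best - x_i) + beta * (x_best - x_i)
        else:
            new = x_best + r * (x_prev - x_i) + beta * (x_best - x_i)
    return _clip(new, params)


def chain_update(
    x_i: np.ndarray,
    x_prev: np.ndarray,
    x_best: np.ndarray,
    draws: UpdateDraws,
    i: int,
    params: MRFOParams = MRFOParams(),
) -> np.ndarray:
    """Chain foraging: step toward the member ahead plus a pull to the best."""
    r, alpha = draws.r, draws.alpha
    anchor = x_best if i == 1 else x_prev
    new = x_i + r * (anchor - x_i) + alpha * (x_best - x_i)
    return _clip(new, params)


def somersault_update(
    x_i: np.ndarray,
    x_best: np.ndarray,
    draws: UpdateDraws,
    params: MRFOParams,
) -> np.ndarray:
    """Somersault foraging: flip around the best with amplitude ``S``."""
    new = x_i + params.somersault_factor * (draws.r2 * x_best - draws.r3 * x_i)
    return _clip(new, params)


# -- population sweep ------------------------------------------------------

FitnessCallable = Callable[[np.ndarray], float]


def _safe_eval(fitness: FitnessCallable, x: np.ndarray) -> float:
    try:
        score = float(fitness(x))
    except Exception as exc:  # noqa: BLE001 - a failing member must not kill the run
        logger.warning("fitness evaluation failed (%s); assigning worst score", exc)
        return SENTINEL_WORST
    if not math.isfinite(score):
        logger.warning("non-finite fitness score %r; assigning worst score", score)
        return SENTINEL_WORST
    return score


def update_population(
    pop: Population,
    fitness: FitnessCallable,
    params: MRFOParams,
    t: int,
    draws_fn: Optional[Callable[[int, int, int, int], UpdateDraws]] = None,
    history: Optional[OptimizationHistory] = None,
) -> Population:
    """One full MRFO sweep: move, re-score, somersault, re-score.

    Members are first sorted by score descending (stable, ties broken by
    member index).  The position updates happen in place, so member ``i``
    references the already-updated member ``i-1``.  The incumbent best is
    updated greedily at every re-evaluation and never worsens.
    """
    if draws_fn is None:
        dim = len(pop.solutions[0])
        draws_fn = lambda tt, ii, sweep, d=dim: draws_for(params, tt, ii, sweep, d)

    order = sorted(range(pop.n), key=lambda j: -pop.scores[j])
    sols = [np.array(pop.solutions[j], dtype=float) for j in order]
    scores = [pop.scores[j] for j in order]

    best_sol = np.array(sols[0], dtype=float)
    best_score = scores[0]
    if pop.best_solution is not None and pop.best_score > best_score:
        best_sol, best_score = np.array(pop.best_solution, dtype=float), pop.best_score

    # sweep 1: cyclone / chain moves
    for idx in range(pop.n):
        i = idx + 1  # 1-based rank
        d = draws_fn(t, i, 1)
        x_prev = sols[idx - 1] if idx > 0 else sols[idx]
        if d.branch_draw < 0.5:
            sols[idx] = cyclone_update(sols[idx], x_prev, best_sol, d, i, t, params)
        else:
            sols[idx] = chain_update(sols[idx], x_prev, best_sol, d, i, params)

    # re-score with greedy best tracking
    for idx in range(pop.n):
        scores[idx] = _safe_eval(fitness, sols[idx])
        if history is not None:
            history.log_eval(t, idx + 1, 1, scores[idx])
        if scores[idx] > best_score:
            best_score = scores[idx]
            best_sol = np.array(sols[idx], dtype=float)

    # sweep 2: somersault
    for idx in range(pop.n):
        d = draws_fn(t, idx + 1, 2)
        sols[idx] = somersault_update(sols[idx], best_sol, d, params)

    for idx in range(pop.n):
        scores[idx] = _safe_eval(fitness, sols[idx])
        if history is not None:
            history.log_eval(t, idx + 1, 2, scores[idx])
        if scores[idx] > best_score:
            best_score = scores[idx]
            best_sol = np.array(sols[idx], dtype=float)

    return Population(
        solutions=sols,
        scores=scores,
        best_solution=best_sol,
        best_score=best_score,
        iteration=t,
    )


def run_mrfo(
    space,
    fitness: FitnessCallable,
    params: MRFOParams,
    history: Optional[OptimizationHistory] = None,
):
    """Full optimization loop.

    ``space`` is either a :class:`~mrfopt.encoding.HyperparameterSpace`
    (the search dimension is its length) or a plain integer dimension.
    Initializes the population, then runs ``t_max`` iterations of
    score-everyone followed by :func:`update_population`.  Returns
    ``(best_solution, best_score, history)``.  Each member costs about three
    fitness evaluations per iteration (the initial scoring pass plus the two
    re-scoring passes inside the sweep); wrap the fitness in a memoizing
    layer when evaluations are expensive.
    """
    dimension = space if isinstance(space, int) else len(space)
    if history is None:
        history = OptimizationHistory()
    pop = init_population(params, dimension)
    for t in range(1, params.t_max + 1):
        for idx in range(pop.n):
            pop.scores[idx] = _safe_eval(fitness, pop.solutions[idx])
            history.log_eval(t, idx + 1, 0, pop.scores[idx])
            if pop.scores[idx] > pop.best_score:
                pop.best_score = pop.scores[idx]
                pop.best_solution = np.array(pop.solutions[idx], dtype=float)
        pop = update_population(pop, fitness, params, t, history=history)
        history.log_iteration(t, pop.best_score, pop.best_solution, pop.scores)
        logger.info("iteration %d: best score %.6f", t, pop.best_score)
    return clip_solution(pop.best_solution), pop.best_score, history
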