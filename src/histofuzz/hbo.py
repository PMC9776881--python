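"""Honey badger optimization (HBO) for box-constrained continuous minimization.

HBO is a population metaheuristic that mimics the foraging of the honey
badger.  Each badger alternates between a *digging* phase — cardioid-shaped
moves around the current best solution (the "prey"), scaled by a smell
intensity that grows with the source strength and decays with the squared
distance to the prey — and a *honey* phase, a guided step toward the prey
following a honeyguide bird.  An exponentially decaying density factor
shifts the search from exploration to exploitation over iterations.

Update rules, with ``r1..r7`` independent uniform draws on ``[0, 1)``::

    init      Y_j   = lb + r1 * (ub - lb)                    (per coordinate)
    intensity Int_j = r2 * SS / (4 pi d_j^2),  SS = ||Y_j - Y_{j+1}||^2,
                      d_j^2 = ||Y_prey - Y_j||^2
    density   phi   = Cc * exp(-iter / iter_max)
    flag      Fg    = +1 if r3 <= 0.5 else -1
    digging   Y_new = Y_prey + Fg*beta*Int_j*Y_prey
                             + Fg*r4*phi*d_vec*cos(2 pi r5)*(1 - cos(2 pi r6))
    honey     Y_new = Y_prey + Fg*r7*phi*d_vec

where ``d_vec = Y_prey - Y_j`` is the raw displacement vector (intensity
uses its squared norm).  Phase choice is a fair coin per badger per
iteration; a candidate replaces a badger only if it improves that badger's
fitness, and the prey is the running global best (greedy elitism), so the
prey-fitness history is non-increasing.

Randomness is drawn from a single generator in a fixed, documented order so
runs are bit-reproducible: per badger, first the phase coin, then for the
digging phase ``r2, r3, r4, r5, r6`` and for the honey phase ``r3, r7``.
Scalar draws (``r2..r7``) are per badger; only the initialization draw
``r1`` is per coordinate.  Badgers are updated sequentially in place, so a
badger's neighbor term may already reflect this iteration's moves.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "HBOConfig",
    "BadgerPopulation",
    "OptimizeResult",
    "ObjectiveError",
    "initialize_population",
    "density_factor",
    "compute_intensity",
    "direction_flag",
    "digging_update",
    "honey_update",
    "optimize",
    "save_history",
]

#: additive guard in the intensity denominator so a badger sitting on the
#: prey never divides by zero
DISTANCE_EPS = 1e-12

_FOUR_PI = 4.0 * np.pi


class ObjectiveError(RuntimeError):
    """Raised when the objective returns a non-finite value."""


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box ``[lower_bounds, upper_bounds]`` in R^d."""

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray

    def __post_init__(self) -> None:
        lb = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        ub = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        if lb.ndim != 1 or ub.ndim != 1 or lb.shape != ub.shape:
            raise ValueError(
                f"bound vectors must be 1-D and equally long, got shapes "
                f"{lb.shape} and {ub.shape}"
            )
        if lb.size == 0:
            raise ValueError("search space must have dimension >= 1")
        if np.any(lb > ub):
            raise ValueError("lower_bounds must be <= upper_bounds elementwise")
        object.__setattr__(self, "lower_bounds", lb)
        object.__setattr__(self, "upper_bounds", ub)

    @property
    def dimension(self) -> int:
        return self.lower_bounds.size

    @classmethod
    def cube(cls, low: float, high: float, dimension: int) -> "SearchSpace":
        """Hypercube ``[low, high]^dimension``."""
        return cls(np.full(dimension, low), np.full(dimension, high))

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower_bounds, self.upper_bounds)


@dataclasses.dataclass(frozen=True)
class HBOConfig:
    """Run parameters.

    ``beta`` is the badger's food-gathering ability (>= 1, default 6);
    ``density_constant`` is the Cc factor of the density schedule
    (default 2).  ``population_size`` must be >= 2 because the intensity
    term compares each badger with its circular-successor neighbor.
    """

    population_size: int = 30
    max_iterations: int = 100
    beta: float = 6.0
    density_constant: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.beta < 1.0:
            raise ValueError("beta must be >= 1")


@dataclasses.dataclass
class BadgerPopulation:
    """Mutable search state: positions, fitness, running best ("prey")."""

    positions: np.ndarray  # (Ns, dim)
    fitness: np.ndarray  # (Ns,)
    prey_position: np.ndarray  # (dim,)
    prey_fitness: float
    iteration: int = 0


@dataclasses.dataclass(frozen=True)
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # prey fitness after init and after each iteration
    n_evaluations: int


def _checked(objective: Callable[[np.ndarray], float], position: np.ndarray) -> float:
    value = float(objective(position))
    if not np.isfinite(value):
        raise ObjectiveError(
            f"objective returned non-finite value {value!r} at position "
            f"{np.array2string(position, precision=6)}"
        )
    return value


def initialize_population(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: HBOConfig,
    rng: np.random.Generator,
) -> BadgerPopulation:
    """Uniform initialization ``Y = lb + r1 * (ub - lb)``, r1 per coordinate."""
    r1 = rng.random((config.population_size, space.dimension))
    positions = space.lower_bounds + r1 * (space.upper_bounds - space.lower_bounds)
    fitness = np.array([_checked(objective, row) for row in positions])
    best = int(np.argmin(fitness))
    return BadgerPopulation(
        positions=positions,
        fitness=fitness,
        prey_position=positions[best].copy(),
        prey_fitness=float(fitness[best]),
    )


def density_factor(iteration: int, config: HBOConfig) -> float:
    """Time-decaying randomness control ``Cc * exp(-iter / iter_max)``.

    1-based: valid for ``1 <= iteration <= max_iterations``, so the factor
    spans ``(Cc*exp(-1/iter_max), ..., Cc/e]`` and never equals Cc itself.
    """
    if not 1 <= iteration <= config.max_iterations:
        raise ValueError(
            f"iteration must be in [1, {config.max_iterations}], got {iteration}"
        )
    return config.density_constant * float(np.exp(-iteration / config.max_iterations))


def compute_intensity(
    y_j: np.ndarray, y_next: np.ndarray, y_prey: np.ndarray, r2: float
) -> float:
    """Smell intensity ``r2 * SS / (4 pi d^2)`` with an epsilon-guarded denominator.

    ``SS`` is the squared distance to the neighbor badger, ``d^2`` the
    squared distance to the prey.
    """
    y_j = np.asarray(y_j, dtype=float)
    source_strength = float(np.sum((y_j - np.asarray(y_next, dtype=float)) ** 2))
    d_sq = float(np.sum((np.asarray(y_prey, dtype=float) - y_j) ** 2))
    return r2 * source_strength / (_FOUR_PI * d_sq + DISTANCE_EPS)


def direction_flag(r3: float) -> int:
    """Search-direction flag: +1 if ``r3 <= 0.5`` (inclusive), else -1."""
    return 1 if r3 <= 0.5 else -1


def digging_update(
    y_prey: np.ndarray,
    intensity: float,
    phi: float,
    d_j: np.ndarray,
    flag: int,
    config: HBOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cardioid-shaped digging move around the prey.

    Draws ``r4, r5, r6`` (in that order) from ``rng``.  The caller clips
    the result to the search box.
    """
    r4, r5, r6 = rng.random(3)
    y_prey = np.asarray(y_prey, dtype=float)
    return (
        y_prey
        + flag * config.beta * intensity * y_prey
        + flag
        * r4
        * phi
        * np.asarray(d_j, dtype=float)
        * np.cos(2.0 * np.pi * r5)
        * (1.0 - np.cos(2.0 * np.pi * r6))
    )


def honey_update(
    y_prey: np.ndarray,
    phi: float,
    d_j: np.ndarray,
    flag: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Honeyguide-following move ``Y_prey + Fg * r7 * phi * d_vec``.

    Draws ``r7`` from ``rng``.  The caller clips the result to the box.
    """
    r7 = float(rng.random())
    return np.asarray(y_prey, dtype=float) + flag * r7 * phi * np.asarray(
        d_j, dtype=float
    )


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: HBOConfig,
    rng: np.random.Generator | None = None,
) -> OptimizeResult:
    """Minimize ``objective`` over ``space`` with the honey badger algorithm.

    Returns the best position found, its fitness, the prey-fitness history
    (entry 0 is the post-initialization best, then one entry per
    iteration; non-increasing by construction), and the total number of
    objective evaluations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = initialize_population(objective, space, config, rng)
    n_evals = config.population_size
    history = [pop.prey_fitness]
    n = config.population_size

    for it in range(1, config.max_iterations + 1):
        phi = density_factor(it, config)
        for j in range(n):
            y_j = pop.positions[j]
            d_vec = pop.prey_position - y_j
            if rng.random() < 0.5:  # digging phase
                r2 = float(rng.random())
                intensity = compute_intensity(
                    y_j, pop.positions[(j + 1) % n], pop.prey_position, r2
                )
                flag = direction_flag(float(rng.random()))
                candidate = digging_update(
                    pop.prey_position, intensity, phi, d_vec, flag, config, rng
                )
            else:  # honey phase
                flag = direction_flag(float(rng.random()))
                candidate = honey_update(pop.prey_position, phi, d_vec, flag, rng)
            candidate = space.clip(candidate)
            value = _checked(objective, candidate)
            n_evals += 1
            if value < pop.fitness[j]:
                pop.positions[j] = candidate
                pop.fitness[j] = value
            if value < pop.prey_fitness:
                pop.prey_position = candidate.copy()
                pop.prey_fitness = value
        pop.iteration = it
        history.append(pop.prey_fitness)

    return OptimizeResult(
        best_position=pop.prey_position.copy(),
        best_fitness=float(pop.prey_fitness),
        history=np.asarray(history, dtype=float),
        n_evaluations=n_evals,
    )


def save_history(history: Sequence[float], path) -> None:
    """Write the convergence history as CSV (iteration, best_fitness)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("iteration,best_fitness\n")
        for i, value in enumerate(history):
            fh.write(f"{i},{value!r}\n")
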