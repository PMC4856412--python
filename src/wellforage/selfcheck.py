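"""Built-in self-checks behind the ``wellforage verify`` command.

Each check exercises an update rule against an independent brute-force
evaluation, or a short simulation against a conservation law.  The pytest
suite covers the same ground more thoroughly; this module exists so an
installed copy can be sanity-checked without the test suite present.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .environment import MapSpec, generate_map
from .evolution import Cohort, Population, run_day
from .model import (
    ModelConstants,
    ThresholdStats,
    Traits,
    compute_eudaimonic,
    compute_motivation,
    update_threshold,
)

Failure = tuple[str, str]


def _check_motivation(rng: np.random.Generator) -> str | None:
    for _ in range(200):
        H, E = rng.normal(size=2) * 10
        c = rng.random()
        m = compute_motivation(H, E, c)
        if not (min(H, E) - 1e-9 <= m <= max(H, E) + 1e-9):
            return f"M={m} outside [{min(H, E)}, {max(H, E)}]"
        if abs(m - (c * H + (1 - c) * E)) > 1e-12:
            return "blend mismatch"
    return None


def _check_threshold(rng: np.random.Generator) -> str | None:
    for _ in range(50):
        ms = rng.normal(size=rng.integers(1, 30)) * 5
        gamma = rng.uniform(0.05, 1.0)
        stats = ThresholdStats()
        for m in ms:
            theta, stats = update_threshold(stats, float(m), gamma)
        t = len(ms) + 1
        num = sum(gamma ** (t - i) * ms[i - 1] for i in range(1, t))
        den = sum(gamma**j for j in range(1, t))
        if abs(theta - num / den) > 1e-9:
            return f"incremental {theta} != direct {num / den}"
    return None


def _check_eudaimonic(rng: np.random.Generator) -> str | None:
    for _ in range(50):
        hist = list(rng.normal(size=rng.integers(2, 20)) * 3)
        dt = int(rng.integers(1, 10))
        lam = float(rng.uniform(0, 3))
        e = compute_eudaimonic(hist, dt, lam, lam)
        W = min(dt, len(hist) - 1)
        window = hist[-W:]
        closed = sum(window) / W + lam * (hist[-1] - hist[-1 - W]) / W
        if abs(e - closed) > 1e-9:
            return f"telescoped closed form mismatch: {e} vs {closed}"
    return None


def _check_conservation(rng: np.random.Generator) -> str | None:
    constants = ModelConstants(num_agents=50, num_days=30, num_generations=1)
    spec = MapSpec.for_kind("random_average", grid_size=40)
    grid = generate_map(spec, rng)
    initial = grid.total_food()
    cohorts = [Cohort(0, "all", Traits(), 50)]
    pop = Population.initialize(cohorts, spec.grid_size, rng)
    consumed = 0.0
    for _ in range(constants.num_days):
        stats = run_day(pop, grid, constants, rng)
        consumed += stats.food_consumed
        if initial - grid.total_food() != consumed:
            return "food removed from grid != food consumed by agents"
    return None


CHECKS: dict[str, Callable[[np.random.Generator], str | None]] = {
    "motivation-blend": _check_motivation,
    "threshold-oracle": _check_threshold,
    "eudaimonic-closed-form": _check_eudaimonic,
    "food-conservation": _check_conservation,
}


def run_selfcheck(seed: int = 0) -> list[Failure]:
    """Run every check; return (name, message) pairs for the failures."""
    failures: list[Failure] = []
    for name, fn in CHECKS.items():
        message = fn(np.random.default_rng(seed))
        if message is not None:
            failures.append((name, message))
    return failures
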