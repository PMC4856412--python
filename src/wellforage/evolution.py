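"""Population life cycle: daily foraging rounds, selection, reproduction.

The engine keeps the whole population in columnar NumPy arrays and advances
it one synchronous action cycle ("day") at a time.  Within a day every agent
computes its motivation, compares it against its adaptive threshold, takes
an aggressive or conservative foraging move, and updates its hedonic and
eudaimonic well-being and its fitness.  Social comparison always reads the
circle members' hedonic levels from the previous completed day, so results
do not depend on the order in which agents are processed; foraging
contention for a shared destination cell is resolved in fixed agent-id
order.

At the end of a generation the top half of the fitness distribution
reproduces clonally, with offspring counts proportional to (positively
shifted) parent fitness and apportioned by largest remainder so the next
generation has exactly ``num_agents`` members.  Offspring inherit their
parent's traits verbatim, are re-scattered uniformly, and draw fresh social
circles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .environment import MapSpec, ResourceGrid, generate_map
from .model import ModelConstants, Traits

__all__ = [
    "Cohort",
    "DayStats",
    "GenerationRecord",
    "Population",
    "run_day",
    "run_generations",
    "sample_circles",
    "select_and_reproduce",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class Cohort:
    """A subpopulation sharing one heritable trait bundle."""

    cohort_id: int
    label: str
    traits: Traits
    count: int


@dataclass
class DayStats:
    """Aggregate outcomes of one day, mainly for conservation checks."""

    food_consumed: float = 0.0
    poison_consumed: int = 0
    aggressive_actions: int = 0


@dataclass
class GenerationRecord:
    """End-of-generation summary of the population that lived it."""

    generation_index: int
    cohort_labels: tuple[str, ...]
    counts: np.ndarray  # carriers per cohort, sums to num_agents
    mean_fitness: np.ndarray  # per cohort; NaN for extinct cohorts
    mean_H: float
    mean_E: float


def sample_circles(
    n_agents: int, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a social circle (distinct other agents) for every agent.

    Returns an ``(n_agents, max(sizes))`` index array; rows with fewer than
    ``max(sizes)`` members are padded with ``-1``.  Sampling is without
    replacement within a row and never includes the agent itself.
    """
    n_max = int(sizes.max(initial=0))
    circles = np.full((n_agents, n_max), -1, dtype=np.int64)
    if n_max == 0:
        return circles
    if np.any(sizes >= n_agents):
        raise ValueError("social circle size must be smaller than the population")
    for n in np.unique(sizes):
        n = int(n)
        if n == 0:
            continue
        rows = np.flatnonzero(sizes == n)
        draw = rng.integers(0, n_agents - 1, size=(rows.size, n))
        draw += draw >= rows[:, None]  # skip self
        # redraw rows containing duplicates until all rows are distinct sets
        while True:
            srt = np.sort(draw, axis=1)
            bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
            if not bad.any():
                break
            redo = np.flatnonzero(bad)
            fresh = rng.integers(0, n_agents - 1, size=(redo.size, n))
            fresh += fresh >= rows[redo, None]
            draw[redo] = fresh
        circles[rows, :n] = draw
    return circles


class Population:
    """Columnar state of a full generation of agents."""

    def __init__(
        self,
        cohorts: Sequence[Cohort],
        cohort_of: np.ndarray,
        grid_size: int,
        rng: np.random.Generator,
        generation_index: int = 0,
        literal_eudaimonic_window: bool = False,
    ):
        self.cohorts = tuple(cohorts)
        self.cohort_of = np.asarray(cohort_of, dtype=np.int64)
        self.generation_index = generation_index
        self.grid_size = grid_size
        self.literal_eudaimonic_window = literal_eudaimonic_window
        n = self.cohort_of.size
        self.n = n

        def trait(name: str, dtype=np.float64) -> np.ndarray:
            per_cohort = np.array(
                [getattr(c.traits, name) for c in self.cohorts], dtype=dtype
            )
            return per_cohort[self.cohort_of]

        self.c = trait("c")
        self.gamma = trait("gamma")
        self.s = trait("s")
        self.alpha = trait("alpha")
        self.p_lambda = trait("p_lambda")
        self.n_lambda = trait("n_lambda")
        self.delta_t = trait("delta_t", np.int64)
        self.n_circle = trait("n_circle", np.int64)

        self.x = rng.integers(0, grid_size, size=n)
        self.y = rng.integers(0, grid_size, size=n)
        self.circle = sample_circles(n, self.n_circle, rng)

        self.fH = np.zeros(n)
        self.sH = np.zeros(n)
        self.H = np.zeros(n)
        self.E = np.zeros(n)
        self.M = np.zeros(n)
        self.fitness = np.zeros(n)
        self.th_num = np.zeros(n)
        self.th_den = np.zeros(n)
        self.last_M = np.zeros(n)
        self.steps = 0  # completed action cycles this generation
        # rolling hedonic history; one spare column for the inclusive-window
        # variant of the eudaimonic integrator
        max_dt = int(self.delta_t.max(initial=1))
        self.H_buf = np.zeros((n, max_dt + 2))

    # -- construction ---------------------------------------------------------

    @classmethod
    def initialize(
        cls,
        cohorts: Sequence[Cohort],
        grid_size: int,
        rng: np.random.Generator,
        literal_eudaimonic_window: bool = False,
    ) -> "Population":
        """Fresh generation-0 population with the cohorts' initial counts."""
        cohort_of = np.repeat(
            np.arange(len(cohorts)), [c.count for c in cohorts]
        )
        return cls(
            cohorts,
            cohort_of,
            grid_size,
            rng,
            generation_index=0,
            literal_eudaimonic_window=literal_eudaimonic_window,
        )

    # -- summaries ------------------------------------------------------------

    def cohort_counts(self) -> np.ndarray:
        return np.bincount(self.cohort_of, minlength=len(self.cohorts))

    def record(self) -> GenerationRecord:
        counts = self.cohort_counts()
        sums = np.bincount(
            self.cohort_of, weights=self.fitness, minlength=len(self.cohorts)
        )
        with np.errstate(invalid="ignore"):
            mean_fit = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return GenerationRecord(
            generation_index=self.generation_index,
            cohort_labels=tuple(c.label for c in self.cohorts),
            counts=counts,
            mean_fitness=mean_fit,
            mean_H=float(self.H.mean()),
            mean_E=float(self.E.mean()),
        )


def run_day(
    pop: Population,
    grid: ResourceGrid,
    constants: ModelConstants,
    rng: np.random.Generator,
) -> DayStats:
    """Advance every agent by one synchronous action cycle."""
    n = pop.n
    g = grid.grid_size
    first = pop.steps == 0

    # motivation from the current (previous-day) well-being levels
    M = pop.c * pop.H + (1.0 - pop.c) * pop.E
    if first:
        aggressive = np.zeros(n, dtype=bool)  # no threshold yet: conservative start
        theta = np.zeros(n)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(
                pop.gamma == 0.0, pop.last_M, pop.th_num / pop.th_den
            )
        aggressive = M > theta
    # fold today's motivation into the threshold statistics for tomorrow
    pop.th_num = pop.gamma * (pop.th_num + M)
    pop.th_den = pop.gamma * (pop.th_den + 1.0)
    pop.last_M = M
    pop.M = M

    # movement: uniform direction, uniform distance up to the action's range
    ranges = np.where(
        aggressive, constants.range_aggressive, constants.range_conservative
    )
    direction = rng.uniform(0.0, _TWO_PI, size=n)
    distance = rng.uniform(0.0, 1.0, size=n) * ranges
    dx = np.rint(distance * np.cos(direction)).astype(np.int64)
    dy = np.rint(distance * np.sin(direction)).astype(np.int64)
    pop.x = (pop.x + dx) % g
    pop.y = (pop.y + dy) % g

    # foraging; simultaneous arrivals at one cell are served in agent-id order
    flat = pop.x * g + pop.y
    food_flat = grid.food.reshape(-1)
    poison_flat = grid.poison.reshape(-1)
    order = np.argsort(flat, kind="stable")  # groups cells, preserves id order
    sorted_cells = flat[order]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = sorted_cells[1:] != sorted_cells[:-1]
    idx = np.arange(n)
    rank = idx - np.maximum.accumulate(np.where(new_group, idx, 0))
    cap = int(constants.f_max)
    stock = food_flat[sorted_cells]
    gain_sorted = np.clip(stock - rank * cap, 0, cap)
    gains = np.empty(n, dtype=np.int64)
    gains[order] = gain_sorted
    np.subtract.at(food_flat, flat, gains)
    poison_hit = np.zeros(n, dtype=bool)
    poison_hit[order] = poison_flat[sorted_cells] & (rank == 0)
    poison_flat[flat[poison_hit]] = False
    food_gain = gains.astype(np.float64) - poison_hit

    # social comparison against the circle's previous-day well-being levels.
    # The comparison basis is configurable: the food-hedonic component
    # (income-like relative consumption; stable for all sociality weights)
    # or the composite hedonic level (literal self-referential form, which
    # is linearly unstable for s > ~0.5 under fixed circles).
    basis_prev = pop.fH if constants.social_basis == "food_hedonic" else pop.H
    if pop.circle.shape[1] > 0:
        member_level = basis_prev[np.maximum(pop.circle, 0)]
        member_level = np.where(pop.circle >= 0, member_level, 0.0)
        sizes = np.maximum(pop.n_circle, 1)
        circle_mean = member_level.sum(axis=1) / sizes
        sH = np.where(
            pop.n_circle > 0,
            basis_prev - circle_mean + constants.beta_s,
            constants.beta_s,
        )
    else:
        sH = np.full(n, constants.beta_s)

    # hedonic update
    pop.fH = pop.fH + pop.alpha * food_gain - constants.beta_f
    H_new = (1.0 - pop.s) * pop.fH + pop.s * sH

    # eudaimonic update over the rolling hedonic history
    buf = pop.H_buf
    buf[:, :-1] = buf[:, 1:]
    buf[:, -1] = H_new
    steps = pop.steps + 1
    W = np.minimum(pop.delta_t, steps)
    vals = buf[:, 1:]
    diffs = buf[:, 1:] - buf[:, :-1]
    swing = np.where(diffs >= 0.0, pop.p_lambda[:, None], pop.n_lambda[:, None])
    contrib = vals + swing * diffs
    km1 = buf.shape[1] - 1
    if pop.literal_eudaimonic_window:
        n_terms = np.minimum(W + 1, steps)
    else:
        n_terms = W
    mask = np.arange(km1)[None, :] >= (km1 - n_terms[:, None])
    E = (contrib * mask).sum(axis=1) / W

    # fitness update
    cost = np.where(
        aggressive, constants.cost_aggressive, constants.cost_conservative
    )
    pop.fitness = pop.fitness + food_gain - cost - constants.beta_0
    pop.sH = sH
    pop.H = H_new
    pop.E = E
    pop.steps = steps
    return DayStats(
        food_consumed=float(gains.sum()),
        poison_consumed=int(poison_hit.sum()),
        aggressive_actions=int(aggressive.sum()),
    )


def offspring_counts(
    fitness: np.ndarray,
    num_offspring: int,
    eps: float = 1e-9,
    tiebreak: np.ndarray | None = None,
    shift: str = "population_min",
) -> tuple[np.ndarray, np.ndarray]:
    """Truncation selection plus fitness-proportional apportionment.

    Parents are the top half of the fitness distribution.  Each parent's
    weight is its fitness, shifted to be positive when necessary;
    ``num_offspring`` slots are apportioned by largest remainder, remainder
    ties going to the higher-fitness parent first.

    ``shift`` picks the zero point of reproductive value when fitness is
    not all-positive: ``"population_min"`` (default) measures each parent's
    fitness from the worst agent of the whole generation, so the weakest
    parent (roughly the population median) retains substantial weight and
    selection within the surviving half is mild; ``"parent_min"`` measures
    from the worst *parent*, which zeroes the median agent's weight and
    concentrates offspring in the upper tail.  When every parent's fitness
    is already positive no shift is applied.

    ``tiebreak`` orders agents of exactly equal fitness (lower value wins);
    it defaults to the agent id.  The population engine passes a random
    permutation instead, because fitness plateaus are common (e.g. agents
    that never found food) and id order would systematically favour
    whichever cohort was listed first.  Returns ``(parent indices,
    counts)``.
    """
    n = fitness.size
    if tiebreak is None:
        tiebreak = np.arange(n)
    if shift not in ("population_min", "parent_min"):
        raise ValueError(f"unknown shift mode {shift!r}")
    order = np.lexsort((tiebreak, -fitness))  # best fitness first
    parents = order[: math.ceil(n / 2)]
    f = fitness[parents]
    fmin = f.min() if shift == "parent_min" else fitness.min()
    w = f - fmin + eps if fmin <= 0.0 else f.astype(np.float64)
    quota = num_offspring * w / w.sum()
    base = np.floor(quota).astype(np.int64)
    frac = quota - base
    short = num_offspring - int(base.sum())
    tie_order = np.lexsort((tiebreak[parents], -f, -frac))
    base[tie_order[:short]] += 1
    return parents, base


def select_and_reproduce(
    pop: Population, constants: ModelConstants, rng: np.random.Generator
) -> Population:
    """Build the next generation from the current one's final fitness."""
    parents, counts = offspring_counts(
        pop.fitness,
        constants.num_agents,
        tiebreak=rng.permutation(pop.n),
        shift=constants.selection_shift,
    )
    parent_rows = np.repeat(parents, counts)
    child_cohorts = pop.cohort_of[parent_rows]
    return Population(
        pop.cohorts,
        child_cohorts,
        pop.grid_size,
        rng,
        generation_index=pop.generation_index + 1,
        literal_eudaimonic_window=pop.literal_eudaimonic_window,
    )


def run_generations(
    spec: MapSpec,
    cohorts: Sequence[Cohort],
    constants: ModelConstants,
    seed: int | np.random.Generator,
    num_generations: int | None = None,
) -> list[GenerationRecord]:
    """Run the full evolutionary loop and return one record per generation.

    The landscape is redrawn from ``spec`` at the start of every generation,
    so depletion never carries over.  All randomness flows from ``seed``
    through a single generator in a fixed order, making the record stream
    fully reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = sum(c.count for c in cohorts)
    if total != constants.num_agents:
        raise ValueError(
            f"cohort counts sum to {total}, expected num_agents={constants.num_agents}"
        )
    gens = constants.num_generations if num_generations is None else num_generations
    pop = Population.initialize(
        cohorts,
        spec.grid_size,
        rng,
        literal_eudaimonic_window=constants.literal_eudaimonic_window,
    )
    records: list[GenerationRecord] = []
    for _ in range(gens):
        grid = generate_map(spec, rng)
        for _day in range(constants.num_days):
            run_day(pop, grid, constants, rng)
        records.append(pop.record())
        pop = select_and_reproduce(pop, constants, rng)
    return records
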