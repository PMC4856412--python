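"""Per-agent state and the per-step well-being, motivation and fitness rules.

An agent carries a fixed bundle of heritable traits and, each action cycle,
turns its recent outcomes into a pair of well-being signals: a fast *hedonic*
level ``H`` (food finds plus social comparison) and a slower *eudaimonic*
level ``E`` (a windowed average of ``H`` with asymmetric weighting of up- and
downswings).  A motivation signal blending the two is compared against an
adaptive threshold -- an exponentially forgetting average of past motivation
-- to pick between an aggressive (long-range, costly) and a conservative
(short-range, cheap) foraging move.  Fitness is the running food intake net
of action and metabolic costs.

The functions in this module are the scalar, single-agent form of the update
rules; :mod:`wellforage.evolution` applies the same arithmetic across whole
populations with NumPy.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "Action",
    "AgentState",
    "InvalidTraitError",
    "ModelConstants",
    "ThresholdStats",
    "ThresholdUndefinedError",
    "Traits",
    "choose_action",
    "combine_hedonic",
    "compute_eudaimonic",
    "compute_motivation",
    "update_fitness",
    "update_food_hedonic",
    "update_social_hedonic",
    "update_threshold",
]


class InvalidTraitError(ValueError):
    """A heritable trait value lies outside its admissible range."""


class ThresholdUndefinedError(RuntimeError):
    """The action threshold was requested before any motivation history exists."""


class Action(enum.Enum):
    """Foraging move kind: long-range/costly vs short-range/cheap."""

    AGGRESSIVE = "aggressive"
    CONSERVATIVE = "conservative"


@dataclass(frozen=True)
class Traits:
    """Heritable behavioural parameters, fixed for an agent's lifetime.

    Parameters
    ----------
    c:
        Motivation blend weight in ``[0, 1]``; ``c`` weights the hedonic
        level and ``1 - c`` the eudaimonic level.
    gamma:
        Forgetting factor in ``[0, 1]`` of the action threshold; larger
        values give older motivations more influence.
    s:
        Sociality weighting in ``[0, 1]``; ``s`` weights the social
        comparison component of hedonic well-being and ``1 - s`` the food
        component.
    alpha:
        Hedonic gain per food unit, ``>= 0``.
    n_circle:
        Size of the fixed social comparison circle, ``>= 0``.
    delta_t:
        Length in action cycles of the memory window feeding the eudaimonic
        integrator, ``>= 1``.
    p_lambda, n_lambda:
        Non-negative weights amplifying upswings resp. downswings of the
        hedonic level inside the eudaimonic integrator.  ``p_lambda >
        n_lambda`` is a "positive outlook".
    """

    c: float = 0.5
    gamma: float = 0.90
    s: float = 0.5
    alpha: float = 2.0
    n_circle: int = 8
    delta_t: int = 4
    p_lambda: float = 1.0
    n_lambda: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c", "gamma", "s"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidTraitError(f"trait {name}={v!r} outside [0, 1]")
        for name in ("alpha", "p_lambda", "n_lambda"):
            v = getattr(self, name)
            if v < 0.0:
                raise InvalidTraitError(f"trait {name}={v!r} must be >= 0")
        if int(self.delta_t) != self.delta_t or self.delta_t < 1:
            raise InvalidTraitError(f"delta_t={self.delta_t!r} must be an integer >= 1")
        if int(self.n_circle) != self.n_circle or self.n_circle < 0:
            raise InvalidTraitError(f"n_circle={self.n_circle!r} must be an integer >= 0")

    def with_(self, **overrides: float) -> "Traits":
        """Return a copy with the given trait values replaced."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class ModelConstants:
    """Model-wide constants shared by every agent.

    All energetic quantities are in food units per action cycle.  The
    defaults are the package's reference parameterisation (see
    ``docs/methods.md`` for how they were chosen).
    """

    beta_f: float = 0.1  # metabolic drain on the food-hedonic level
    beta_s: float = 0.1  # base hedonic gain from socialising
    beta_0: float = 0.1  # base metabolic fitness expenditure
    f_max: float = 5.0  # per-cycle food intake cap
    cost_aggressive: float = 0.8
    cost_conservative: float = 0.4
    range_aggressive: float = 10.0
    range_conservative: float = 2.0
    num_agents: int = 400
    num_days: int = 100
    num_generations: int = 100
    literal_eudaimonic_window: bool = False  # use the (delta_t + 1)-term sum variant
    selection_shift: str = "population_min"  # zero point for reproductive weights
    social_basis: str = "food_hedonic"  # well-being level compared within the circle

    def __post_init__(self) -> None:
        if self.selection_shift not in ("population_min", "parent_min"):
            raise ValueError(
                f"selection_shift={self.selection_shift!r} must be"
                " 'population_min' or 'parent_min'"
            )
        if self.social_basis not in ("food_hedonic", "hedonic"):
            raise ValueError(
                f"social_basis={self.social_basis!r} must be"
                " 'food_hedonic' or 'hedonic'"
            )
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if not self.cost_aggressive >= self.cost_conservative >= 0:
            raise ValueError("need cost_aggressive >= cost_conservative >= 0")
        if not self.range_aggressive > self.range_conservative > 0:
            raise ValueError("need range_aggressive > range_conservative > 0")
        for name in ("num_agents", "num_days", "num_generations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def action_cost(self, action: Action) -> float:
        return self.cost_aggressive if action is Action.AGGRESSIVE else self.cost_conservative

    def action_range(self, action: Action) -> float:
        return self.range_aggressive if action is Action.AGGRESSIVE else self.range_conservative


@dataclass
class ThresholdStats:
    """Sufficient statistics for the forgetting-average action threshold.

    The threshold at step ``t`` is a normalised, geometrically discounted
    average of the motivations observed at steps ``1 .. t-1``.  It is carried
    incrementally as a weighted numerator/denominator pair so each update is
    O(1):

    ``numerator_t   = gamma * (numerator_{t-1} + M_{t-1})``
    ``denominator_t = gamma * (denominator_{t-1} + 1)``
    """

    numerator: float = 0.0
    denominator: float = 0.0
    count: int = 0  # number of motivations absorbed
    last_m: float = math.nan  # retained for the gamma -> 0 limit


def compute_motivation(H: float, E: float, c: float) -> float:
    """Blend hedonic and eudaimonic well-being into a motivation signal.

    Returns ``c * H + (1 - c) * E``; a convex combination, so the result
    always lies between ``min(H, E)`` and ``max(H, E)``.
    """
    if not 0.0 <= c <= 1.0:
        raise InvalidTraitError(f"c={c!r} outside [0, 1]")
    return c * H + (1.0 - c) * E


def update_threshold(
    stats: ThresholdStats, M_prev: float, gamma: float
) -> tuple[float, ThresholdStats]:
    """Absorb the previous step's motivation and return the new threshold.

    Folds ``M_prev`` into the discounted numerator/denominator pair and
    returns the threshold valid for the *current* step, i.e. the
    geometrically weighted mean of all motivations seen so far.  For
    ``gamma == 0`` every geometric weight vanishes and the threshold is
    taken as the limit value ``M_prev`` (the most recent motivation).
    """
    if not 0.0 <= gamma <= 1.0:
        raise InvalidTraitError(f"gamma={gamma!r} outside [0, 1]")
    new = ThresholdStats(
        numerator=gamma * (stats.numerator + M_prev),
        denominator=gamma * (stats.denominator + 1.0),
        count=stats.count + 1,
        last_m=M_prev,
    )
    if gamma == 0.0:
        return M_prev, new
    return new.numerator / new.denominator, new


def threshold_from_stats(stats: ThresholdStats, gamma: float) -> float:
    """Threshold implied by already-accumulated statistics, without update."""
    if stats.count == 0:
        raise ThresholdUndefinedError("no motivation history yet; no threshold defined")
    if gamma == 0.0:
        return stats.last_m
    return stats.numerator / stats.denominator


def choose_action(M: float, theta: float) -> Action:
    """Aggressive iff motivation strictly exceeds the threshold."""
    return Action.AGGRESSIVE if M > theta else Action.CONSERVATIVE


def update_food_hedonic(fH_prev: float, food_gain: float, alpha: float, beta_f: float) -> float:
    """Advance the food component of hedonic well-being by one cycle.

    ``food_gain`` is the net food intake this cycle (negative when a poison
    item was consumed); ``beta_f`` drains the level every cycle regardless
    of outcome.
    """
    return fH_prev + alpha * food_gain - beta_f

def update_social_hedonic(
    H_self: float, H_circle: Sequence[float], beta_s: float, *, s: float = 1.0
) -> float:
    """Social comparison component: own level relative to the circle average.

    The agent is happier when it is doing better than the average over its
    fixed comparison circle, and unhappier otherwise; ``beta_s`` is a flat
    gain from socialising.  An empty circle is only legal for an agent whose
    sociality weight ``s`` is zero, in which case the (unused) component is
    reported as ``beta_s``.
    """
    if len(H_circle) == 0:
        if s > 0.0:
            raise ValueError("empty social circle with sociality weight s > 0")
        return beta_s
    return H_self - sum(H_circle) / len(H_circle) + beta_s


def combine_hedonic(fH: float, sH: float, s: float) -> float:
    """Mix the food and social hedonic components with sociality weight ``s``."""
    if not 0.0 <= s <= 1.0:
        raise InvalidTraitError(f"s={s!r} outside [0, 1]")
    return (1.0 - s) * fH + s * sH


def compute_eudaimonic(
    H_history: Sequence[float],
    delta_t: int,
    p_lambda: float,
    n_lambda: float,
    *,
    literal_window: bool = False,
) -> float:
    """Eudaimonic well-being: windowed mean of ``H`` with asymmetric swings.

    ``H_history`` lists hedonic levels oldest-first, ending with the current
    one.  Writing ``d_i = H_i - H_{i-1}`` for the backward differences, the
    integrator averages ``H_i + p_lambda * max(d_i, 0) + n_lambda *
    min(d_i, 0)`` over the ``W`` most recent steps, ``W = min(delta_t,
    available steps)``.  Upswings therefore raise, and downswings lower, the
    longer-term evaluation beyond the plain window mean, by amounts the
    outlook weights control.

    With ``literal_window=True`` the sum runs over ``W + 1`` terms (the
    window endpoints inclusive) while still dividing by ``W``; see
    ``docs/methods.md`` for why the ``W``-term mean is the default.
    """
    if int(delta_t) != delta_t or delta_t < 1:
        raise InvalidTraitError(f"delta_t={delta_t!r} must be an integer >= 1")
    if len(H_history) < 2:
        raise ValueError("H_history must hold at least 2 values")
    steps = len(H_history) - 1  # number of backward differences available
    W = min(int(delta_t), steps)
    n_terms = min(W + 1, steps) if literal_window else W
    total = 0.0
    for j in range(len(H_history) - n_terms, len(H_history)):
        d = H_history[j] - H_history[j - 1]
        w = p_lambda if d >= 0 else n_lambda
        total += H_history[j] + w * d
    return total / W


def update_fitness(
    fitness_prev: float, food_gain: float, action_cost: float, beta_0: float
) -> float:
    """Accumulate fitness: food intake net of action and metabolic costs."""
    return fitness_prev + food_gain - action_cost - beta_0


@dataclass
class AgentState:
    """Full mutable state of one agent, for inspection and small-scale runs.

    The population engine keeps this state in columnar NumPy arrays; this
    dataclass is the per-agent view used by tests, examples and the
    reference step-by-step updates.
    """

    agent_id: int
    cohort_id: int
    traits: Traits
    x: int = 0
    y: int = 0
    fH: float = 0.0
    sH: float = 0.0
    H: float = 0.0
    E: float = 0.0
    M: float = 0.0
    theta: float = math.nan
    fitness: float = 0.0
    H_history: list[float] = field(default_factory=lambda: [0.0])
    threshold_stats: ThresholdStats = field(default_factory=ThresholdStats)
    circle: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.circle and len(self.circle) != self.traits.n_circle:
            raise ValueError("circle size does not match the n_circle trait")

    @property
    def age(self) -> int:
        """Number of completed action cycles."""
        return len(self.H_history) - 1
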