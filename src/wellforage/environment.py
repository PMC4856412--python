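"""Resource landscapes and movement/foraging on a toroidal lattice.

Four landscape regimes differing in the spatial distribution of food are
supported: uniformly random placement at a scarce or an average density, and
patchy placement (disc-shaped clusters) at an average or an abundant overall
density.  Any regime can additionally carry "poison": each resource site is
independently flagged noxious with probability ``poison_fraction``, and a
poison item costs one food unit of fitness (and of food-hedonic input) when
consumed.

Grids are regenerated from their :class:`MapSpec` at the start of every
generation, so within-generation depletion never carries over.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, TextIO

import numpy as np

from .model import Action, AgentState, ModelConstants

__all__ = [
    "DegenerateMapError",
    "KIND_DEFAULTS",
    "MAP_KINDS",
    "MapSpec",
    "ResourceGrid",
    "generate_map",
    "load_grid",
    "move_and_forage",
    "save_grid",
]

MapKind = Literal["random_scarce", "random_average", "patchy_average", "patchy_abundant"]

MAP_KINDS: tuple[MapKind, ...] = (
    "random_scarce",
    "random_average",
    "patchy_average",
    "patchy_abundant",
)

#: Default geometry per regime.  Densities follow the qualitative
#: scarce < average < abundant ordering; patchy regimes are specified by
#: patch count and radius instead of a per-cell density.  Units per
#: occupied site differ by regime: scarce food comes in richer but rarer
#: lumps, average-density patches in 2-unit cells, the rest in single
#: units (see docs/methods.md for how these were chosen).
KIND_DEFAULTS: dict[str, dict[str, float | int | None]] = {
    "random_scarce": {
        "food_density": 0.01, "units_per_site": 5,
        "patch_count": None, "patch_radius": None,
    },
    "random_average": {
        "food_density": 0.05, "units_per_site": 1,
        "patch_count": None, "patch_radius": None,
    },
    "patchy_average": {
        "food_density": None, "units_per_site": 2,
        "patch_count": 20, "patch_radius": 8,
    },
    "patchy_abundant": {
        "food_density": None, "units_per_site": 1,
        "patch_count": 40, "patch_radius": 10,
    },
}


class DegenerateMapError(ValueError):
    """The requested map would carry fewer than one expected resource site."""


@dataclass(frozen=True)
class MapSpec:
    """Declarative description of a resource landscape.

    Use :meth:`for_kind` to obtain a spec with the regime's default
    geometry; every field can be overridden.
    """

    kind: MapKind
    grid_size: int = 200
    food_density: float | None = None  # random regimes: fraction of cells with food
    units_per_site: int = 1
    patch_count: int | None = None  # patchy regimes
    patch_radius: int | None = None
    poison_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if not 0.0 <= self.poison_fraction <= 1.0:
            raise ValueError("poison_fraction must lie in [0, 1]")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if self.units_per_site < 1:
            raise ValueError("units_per_site must be >= 1")
        if self.is_random:
            if self.food_density is None or not 0.0 < self.food_density <= 1.0:
                raise ValueError("random regimes need food_density in (0, 1]")
            if self.food_density * self.grid_size**2 < 1.0:
                raise DegenerateMapError(
                    "expected fewer than one resource site; map would be empty"
                )
        else:
            if not self.patch_count or not self.patch_radius:
                raise ValueError("patchy regimes need patch_count and patch_radius")

    @property
    def is_random(self) -> bool:
        return self.kind.startswith("random")

    @classmethod
    def for_kind(cls, kind: MapKind, **overrides) -> "MapSpec":
        params = {k: v for k, v in KIND_DEFAULTS[kind].items()}
        params.update(overrides)
        return cls(kind=kind, **params)

    def with_(self, **overrides) -> "MapSpec":
        return replace(self, **overrides)


@dataclass
class ResourceGrid:
    """A lattice of food unit counts plus boolean poison flags.

    A cell is never simultaneously food-bearing and poison-flagged: a
    resource site is generated as one or the other.
    """

    food: np.ndarray  # (G, G) non-negative int
    poison: np.ndarray  # (G, G) bool

    def __post_init__(self) -> None:
        if self.food.shape != self.poison.shape:
            raise ValueError("food and poison lattices must share a shape")
        if np.any((self.food > 0) & self.poison):
            raise ValueError("a cell cannot be both food-bearing and poison-flagged")

    @property
    def grid_size(self) -> int:
        return self.food.shape[0]

    def total_food(self) -> int:
        return int(self.food.sum())

    def total_poison(self) -> int:
        return int(self.poison.sum())

    def copy(self) -> "ResourceGrid":
        return ResourceGrid(self.food.copy(), self.poison.copy())


def _patch_mask(grid_size: int, centers: np.ndarray, radius: int) -> np.ndarray:
    """Boolean mask of cells within toroidal distance ``radius`` of any center."""
    offs = [
        (dx, dy)
        for dx in range(-radius, radius + 1)
        for dy in range(-radius, radius + 1)
        if dx * dx + dy * dy <= radius * radius
    ]
    offs_arr = np.array(offs)  # (K, 2)
    cells = (centers[:, None, :] + offs_arr[None, :, :]) % grid_size  # (P, K, 2)
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    mask[cells[..., 0].ravel(), cells[..., 1].ravel()] = True
    return mask


def generate_map(spec: MapSpec, rng: np.random.Generator) -> ResourceGrid:
    """Draw a fresh landscape from ``spec``.

    Random regimes occupy each cell independently with probability
    ``food_density``; patchy regimes fill every cell within ``patch_radius``
    of ``patch_count`` uniformly placed disc centers.  Each occupied site is
    then independently flagged poison with probability ``poison_fraction``
    (such sites carry no food); the rest receive ``units_per_site`` food
    units.  Identical ``(spec, rng state)`` yields an identical grid.
    """
    g = spec.grid_size
    if spec.is_random:
        occupied = rng.random((g, g)) < spec.food_density
    else:
        centers = rng.integers(0, g, size=(int(spec.patch_count), 2))
        occupied = _patch_mask(g, centers, int(spec.patch_radius))
    if spec.poison_fraction > 0.0:
        poison = occupied & (rng.random((g, g)) < spec.poison_fraction)
    else:
        poison = np.zeros((g, g), dtype=bool)
    food = np.where(occupied & ~poison, spec.units_per_site, 0).astype(np.int64)
    return ResourceGrid(food=food, poison=poison)


def displacement(direction: float, distance: float) -> tuple[int, int]:
    """Integer lattice displacement for a continuous polar move."""
    return (
        int(round(distance * math.cos(direction))),
        int(round(distance * math.sin(direction))),
    )


def harvest(grid: ResourceGrid, x: int, y: int, f_max: float) -> tuple[float, int]:
    """Consume the resources of one cell: returns (net food gain, poison count).

    Food intake is capped at ``f_max`` units; leftover food stays on the
    cell.  A poison flag is consumed whole and contributes ``-1`` to the net
    gain.
    """
    gain = float(min(int(grid.food[x, y]), int(f_max)))
    grid.food[x, y] -= int(gain)
    poison_count = 0
    if grid.poison[x, y]:
        grid.poison[x, y] = False
        poison_count = 1
        gain -= 1.0
    return gain, poison_count


def move_and_forage(
    agent: AgentState,
    action: Action,
    grid: ResourceGrid,
    constants: ModelConstants,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], float, int]:
    """Move one agent and let it harvest its destination cell.

    The move direction is uniform on ``[0, 2*pi)`` and the distance uniform
    on ``(0, range]``, with the range set by the action kind; the continuous
    displacement is rounded to the nearest cell and wraps toroidally.  Only
    the destination cell is harvested.  Returns the new position, the net
    food gain (poison contributing ``-1``), and the poison count.
    """
    g = grid.grid_size
    direction = rng.uniform(0.0, 2.0 * math.pi)
    distance = rng.uniform(0.0, constants.action_range(action))
    dx, dy = displacement(direction, distance)
    new_x, new_y = (agent.x + dx) % g, (agent.y + dy) % g
    gain, poison_count = harvest(grid, new_x, new_y, constants.f_max)
    agent.x, agent.y = new_x, new_y
    return (new_x, new_y), gain, poison_count


# -- plain-text grid fixtures -------------------------------------------------
#
# One row of whitespace-separated integers per lattice row: the food unit
# count of each cell, with -1 marking a poison-flagged cell.


def save_grid(grid: ResourceGrid, path_or_file: str | Path | TextIO) -> None:
    """Write a grid in the plain-text fixture format."""
    encoded = np.where(grid.poison, -1, grid.food)
    if isinstance(path_or_file, (str, Path)):
        np.savetxt(path_or_file, encoded, fmt="%d")
    else:
        np.savetxt(path_or_file, encoded, fmt="%d")


def load_grid(path_or_file: str | Path | TextIO | Iterable[str]) -> ResourceGrid:
    """Read a grid written by :func:`save_grid`."""
    if isinstance(path_or_file, (str, Path)):
        encoded = np.loadtxt(path_or_file, dtype=np.int64, ndmin=2)
    else:
        encoded = np.loadtxt(path_or_file, dtype=np.int64, ndmin=2)
    poison = encoded == -1
    food = np.where(poison, 0, encoded)
    return ResourceGrid(food=food, poison=poison)


def grid_to_text(grid: ResourceGrid) -> str:
    buf = io.StringIO()
    save_grid(grid, buf)
    return buf.getvalue()
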