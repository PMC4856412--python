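"""The six published experiment designs and the replicate protocol.

Each experiment splits the population into equal cohorts carrying different
levels of one happiness-related trait (or, for the outlook experiments, a
joint pair of swing weights), runs the evolutionary loop independently on
each of the four landscape regimes, repeats the whole thing over replicates
with distinct seeds, and summarises the per-generation carrier counts as
means with 95% Student-t confidence intervals across replicates.

Designs
-------
``1A``  motivation blend ``c`` swept 0.0 .. 1.0 in steps of 0.1 (11 cohorts)
``1B``  ``c`` = 0.3 vs 0.7
``2A``  food-hedonic gain ``alpha`` swept 0.5 .. 3.0 in steps of 0.5
``2B``  ``alpha`` = 0.5 vs 2.0
``3A``  sociality ``s`` in {0.2, 0.4, 0.6, 0.8} (circle size fixed at 8)
``3B``  ``s`` = 0.2 vs 0.8
``4A``  eudaimonic memory window ``delta_t`` in {1, 2, 4, 8, 16}
``4B``  ``delta_t`` = 2 vs 8
``5``   outlook (p_lambda, n_lambda) = (2.0, 0.5) vs (0.5, 2.0)
``6``   same outlook contrast on maps where 70% of resource items are poison
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .environment import MAP_KINDS, MapSpec
from .evolution import Cohort, GenerationRecord, run_generations
from .model import ModelConstants, Traits

__all__ = [
    "EXPERIMENT_IDS",
    "ExperimentConfig",
    "RunSummary",
    "build_experiment",
    "dominance_verdict",
    "equal_split",
    "run_experiment",
    "win_fraction",
]

EXPERIMENT_IDS = ("1A", "1B", "2A", "2B", "3A", "3B", "4A", "4B", "5", "6")

_JOINT_OUTLOOK = "outlook"  # varied_trait name for the (p_lambda, n_lambda) pair


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved design of one experiment."""

    experiment_id: str
    varied_trait: str
    levels: tuple  # trait values, or (p_lambda, n_lambda) pairs for "outlook"
    map_kinds: tuple[str, ...] = MAP_KINDS
    poison_fraction: float = 0.0
    replicates: int = 10
    fixed_traits: Traits = field(default_factory=Traits)
    constants: ModelConstants = field(default_factory=ModelConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.experiment_id == "6" and self.poison_fraction <= 0.0:
            raise ValueError("experiment 6 requires poison_fraction > 0")

    def with_(self, **overrides) -> "ExperimentConfig":
        return replace(self, **overrides)

    def cohort_label(self, level) -> str:
        if self.varied_trait == _JOINT_OUTLOOK:
            return f"p_lambda={level[0]},n_lambda={level[1]}"
        return f"{self.varied_trait}={level}"

    def cohorts(self) -> list[Cohort]:
        """Equal split of the population over the trait levels."""
        sizes = equal_split(self.constants.num_agents, len(self.levels))
        out = []
        for i, (level, size) in enumerate(zip(self.levels, sizes)):
            if self.varied_trait == _JOINT_OUTLOOK:
                tr = self.fixed_traits.with_(p_lambda=level[0], n_lambda=level[1])
            else:
                tr = self.fixed_traits.with_(**{self.varied_trait: level})
            out.append(Cohort(i, self.cohort_label(level), tr, int(size)))
        return out

    def map_spec(self, kind: str) -> MapSpec:
        return MapSpec.for_kind(kind, poison_fraction=self.poison_fraction)


def equal_split(total: int, k: int) -> np.ndarray:
    """Split ``total`` into ``k`` near-equal parts (earlier parts get the rest)."""
    base, extra = divmod(total, k)
    return np.array([base + (1 if i < extra else 0) for i in range(k)])


_DESIGNS: dict[str, tuple[str, tuple]] = {
    "1A": ("c", tuple(round(0.1 * i, 1) for i in range(11))),
    "1B": ("c", (0.3, 0.7)),
    "2A": ("alpha", (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)),
    "2B": ("alpha", (0.5, 2.0)),
    "3A": ("s", (0.2, 0.4, 0.6, 0.8)),
    "3B": ("s", (0.2, 0.8)),
    "4A": ("delta_t", (1, 2, 4, 8, 16)),
    "4B": ("delta_t", (2, 8)),
    "5": (_JOINT_OUTLOOK, ((2.0, 0.5), (0.5, 2.0))),
    "6": (_JOINT_OUTLOOK, ((2.0, 0.5), (0.5, 2.0))),
}


def build_experiment(
    experiment_id: str,
    *,
    replicates: int = 10,
    seed: int = 0,
    fixed_traits: Traits | None = None,
    constants: ModelConstants | None = None,
    map_kinds: Sequence[str] = MAP_KINDS,
) -> ExperimentConfig:
    """Return the published design for one of the ten experiment ids."""
    key = str(experiment_id).upper()
    if key not in _DESIGNS:
        raise KeyError(f"unknown experiment id {experiment_id!r}")
    trait, levels = _DESIGNS[key]
    return ExperimentConfig(
        experiment_id=key,
        varied_trait=trait,
        levels=levels,
        map_kinds=tuple(map_kinds),
        poison_fraction=0.7 if key == "6" else 0.0,
        replicates=replicates,
        fixed_traits=fixed_traits or Traits(),
        constants=constants or ModelConstants(),
        seed=seed,
    )


@dataclass
class RunSummary:
    """Replicate-resolved carrier-count trajectories of one experiment.

    ``counts`` has shape ``(maps, replicates, generations, cohorts)``;
    ``mean_fitness`` matches it.  Replicate ``r`` of every map kind uses
    seed ``base_seed + r``.
    """

    experiment_id: str
    map_kinds: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    counts: np.ndarray
    mean_fitness: np.ndarray
    base_seed: int
    replicates: int

    @property
    def generations(self) -> int:
        return self.counts.shape[2]

    def _map_index(self, map_kind: str) -> int:
        return self.map_kinds.index(map_kind)

    def mean_counts(self, map_kind: str) -> np.ndarray:
        """Per-generation per-cohort mean carrier count across replicates."""
        return self.counts[self._map_index(map_kind)].mean(axis=0)

    def ci_halfwidth(self, map_kind: str, confidence: float = 0.95) -> np.ndarray:
        """Student-t CI half-width across replicates (0 when replicates == 1)."""
        block = self.counts[self._map_index(map_kind)]
        n = block.shape[0]
        if n < 2:
            warnings.warn(
                "confidence interval degenerate with a single replicate",
                stacklevel=2,
            )
            return np.zeros(block.shape[1:])
        tcrit = sps.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        return tcrit * block.std(axis=0, ddof=1) / np.sqrt(n)

    def to_frame(self) -> pd.DataFrame:
        """Tidy replicate-level table: one row per (map, replicate, generation, cohort)."""
        m, r, g, k = self.counts.shape
        idx = pd.MultiIndex.from_product(
            [self.map_kinds, range(r), range(g), self.cohort_labels],
            names=["map_kind", "replicate", "generation", "cohort"],
        )
        return pd.DataFrame(
            {
                "carrier_count": self.counts.reshape(-1),
                "mean_fitness": self.mean_fitness.reshape(-1),
            },
            index=idx,
        ).reset_index()

    def summary_frame(self, confidence: float = 0.95) -> pd.DataFrame:
        """Per-generation cohort means and CI half-widths, one row per cell."""
        rows = []
        for kind in self.map_kinds:
            means = self.mean_counts(kind)
            half = self.ci_halfwidth(kind, confidence)
            for gen in range(means.shape[0]):
                for j, label in enumerate(self.cohort_labels):
                    rows.append(
                        {
                            "map_kind": kind,
                            "generation": gen,
                            "cohort": label,
                            "mean_count": means[gen, j],
                            "ci_halfwidth": half[gen, j],
                            "replicates": self.replicates,
                        }
                    )
        return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig,
    *,
    num_generations: int | None = None,
    progress: bool = False,
) -> RunSummary:
    """Run every (map kind, replicate) cell of an experiment.

    Replicate ``r`` runs with seed ``config.seed + r`` on each map, so the
    replicate streams are distinct but reproducible.  ``num_generations``
    optionally overrides the constants' generation count (for scaled-down
    runs).
    """
    cohorts = config.cohorts()
    gens = (
        config.constants.num_generations
        if num_generations is None
        else num_generations
    )
    counts = np.zeros(
        (len(config.map_kinds), config.replicates, gens, len(cohorts))
    )
    fitness = np.full_like(counts, np.nan)
    iterator = enumerate(config.map_kinds)
    for mi, kind in iterator:
        spec = config.map_spec(kind)
        for r in range(config.replicates):
            if progress:
                print(f"[{config.experiment_id}] {kind} replicate {r + 1}/{config.replicates}")
            records = run_generations(
                spec,
                cohorts,
                config.constants,
                seed=config.seed + r,
                num_generations=gens,
            )
            for gi, rec in enumerate(records):
                counts[mi, r, gi] = rec.counts
                fitness[mi, r, gi] = rec.mean_fitness
    return RunSummary(
        experiment_id=config.experiment_id,
        map_kinds=config.map_kinds,
        cohort_labels=tuple(c.label for c in cohorts),
        counts=counts,
        mean_fitness=fitness,
        base_seed=config.seed,
        replicates=config.replicates,
    )


@dataclass
class DominanceVerdict:
    """Cohorts ordered by mean carrier count over the trailing window."""

    map_kind: str
    generation_window: int
    ordering: tuple[str, ...]  # best first
    window_means: dict[str, float]
    replicate_means: np.ndarray  # (replicates, cohorts), window-averaged
    cohort_labels: tuple[str, ...]

    @property
    def dominant(self) -> str | None:
        """Top cohort, or None when the top two are exactly tied."""
        if len(self.ordering) >= 2:
            a, b = self.ordering[0], self.ordering[1]
            if self.window_means[a] == self.window_means[b]:
                return None
        return self.ordering[0]

    def sign_test(self, cohort_a: str, cohort_b: str) -> tuple[int, int, float]:
        """Paired per-replicate comparison of two cohorts.

        Returns ``(wins for a, decisive replicates, binomial p-value)`` for
        the two-sided exact sign test on the window-averaged counts.
        """
        ia = self.cohort_labels.index(cohort_a)
        ib = self.cohort_labels.index(cohort_b)
        diff = self.replicate_means[:, ia] - self.replicate_means[:, ib]
        wins = int((diff > 0).sum())
        decisive = int((diff != 0).sum())
        p = sps.binomtest(wins, decisive, 0.5).pvalue if decisive else 1.0
        return wins, decisive, p


def dominance_verdict(
    summary: RunSummary, map_kind: str, generation_window: int = 10
) -> DominanceVerdict:
    """Rank cohorts by mean carrier count over the final generations."""
    if generation_window > summary.generations:
        raise ValueError(
            f"window of {generation_window} exceeds the {summary.generations}"
            " simulated generations"
        )
    block = summary.counts[summary._map_index(map_kind)]
    tail = block[:, summary.generations - generation_window :, :]
    rep_means = tail.mean(axis=1)  # (replicates, cohorts)
    means = rep_means.mean(axis=0)
    order = np.argsort(-means, kind="stable")
    labels = summary.cohort_labels
    return DominanceVerdict(
        map_kind=map_kind,
        generation_window=generation_window,
        ordering=tuple(labels[i] for i in order),
        window_means={labels[i]: float(means[i]) for i in range(len(labels))},
        replicate_means=rep_means,
        cohort_labels=labels,
    )


def win_fraction(
    summary: RunSummary,
    map_kind: str,
    cohort_a: str,
    cohort_b: str,
    generation_window: int = 10,
) -> float:
    """Fraction of replicates in which cohort ``a`` out-counts cohort ``b``.

    Counts are averaged over the trailing ``generation_window`` generations
    before the per-replicate comparison.
    """
    verdict = dominance_verdict(summary, map_kind, generation_window)
    wins, _, _ = verdict.sign_test(cohort_a, cohort_b)
    return wins / summary.replicates
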