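"""Population engine: day cycle, selection, reproduction, generation loop.

The central check here replays the engine's random draws through an
independent scalar implementation built directly from the single-agent
update rules, and requires state-for-state agreement over many days.
"""

import math

import numpy as np
import pytest

from wellforage import model as md
from wellforage.environment import MapSpec, ResourceGrid, generate_map
from wellforage.evolution import (
    Cohort,
    Population,
    offspring_counts,
    run_day,
    run_generations,
    sample_circles,
    select_and_reproduce,
)
from wellforage.model import Action, ModelConstants, Traits


def two_cohorts(n=20, **kwargs):
    half = n // 2
    return [
        Cohort(0, "a", Traits(**kwargs), half),
        Cohort(1, "b", Traits(**kwargs), n - half),
    ]


# -- scalar reference ---------------------------------------------------------


def reference_day(states, grid, constants, dirs, dist_fracs, grid_size):
    """One synchronous day computed agent-by-agent with the scalar rules."""
    level_prev = {
        st.agent_id: (st.fH if constants.social_basis == "food_hedonic" else st.H)
        for st in states
    }
    actions = []
    for st in states:
        m = md.compute_motivation(st.H, st.E, st.traits.c)
        if st.threshold_stats.count == 0:
            action = Action.CONSERVATIVE
        else:
            theta = md.threshold_from_stats(st.threshold_stats, st.traits.gamma)
            action = md.choose_action(m, theta)
        _, st.threshold_stats = md.update_threshold(
            st.threshold_stats, m, st.traits.gamma
        )
        st.M = m
        actions.append(action)
    for st, action, direction, frac in zip(states, actions, dirs, dist_fracs):
        dist = frac * constants.action_range(action)
        st.x = (st.x + int(round(dist * math.cos(direction)))) % grid_size
        st.y = (st.y + int(round(dist * math.sin(direction)))) % grid_size
    gains = {}
    for st in states:  # agent-id order resolves contention
        g = min(int(grid.food[st.x, st.y]), int(constants.f_max))
        grid.food[st.x, st.y] -= g
        gain = float(g)
        if grid.poison[st.x, st.y]:
            grid.poison[st.x, st.y] = False
            gain -= 1.0
        gains[st.agent_id] = gain
    for st, action in zip(states, actions):
        circle_levels = [level_prev[j] for j in st.circle]
        sH = md.update_social_hedonic(
            level_prev[st.agent_id], circle_levels, constants.beta_s, s=st.traits.s
        )
        st.fH = md.update_food_hedonic(
            st.fH, gains[st.agent_id], st.traits.alpha, constants.beta_f
        )
        st.sH = sH
        st.H = md.combine_hedonic(st.fH, sH, st.traits.s)
        st.H_history.append(st.H)
        st.E = md.compute_eudaimonic(
            st.H_history, st.traits.delta_t, st.traits.p_lambda, st.traits.n_lambda
        )
        st.fitness = md.update_fitness(
            st.fitness, gains[st.agent_id], constants.action_cost(action), constants.beta_0
        )


@pytest.mark.parametrize("social_basis", ["food_hedonic", "hedonic"])
def test_engine_matches_scalar_reference(social_basis):
    """The vectorised day cycle reproduces the scalar single-agent rules
    exactly, including foraging contention and poison consumption."""
    grid_size, n, days = 30, 14, 50
    constants = ModelConstants(num_agents=n, social_basis=social_basis)
    rng = np.random.default_rng(42)
    cohorts = [
        Cohort(0, "a", Traits(c=0.3, gamma=0.8, s=0.6, alpha=1.5, n_circle=3,
                              delta_t=3, p_lambda=2.0, n_lambda=0.5), 7),
        Cohort(1, "b", Traits(c=0.9, gamma=0.0, s=0.0, alpha=1.0, n_circle=0,
                              delta_t=6, p_lambda=0.5, n_lambda=2.0), 7),
    ]
    pop = Population.initialize(cohorts, grid_size, rng)
    spec = MapSpec.for_kind(
        "random_average", grid_size=grid_size, food_density=0.3,
        units_per_site=7, poison_fraction=0.3,
    )
    grid = generate_map(spec, rng)
    ref_grid = grid.copy()
    states = [
        md.AgentState(
            agent_id=i,
            cohort_id=int(pop.cohort_of[i]),
            traits=cohorts[pop.cohort_of[i]].traits,
            x=int(pop.x[i]),
            y=int(pop.y[i]),
            circle=[int(j) for j in pop.circle[i] if j >= 0],
        )
        for i in range(n)
    ]
    for day in range(days):
        saved = rng.bit_generator.state
        run_day(pop, grid, constants, rng)
        replay = np.random.default_rng()
        replay.bit_generator.state = saved
        dirs = replay.uniform(0.0, 2.0 * math.pi, n)
        fracs = replay.uniform(0.0, 1.0, n)
        reference_day(states, ref_grid, constants, dirs, fracs, grid_size)
        for i, st in enumerate(states):
            for attr, arr in (
                ("x", pop.x), ("y", pop.y), ("fH", pop.fH), ("sH", pop.sH),
                ("H", pop.H), ("E", pop.E), ("M", pop.M), ("fitness", pop.fitness),
            ):
                assert getattr(st, attr) == pytest.approx(arr[i], abs=1e-9), (
                    f"day {day}, agent {i}, field {attr}"
                )
        assert np.array_equal(ref_grid.food, grid.food)
        assert np.array_equal(ref_grid.poison, grid.poison)


def test_hedonic_decomposition_holds_every_day(rng):
    """H always equals the sociality-weighted mix of its two components."""
    constants = ModelConstants(num_agents=30)
    pop = Population.initialize(two_cohorts(30, s=0.37), 40, rng)
    spec = MapSpec.for_kind("random_average", grid_size=40)
    grid = generate_map(spec, rng)
    for _ in range(25):
        run_day(pop, grid, constants, rng)
        assert np.allclose(
            pop.H, (1 - pop.s) * pop.fH + pop.s * pop.sH, atol=1e-9
        )


def test_cold_start_day_matches_hand_derivation(rng):
    """Asocial agent, empty grid, one day: pure decay plus conservative cost."""
    constants = ModelConstants(num_agents=1)
    cohorts = [Cohort(0, "solo", Traits(s=0.0, n_circle=0), 1)]
    pop = Population.initialize(cohorts, 10, rng)
    grid = ResourceGrid(
        food=np.zeros((10, 10), dtype=np.int64), poison=np.zeros((10, 10), bool)
    )
    stats = run_day(pop, grid, constants, rng)
    assert stats.aggressive_actions == 0  # no threshold yet: conservative start
    assert pop.fH[0] == pytest.approx(-constants.beta_f)
    assert pop.H[0] == pytest.approx(-constants.beta_f)
    assert pop.fitness[0] == pytest.approx(
        -constants.cost_conservative - constants.beta_0
    )


def test_constant_world_converges_to_fixed_point(rng):
    """An isolated agent on an empty grid settles into a steady decline in
    which all hedonic differences equal -beta_f, and E tracks H up to the
    swing-weighted drift term."""
    constants = ModelConstants(num_agents=1, beta_f=0.1)
    cohorts = [Cohort(0, "solo", Traits(s=0.0, n_circle=0, p_lambda=1.0, n_lambda=1.0), 1)]
    pop = Population.initialize(cohorts, 10, rng)
    grid = ResourceGrid(
        food=np.zeros((10, 10), dtype=np.int64), poison=np.zeros((10, 10), bool)
    )
    H_vals = []
    for _ in range(60):
        run_day(pop, grid, constants, rng)
        H_vals.append(pop.H[0])
    diffs = np.diff(H_vals[-10:])
    assert np.allclose(diffs, -constants.beta_f, atol=1e-9)
    # under constant drift -beta_f, the window mean lags H by
    # beta_f * (W - 1) / 2 and the swing term adds lambda * (-beta_f)
    W = int(pop.delta_t[0])
    expected_E = pop.H[0] + constants.beta_f * (W - 1) / 2 - constants.beta_f
    assert pop.E[0] == pytest.approx(expected_E, abs=1e-6)


def test_food_conservation_within_generation(rng):
    constants = ModelConstants(num_agents=60)
    pop = Population.initialize(two_cohorts(60), 40, rng)
    spec = MapSpec.for_kind("random_average", grid_size=40, units_per_site=3)
    grid = generate_map(spec, rng)
    initial = grid.total_food()
    consumed = 0.0
    for _ in range(30):
        stats = run_day(pop, grid, constants, rng)
        consumed += stats.food_consumed
        assert initial - grid.total_food() == consumed


def test_poison_flags_never_increase(rng):
    constants = ModelConstants(num_agents=60)
    pop = Population.initialize(two_cohorts(60), 40, rng)
    spec = MapSpec.for_kind("random_average", grid_size=40, poison_fraction=0.5)
    grid = generate_map(spec, rng)
    previous = grid.total_poison()
    for _ in range(30):
        run_day(pop, grid, constants, rng)
        current = grid.total_poison()
        assert current <= previous
        previous = current


class TestSampleCircles:
    def test_rows_are_distinct_and_exclude_self(self, rng):
        sizes = np.full(50, 8)
        circles = sample_circles(50, sizes, rng)
        for i, row in enumerate(circles):
            assert len(set(row.tolist())) == 8
            assert i not in row

    def test_mixed_sizes_padded_with_sentinel(self, rng):
        sizes = np.array([0, 2, 5])
        circles = sample_circles(3, np.array([0, 2, 2]), rng)
        assert circles.shape == (3, 2)
        assert (circles[0] == -1).all()

    def test_circle_larger_than_population_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_circles(4, np.full(4, 4), rng)


class TestOffspringCounts:
    def test_positive_fitness_proportional_hand_example(self):
        # parents are the top half {10, 6}; no shift needed; 4 slots split
        # 10:6 -> quotas 2.5/1.5 -> largest remainder tie to higher fitness
        parents, counts = offspring_counts(
            np.array([10.0, 6.0, 2.0, -2.0]), 4, shift="parent_min"
        )
        assert parents.tolist() == [0, 1]
        assert counts.tolist() == [3, 1]

    def test_population_min_shift_softens_selection(self):
        parents, counts = offspring_counts(
            np.array([10.0, 6.0, 2.0, -2.0]), 4, shift="population_min"
        )
        assert parents.tolist() == [0, 1]
        assert counts.tolist() == [2, 2]

    def test_equal_fitness_gives_equal_apportionment(self):
        parents, counts = offspring_counts(np.full(6, -3.0), 6)
        assert counts.tolist() == [2, 2, 2]

    def test_offspring_total_always_exact(self, rng):
        for _ in range(50):
            fitness = rng.normal(size=rng.integers(2, 30)) * rng.uniform(0.1, 100)
            n_out = int(rng.integers(1, 500))
            for shift in ("parent_min", "population_min"):
                parents, counts = offspring_counts(fitness, n_out, shift=shift)
                assert counts.sum() == n_out
                assert len(parents) == math.ceil(fitness.size / 2)

    def test_only_top_half_reproduces(self, rng):
        fitness = rng.normal(size=21)
        parents, counts = offspring_counts(fitness, 40)
        cutoff = np.sort(fitness)[::-1][math.ceil(21 / 2) - 1]
        assert (fitness[parents] >= cutoff).all()
        losers = np.setdiff1d(np.arange(21), parents)
        assert (fitness[losers] <= cutoff).all()


class TestSelectAndReproduce:
    def test_population_size_restored_and_traits_clonal(self, rng):
        constants = ModelConstants(num_agents=30)
        pop = Population.initialize(two_cohorts(30, delta_t=5), 20, rng)
        pop.fitness = rng.normal(size=30)
        child = select_and_reproduce(pop, constants, rng)
        assert child.n == 30
        assert child.generation_index == 1
        for cohort_id in np.unique(child.cohort_of):
            tr = child.cohorts[cohort_id].traits
            rows = child.cohort_of == cohort_id
            assert (child.delta_t[rows] == tr.delta_t).all()
            assert (child.c[rows] == tr.c).all()

    def test_offspring_state_is_fresh(self, rng):
        constants = ModelConstants(num_agents=20)
        pop = Population.initialize(two_cohorts(20), 20, rng)
        grid = generate_map(MapSpec.for_kind("random_average", grid_size=20), rng)
        for _ in range(5):
            run_day(pop, grid, constants, rng)
        child = select_and_reproduce(pop, constants, rng)
        assert (child.fitness == 0).all()
        assert (child.H == 0).all()
        assert child.steps == 0

    def test_extinct_cohort_cannot_reappear(self, rng):
        constants = ModelConstants(num_agents=20)
        pop = Population.initialize(two_cohorts(20), 20, rng)
        # rig fitness so cohort b is strictly dominated
        pop.fitness = np.where(pop.cohort_of == 0, 1.0, -1.0)
        child = select_and_reproduce(pop, constants, rng)
        assert (child.cohort_of == 0).all()
        child.fitness = rng.normal(size=20)
        grandchild = select_and_reproduce(child, constants, rng)
        assert (grandchild.cohort_of == 0).all()


class TestRunGenerations:
    @staticmethod
    def _records(seed, gens=3):
        spec = MapSpec.for_kind("random_average", grid_size=30)
        constants = ModelConstants(num_agents=24, num_days=10, num_generations=gens)
        return run_generations(spec, two_cohorts(24), constants, seed=seed)

    def test_one_record_per_generation_with_conserved_counts(self):
        records = self._records(3, gens=4)
        assert len(records) == 4
        for rec in records:
            assert rec.counts.sum() == 24

    def test_single_generation_counts_match_initial_split(self):
        (rec,) = self._records(5, gens=1)
        assert rec.counts.tolist() == [12, 12]

    def test_same_seed_reproduces_identical_streams(self):
        a = self._records(11)
        b = self._records(11)
        for ra, rb in zip(a, b):
            assert ra.counts.tolist() == rb.counts.tolist()
            np.testing.assert_allclose(ra.mean_fitness, rb.mean_fitness, atol=1e-12)
            assert ra.mean_H == rb.mean_H

    def test_cohort_sizes_must_sum_to_population(self):
        spec = MapSpec.for_kind("random_average", grid_size=30)
        constants = ModelConstants(num_agents=25, num_days=2, num_generations=1)
        with pytest.raises(ValueError):
            run_generations(spec, two_cohorts(24), constants, seed=0)

    def test_day_cycle_preserves_cohort_counts(self, rng):
        constants = ModelConstants(num_agents=24)
        pop = Population.initialize(two_cohorts(24), 30, rng)
        grid = generate_map(MapSpec.for_kind("random_average", grid_size=30), rng)
        before = pop.cohort_counts().tolist()
        for _ in range(10):
            run_day(pop, grid, constants, rng)
        assert pop.cohort_counts().tolist() == before
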