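"""Hybrid genetic-algorithm / simulated-annealing search over fixed-size
subsets of a candidate set, plus the clustered orchestrations and an
exhaustive-enumeration oracle.

The default budget is 200 GA generations with 10 simulated-annealing steps
after each generation (2000 SA steps in total). The GA uses tournament
selection, a size-preserving uniform exchange crossover, single-swap
mutation and elitism; the SA chain performs Metropolis swap moves on the
incumbent best with geometric cooling. Every run is bit-reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .clustering import Partition, apportion

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Search budget and operator settings.

    ``ga_generations * sa_steps_per_generation`` is the total number of SA
    steps (2000 at the defaults). The initial SA temperature is the standard
    deviation of the criterion over ``temperature_probe_subsets`` random
    subsets — scale-free across criteria of very different magnitudes — and
    cooling is geometric down to ``final_temperature_fraction`` of it.
    """

    ga_generations: int = 200
    sa_steps_per_generation: int = 10
    population_size: int = 100
    elite_fraction: float = 0.1
    tournament_size: int = 3
    mutation_rate: float = 0.2
    temperature_probe_subsets: int = 50
    final_temperature_fraction: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ga_generations", "sa_steps_per_generation", "population_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def total_sa_steps(self) -> int:
        return self.ga_generations * self.sa_steps_per_generation


@dataclass
class SubsetSolution:
    """An optimized training set and its search bookkeeping."""

    selected_ids: list[str]
    criterion_value: float
    evaluations_used: int
    trace: list[float] = field(default_factory=list)


class _Cache:
    """Memoized criterion evaluation keyed on the index tuple."""

    def __init__(self, evaluate, candidate: list[str]):
        self._evaluate = evaluate
        self._candidate = candidate
        self._store: dict[tuple, float] = {}
        self.calls = 0

    def __call__(self, idx_tuple: tuple) -> float:
        value = self._store.get(idx_tuple)
        if value is None:
            try:
                value = float(self._evaluate([self._candidate[i] for i in idx_tuple]))
            except Exception:
                logger.error("criterion failed on subset %s", idx_tuple)
                raise
            self._store[idx_tuple] = value
            self.calls += 1
        return value


def _random_solution(groups, rng) -> tuple:
    picks: list[int] = []
    for pool, quota in groups:
        if quota:
            picks.extend(rng.choice(pool, size=quota, replace=False))
    return tuple(sorted(picks))


def _swap_move(solution: tuple, groups, rng) -> tuple:
    """Exchange one selected member for an unselected one inside one group."""
    sol = set(solution)
    movable = [
        gi
        for gi, (pool, quota) in enumerate(groups)
        if 0 < quota < len(pool)
    ]
    if not movable:
        return solution
    gi = movable[rng.integers(len(movable))]
    pool, _ = groups[gi]
    inside = [i for i in pool if i in sol]
    outside = [i for i in pool if i not in sol]
    out = inside[rng.integers(len(inside))]
    into = outside[rng.integers(len(outside))]
    sol.discard(out)
    sol.add(into)
    return tuple(sorted(sol))


def _crossover(p1: tuple, p2: tuple, groups, rng) -> tuple:
    """Size-preserving uniform exchange: keep the parents' intersection, fill
    the per-group quota uniformly from their symmetric difference."""
    s1, s2 = set(p1), set(p2)
    child: list[int] = []
    for pool, quota in groups:
        pool_set = set(pool)
        both = sorted((s1 & s2) & pool_set)
        either = sorted((s1 ^ s2) & pool_set)
        need = quota - len(both)
        picks = list(both)
        if need > 0:
            chosen = rng.choice(len(either), size=need, replace=False)
            picks.extend(either[i] for i in chosen)
        child.extend(picks[:quota])
    return tuple(sorted(child))


def _search(groups, cache: _Cache, config: SearchConfig, rng) -> tuple[tuple, float, list]:
    """GA + SA engine over group-constrained subsets. Returns the best subset
    ever evaluated, its value, and the per-generation best-so-far trace."""
    pop_n = config.population_size
    population = [_random_solution(groups, rng) for _ in range(pop_n)]
    fitness = [cache(s) for s in population]

    # scale-free initial temperature from random probes
    probes = [cache(_random_solution(groups, rng)) for _ in range(config.temperature_probe_subsets)]
    t0 = float(np.std(probes))
    if not np.isfinite(t0) or t0 <= 0:
        t0 = 1.0
    alpha = config.final_temperature_fraction ** (1.0 / max(config.total_sa_steps, 1))

    order = np.argsort(fitness)[::-1]
    best, best_val = population[order[0]], fitness[order[0]]
    trace = [best_val]
    elite_n = max(1, int(round(config.elite_fraction * pop_n)))
    sa_state, sa_val = best, best_val
    step = 0

    for _gen in range(config.ga_generations):
        order = np.argsort(fitness)[::-1]
        elites = [population[i] for i in order[:elite_n]]
        new_pop = list(elites)
        while len(new_pop) < pop_n:
            parents = []
            for _ in range(2):
                contenders = rng.integers(pop_n, size=config.tournament_size)
                winner = max(contenders, key=lambda i: fitness[i])
                parents.append(population[winner])
            child = _crossover(parents[0], parents[1], groups, rng)
            if rng.random() < config.mutation_rate:
                child = _swap_move(child, groups, rng)
            new_pop.append(child)
        population = new_pop
        fitness = [cache(s) for s in population]
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_val:
            best, best_val = population[gen_best], fitness[gen_best]

        # Metropolis swap moves on the incumbent, geometric cooling
        if sa_val < best_val:
            sa_state, sa_val = best, best_val
        for _ in range(config.sa_steps_per_generation):
            temp = t0 * alpha**step
            step += 1
            proposal = _swap_move(sa_state, groups, rng)
            if proposal == sa_state:
                continue
            val = cache(proposal)
            delta = val - sa_val
            if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-300)):
                sa_state, sa_val = proposal, val
                if val > best_val:
                    best, best_val = proposal, val
        # reinject the SA incumbent in place of the worst individual
        worst = int(np.argmin(fitness))
        population[worst], fitness[worst] = sa_state, sa_val
        trace.append(best_val)

    return best, best_val, trace


def optimize_subset(evaluate, candidate_ids, size: int, config: SearchConfig | None = None) -> SubsetSolution:
    """Maximize ``evaluate`` over size-``size`` subsets of the candidate set."""
    config = config or SearchConfig()
    candidate = list(candidate_ids)
    nc = len(candidate)
    if not 1 <= size <= nc:
        raise ValueError(f"size must be in [1, {nc}]")
    cache = _Cache(evaluate, candidate)
    if size == nc:  # single feasible subset: no search
        idx = tuple(range(nc))
        value = cache(idx)
        return SubsetSolution(candidate, value, cache.calls, [value])
    rng = np.random.default_rng(config.rng_seed)
    groups = [(list(range(nc)), size)]
    best, best_val, trace = _search(groups, cache, config, rng)
    return SubsetSolution([candidate[i] for i in best], best_val, cache.calls, trace)


def optimize_clustered(
    evaluate,
    candidate_ids,
    size: int,
    partition: Partition,
    mode: str,
    config: SearchConfig | None = None,
    within_evaluators: dict[int, object] | None = None,
) -> SubsetSolution:
    """Cluster-aware training-set optimization.

    mode="within": per-cluster quotas by largest-remainder apportionment, an
    independent search inside each cluster, and the union of the per-cluster
    optima (the within-cluster CDmean orchestration). ``within_evaluators``
    may map cluster label -> evaluator; otherwise ``evaluate`` is used for
    every cluster.

    mode="overall": a single search whose moves only exchange individuals
    within the same cluster, holding per-cluster counts at the apportioned
    quotas while the criterion is evaluated globally.
    """
    config = config or SearchConfig()
    if mode not in ("within", "overall"):
        raise ValueError("mode must be 'within' or 'overall'")
    candidate = list(candidate_ids)
    label_of = partition.label_of()
    missing = [s for s in candidate if s not in label_of]
    if missing:
        raise ValueError(f"partition does not cover candidate ids: {missing[:3]}")
    members: dict[int, list[str]] = {l: [] for l in range(partition.k)}
    for s in candidate:
        members[label_of[s]].append(s)
    sizes = np.array([len(members[l]) for l in range(partition.k)])
    rng = np.random.default_rng(config.rng_seed)
    quotas = apportion(sizes, size, rng)
    if np.any(quotas > sizes):
        raise ValueError("a cluster quota exceeds the cluster size")

    if mode == "within":
        selected: list[str] = []
        total_value = 0.0
        evals = 0
        trace: list[float] = []
        for label in range(partition.k):
            if quotas[label] == 0:
                continue
            ev = within_evaluators[label] if within_evaluators else evaluate
            sub_config = SearchConfig(
                **{**config.__dict__, "rng_seed": int(config.rng_seed) + label + 1}
            )
            sol = optimize_subset(ev, members[label], int(quotas[label]), sub_config)
            selected.extend(sol.selected_ids)
            total_value += sol.criterion_value
            evals += sol.evaluations_used
            trace.append(sol.criterion_value)
        order = {s: i for i, s in enumerate(candidate)}
        selected.sort(key=order.get)
        return SubsetSolution(selected, total_value, evals, trace)

    # overall mode
    pos = {s: i for i, s in enumerate(candidate)}
    groups = [
        ([pos[s] for s in members[l]], int(quotas[l]))
        for l in range(partition.k)
        if len(members[l])
    ]
    cache = _Cache(evaluate, candidate)
    if size == len(candidate):
        idx = tuple(range(len(candidate)))
        value = cache(idx)
        return SubsetSolution(candidate, value, cache.calls, [value])
    best, best_val, trace = _search(groups, cache, config, rng)
    return SubsetSolution([candidate[i] for i in best], best_val, cache.calls, trace)


def exhaustive_best_subset(
    evaluate, candidate_ids, size: int, cap: int = 10**6
) -> SubsetSolution:
    """Exact optimum by enumerating every subset (testing oracle).

    Candidates are scanned in lexicographic id order and ties keep the first
    (lexicographically smallest) subset, so the result is reproducible.
    """
    candidate = sorted(candidate_ids)
    nc = len(candidate)
    if not 1 <= size <= nc:
        raise ValueError(f"size must be in [1, {nc}]")
    n_comb = math.comb(nc, size)
    if n_comb > cap:
        raise ValueError(f"C({nc},{size}) = {n_comb} exceeds the cap of {cap}")
    best_ids, best_val = None, -np.inf
    calls = 0
    for combo in itertools.combinations(candidate, size):
        value = float(evaluate(list(combo)))
        calls += 1
        if value > best_val:
            best_ids, best_val = list(combo), value
    return SubsetSolution(best_ids, best_val, calls, [best_val])
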