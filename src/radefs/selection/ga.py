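"""Genetic-algorithm wrapper selection.

Chromosomes are binary inclusion vectors over the candidate pool.  Fitness is
the weighted sum

    lambda2 * c2(P)  -  lambda1 * c1(|P|)  -  kappa * | |P| - p_target |

where ``c2`` is the internal cross-validated balanced accuracy of the subset
and ``c1 = |P| / d`` is the normalized feature count, so equal weights favor
the smaller of two equally accurate subsets.  ``kappa > 0`` turns the search
into the GAp variant, softly constraining the subset size to a target.

Evolution per run: tournament (or roulette) selection, single-point crossover,
per-chromosome mutation (a mutated chromosome flips each gene with probability
1/d), and elitism.  Replicate runs are aggregated by selection-frequency
consensus, ties broken by mean fitness contribution then name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cohort import Cohort
from .base import SelectionRequest, SelectionResult, SubsetScorer, candidate_pool


@dataclass(frozen=True)
class FitnessSpec:
    """Weights of the subset-size / performance trade-off."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    p_target: int | None = None
    kappa: float | None = None  # defaults to 1/d when p_target is set

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("fitness weights must be nonnegative")


@dataclass(frozen=True)
class GAParams:
    """Evolution schedule; defaults follow the reference configuration
    (population 5000, 500 generations, crossover 0.5, mutation 0.2)."""

    population: int = 5000
    generations: int = 500
    crossover_rate: float = 0.5
    mutation_rate: float = 0.2
    tournament_size: int = 3
    elitism: int = 1
    selection_scheme: str = "tournament"  # or "roulette"

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.selection_scheme not in ("tournament", "roulette"):
            raise ValueError("selection_scheme must be tournament or roulette")


def fitness_value(
    bacc: float, subset_size: int, d: int, spec: FitnessSpec
) -> float:
    """The scalar fitness of a subset given its CV BACC and size."""
    val = spec.lambda2 * bacc - spec.lambda1 * subset_size / d
    if spec.p_target is not None:
        kappa = spec.kappa if spec.kappa is not None else 1.0 / d
        val -= kappa * abs(subset_size - spec.p_target)
    return val


def _evolve_once(
    scorer: SubsetScorer,
    fitness: FitnessSpec,
    params: GAParams,
    init_density: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[float]]:
    """One GA run; returns (best mask, best fitness, best-fitness trace)."""
    d = scorer.d
    pop = rng.random((params.population, d)) < init_density
    for row in pop:  # never evaluate an empty chromosome
        if not row.any():
            row[rng.integers(d)] = True

    def evaluate(population: np.ndarray) -> np.ndarray:
        return np.array([
            fitness_value(scorer.score_mask(ind), int(ind.sum()), d, fitness)
            for ind in population
        ])

    fit = evaluate(pop)
    trace = [float(fit.max())]
    for _ in range(params.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: params.elitism]].copy()
        if params.selection_scheme == "tournament":
            t = params.tournament_size
            contenders = rng.integers(0, len(pop), size=(len(pop), t))
            winners = contenders[
                np.arange(len(pop)), np.argmax(fit[contenders], axis=1)
            ]
        else:  # roulette on rank weights (fitness can be negative)
            ranks = np.empty(len(pop))
            ranks[order] = np.arange(len(pop), 0, -1)
            w = ranks / ranks.sum()
            winners = rng.choice(len(pop), size=len(pop), p=w)
        parents = pop[winners]
        children = parents.copy()
        for i in range(0, len(children) - 1, 2):
            if rng.random() < params.crossover_rate:
                cut = rng.integers(1, d)
                a = children[i].copy()
                children[i, cut:] = children[i + 1, cut:]
                children[i + 1, cut:] = a[cut:]
        mutate = rng.random(len(children)) < params.mutation_rate
        if mutate.any():
            flips = rng.random((int(mutate.sum()), d)) < (1.0 / d)
            children[mutate] ^= flips
        for row in children:
            if not row.any():
                row[rng.integers(d)] = True
        children[: params.elitism] = elite
        pop = children
        fit = evaluate(pop)
        trace.append(float(fit.max()))
    best = int(np.argmax(fit))
    return pop[best].copy(), float(fit[best]), trace


def ga_select(
    cohort: Cohort,
    request: SelectionRequest,
    fitness: FitnessSpec | None = None,
    params: GAParams | None = None,
    task: str = "three_class",
) -> SelectionResult:
    """Run ``request.runs`` GA replicates and form the frequency consensus."""
    fitness = fitness or FitnessSpec()
    params = params or GAParams()
    pool = candidate_pool(cohort, request)
    scorer = SubsetScorer(
        cohort, pool, estimator=request.estimator, task=task, seed=request.seed
    )
    d = scorer.d
    init_density = min(max(request.p / d, 1.0 / d), 0.9)
    master = np.random.default_rng(request.seed)
    run_subsets: list[list[str]] = []
    run_fitness: list[float] = []
    traces: list[list[float]] = []
    for _ in range(request.runs):
        rng = np.random.default_rng(master.integers(2**31))
        mask, best_fit, trace = _evolve_once(scorer, fitness, params,
                                             init_density, rng)
        run_subsets.append([pool[j] for j in np.flatnonzero(mask)])
        run_fitness.append(best_fit)
        traces.append(trace)

    n_runs = len(run_subsets)
    freq: dict[str, float] = {}
    contrib: dict[str, float] = {}
    for subset, f in zip(run_subsets, run_fitness):
        for name in subset:
            freq[name] = freq.get(name, 0.0) + 1.0 / n_runs
            contrib[name] = contrib.get(name, 0.0) + f / n_runs
    ranked = sorted(freq, key=lambda n: (-freq[n], -contrib[n], n))
    selected = ranked[: request.p]
    if len(selected) < request.p:  # consensus support smaller than p: pad
        rest = [n for n in pool if n not in freq]
        selected = selected + rest[: request.p - len(selected)]
    return SelectionResult(request, selected, freq,
                           trace=[{"best_fitness": t} for t in traces])
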