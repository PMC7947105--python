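"""Genetic function approximation: GA-driven descriptor-subset selection.

Candidate QSAR models are descriptor subsets; each is fitted by ordinary
least squares and scored with Friedman's lack-of-fit (LOF), whose
complexity penalty discourages large models.  A generational GA with
tournament selection, single-point subset crossover, member-swap mutation
and elitism evolves the population; elitism makes the best score
monotonically non-increasing across generations.

``enumerate_models`` fits every subset of a given size exactly and serves
as the brute-force oracle the GA is tested against on small instances.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .dataio import QsarDataset
from .linear_model import LinearModel, fit_ols

__all__ = ["GfaConfig", "GfaResult", "gfa_search", "enumerate_models"]


@dataclass
class GfaConfig:
    population_size: int = 100
    generations: int = 500
    model_terms: tuple[int, int] = (4, 4)  # (min, max) descriptors per model
    mutation_probability: float = 0.1
    crossover_probability: float = 0.9
    d_smoothing: float = 0.5
    seed: int = 0
    elitism: int = 2
    tournament_size: int = 3
    immigrant_fraction: float = 0.05  # fresh random subsets per generation
    top_k: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.model_terms
        if not (1 <= lo <= hi):
            raise ValueError("model_terms must satisfy 1 <= min <= max")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for prob in (self.mutation_probability, self.crossover_probability):
            if not (0.0 <= prob <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GfaResult:
    ranked_models: list[tuple[LinearModel, float]]  # ascending by LOF
    history: list[float]  # best LOF per generation
    config: GfaConfig
    seed: int

    @property
    def best(self) -> LinearModel:
        return self.ranked_models[0][0]


class _Fitness:
    """LOF of the OLS fit on a descriptor subset, memoized by subset."""

    def __init__(self, X: np.ndarray, y: np.ndarray, names: list[str], d: float):
        self.X = X
        self.y = y
        self.names = names
        self.d = d
        self.cache: dict[frozenset[int], float] = {}

    def __call__(self, subset: tuple[int, ...]) -> float:
        key = frozenset(subset)
        if key not in self.cache:
            cols = sorted(key)
            try:
                model = fit_ols(
                    self.X[:, cols],
                    self.y,
                    descriptor_names=[self.names[j] for j in cols],
                    d_smoothing=self.d,
                )
                self.cache[key] = model.lof
            except (ValueError, np.linalg.LinAlgError):
                self.cache[key] = np.inf
        return self.cache[key]

    def fit(self, subset: tuple[int, ...]) -> LinearModel:
        cols = sorted(set(subset))
        return fit_ols(
            self.X[:, cols],
            self.y,
            descriptor_names=[self.names[j] for j in cols],
            d_smoothing=self.d,
        )


def _repair(
    genes: list[int], lo: int, hi: int, n_desc: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Dedupe and resize a child subset to the allowed term range."""
    genes = list(dict.fromkeys(genes))
    while len(genes) > hi:
        genes.pop(int(rng.integers(len(genes))))
    pool = [j for j in range(n_desc) if j not in genes]
    while len(genes) < lo and pool:
        genes.append(pool.pop(int(rng.integers(len(pool)))))
    return tuple(sorted(genes))


def gfa_search(dataset: QsarDataset, config: GfaConfig | None = None) -> GfaResult:
    """Evolve descriptor subsets by LOF fitness; deterministic given the seed.

    Operates on the training partition when the dataset carries one,
    otherwise on all compounds.  Returns the final population deduplicated
    by descriptor set and ranked ascending by LOF.
    """
    config = config or GfaConfig()
    work = dataset.subset("train") if dataset.partition is not None else dataset
    X = work.table.values
    y = work.y
    names = work.table.descriptor_names
    n, n_desc = X.shape
    lo, hi = config.model_terms
    if hi > n_desc:
        raise ValueError(
            f"model_terms max {hi} exceeds the {n_desc} available descriptors"
        )
    if n <= hi + 1:
        raise ValueError(f"training size {n} too small for {hi}-term models")

    rng = np.random.default_rng(config.seed)
    fitness = _Fitness(X, y, names, config.d_smoothing)

    def random_subset() -> tuple[int, ...]:
        size = int(rng.integers(lo, hi + 1))
        return tuple(sorted(rng.choice(n_desc, size=size, replace=False).tolist()))

    population = [random_subset() for _ in range(config.population_size)]
    history: list[float] = []

    def tournament() -> tuple[int, ...]:
        picks = rng.integers(len(population), size=config.tournament_size)
        return min((population[i] for i in picks), key=fitness)

    n_immigrants = int(config.immigrant_fraction * config.population_size)
    for _ in range(config.generations):
        scored = sorted(population, key=fitness)
        history.append(fitness(scored[0]))
        next_pop = scored[: config.elitism]
        # random immigrants guard against premature convergence
        for _ in range(min(n_immigrants, config.population_size - len(next_pop))):
            next_pop.append(random_subset())
        while len(next_pop) < config.population_size:
            parent_a, parent_b = tournament(), tournament()
            if rng.random() < config.crossover_probability:
                a, b = sorted(parent_a), sorted(parent_b)
                cut_a = int(rng.integers(len(a) + 1))
                cut_b = int(rng.integers(len(b) + 1))
                child = a[:cut_a] + b[cut_b:]
            else:
                child = list(parent_a)
            # member-swap mutation: replace a gene with a random non-member
            mutated = list(dict.fromkeys(child))
            for i in range(len(mutated)):
                if rng.random() < config.mutation_probability:
                    outside = [j for j in range(n_desc) if j not in mutated]
                    if outside:
                        mutated[i] = outside[int(rng.integers(len(outside)))]
            next_pop.append(_repair(mutated, lo, hi, n_desc, rng))
        population = next_pop

    finals = sorted(set(population), key=lambda s: (fitness(s), s))
    if all(np.isinf(fitness(s)) for s in finals):
        raise ValueError("every candidate fit was rank-deficient")
    ranked = []
    for subset in finals[: config.top_k]:
        score = fitness(subset)
        if np.isinf(score):
            continue
        ranked.append((fitness.fit(subset), score))
    return GfaResult(
        ranked_models=ranked, history=history, config=config, seed=config.seed
    )


def enumerate_models(
    dataset: QsarDataset,
    subset_size: int,
    d_smoothing: float = 0.5,
    cap: int = 100_000,
) -> list[tuple[tuple[str, ...], float]]:
    """Fit and LOF-score every descriptor subset of the given size; exact.

    The brute-force oracle for :func:`gfa_search`.  Refuses instances with
    more than ``cap`` subsets.
    """
    work = dataset.subset("train") if dataset.partition is not None else dataset
    names = work.table.descriptor_names
    n_desc = len(names)
    if subset_size > n_desc:
        raise ValueError(
            f"subset_size {subset_size} exceeds {n_desc} descriptors"
        )
    total = comb(n_desc, subset_size)
    if total > cap:
        raise ValueError(
            f"{total} subsets exceed the cap of {cap}; use gfa_search instead"
        )
    fitness = _Fitness(work.table.values, work.y, names, d_smoothing)
    out = []
    for subset in combinations(range(n_desc), subset_size):
        score = fitness(subset)
        if np.isfinite(score):
            out.append((tuple(names[j] for j in subset), score))
    out.sort(key=lambda t: t[1])
    return out
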