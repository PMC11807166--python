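"""Adaptive genetic-algorithm feature selector.

Chromosomes are binary inclusion vectors over the feature columns. Each
generation is evaluated, roulette-wheel parents are drawn with probability
proportional to fitness, offspring are produced by a per-gene probabilistic
swap crossover and mutated with a flip probability that increases linearly
from ``min_mutation_prob`` at the first generation to ``max_mutation_prob``
at the last. The best solution ever seen is tracked globally (and
re-injected over the worst member if it ever vanishes from the population),
so the best-fitness trajectory is non-decreasing.

The fitness of a chromosome is

    fitness = alpha * acc + (1 - alpha) * (d - sum_i agent_i) / d

where ``acc`` is either a filter surrogate — the mean mRMR score of the
selected features, normalized by the best single-feature score — or, in
wrapper mode, the validation accuracy of a KNN classifier fitted on the
training rows restricted to the selected features. The filter surrogate is
the cheap default: it removes the classifier from the evolutionary loop
entirely. The second term rewards small feature subsets with weight
``1 - alpha``.

All randomness flows through a single ``numpy`` Generator seeded from the
config, consumed in a fixed call order, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import List, Optional

import numpy as np

from .datasets import FeatureDataset
from .errors import EmptySelectionError, GafsError, MissingSplitError
from .filtering import FilterScores, get_filter

logger = logging.getLogger(__name__)

FITNESS_MODES = ("filter", "wrapper")
CROSSOVER_OPS = ("uniform", "k_point")


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary hyperparameters.

    Defaults are the published configuration of the method: population 20,
    60 iterations, crossover probability 0.8, mutation probability growing
    from 0.01 to 0.04, accuracy weight alpha 0.99, KNN with k = 5.
    """

    population_size: int = 20
    max_iterations: int = 60
    crossover_prob: float = 0.8
    min_mutation_prob: float = 0.01
    max_mutation_prob: float = 0.04
    alpha: float = 0.99
    fitness_mode: str = "filter"
    knn_k: int = 5
    seed: int = 0
    # per-gene probabilistic swap is the default operator; a classical
    # k-point variant is available behind this switch
    crossover_op: str = "uniform"
    n_crossover_points: int = 2
    filter_name: str = "mrmr"

    def __post_init__(self):
        if self.population_size < 2:
            raise GafsError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise GafsError("max_iterations must be >= 1")
        for name in ("crossover_prob", "min_mutation_prob", "max_mutation_prob",
                     "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GafsError(f"{name} must be in [0, 1], got {v}")
        if self.min_mutation_prob > self.max_mutation_prob:
            raise GafsError("min_mutation_prob must be <= max_mutation_prob")
        if self.fitness_mode not in FITNESS_MODES:
            raise GafsError(f"fitness_mode must be one of {FITNESS_MODES}")
        if self.crossover_op not in CROSSOVER_OPS:
            raise GafsError(f"crossover_op must be one of {CROSSOVER_OPS}")
        if self.knn_k < 1:
            raise GafsError("knn_k must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FSResult:
    """Outcome of a GA run: the best chromosome, its fitness, the
    per-iteration best-fitness trajectory (non-decreasing), the selected
    feature indices, and the number of fitness evaluations spent."""

    best_chromosome: np.ndarray
    best_fitness: float
    trajectory: List[float]
    selected_indices: np.ndarray
    evaluations: int


# ---------------------------------------------------------------- operators


def repair(genes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Switch one uniformly random gene on if the chromosome is all zero
    (the mean over an empty selection is undefined)."""
    if not genes.any():
        genes = genes.copy()
        genes[rng.integers(genes.size)] = 1
    return genes


def initialize_population(
    d: int, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random initial population with varied subset sizes.

    Each chromosome draws its own inclusion density uniformly from
    [0.2, 0.8] and then draws genes Bernoulli(density), so popcounts span a
    wide range; all-zero chromosomes are repaired.
    """
    if d < 1:
        raise GafsError("need at least one feature")
    pop = np.empty((config.population_size, d), dtype=np.int8)
    for i in range(config.population_size):
        density = rng.uniform(0.2, 0.8)
        genes = (rng.random(d) < density).astype(np.int8)
        pop[i] = repair(genes, rng)
    return pop


def chromosome_score(genes: np.ndarray, scores: FilterScores) -> float:
    """Mean mRMR score over the selected positions."""
    sel = np.asarray(genes, dtype=bool)
    if not sel.any():
        raise EmptySelectionError("chromosome selects no feature")
    return float(scores.scores[sel].mean())


def weighted_objective(acc: float, n_selected: int, d: int, alpha: float) -> float:
    """alpha * acc + (1 - alpha) * (d - n_selected) / d."""
    return alpha * acc + (1.0 - alpha) * (d - n_selected) / d


def fitness(
    genes: np.ndarray,
    ds: FeatureDataset,
    scores: FilterScores,
    config: GAConfig,
) -> float:
    """Fitness of one chromosome on a dataset.

    Filter mode: acc is the chromosome's mean mRMR score normalized to
    [0, 1] by the maximum single-feature score (capped at 1). Wrapper mode:
    acc is KNN(k=knn_k) validation accuracy, trained on the train split
    restricted to the selected features. Test rows never enter fitness.
    """
    genes = np.asarray(genes)
    sel = genes.astype(bool)
    if not sel.any():
        raise EmptySelectionError("chromosome selects no feature")
    d = genes.size
    if config.fitness_mode == "filter":
        max_score = float(scores.scores.max())
        if max_score <= 0:
            acc = 0.0
        else:
            acc = min(chromosome_score(genes, scores) / max_score, 1.0)
    else:
        acc = _wrapper_accuracy(sel, ds, config)
    return weighted_objective(acc, int(sel.sum()), d, config.alpha)


def _wrapper_accuracy(sel: np.ndarray, ds: FeatureDataset, config: GAConfig) -> float:
    from .metrics import knn_predict  # deferred: metrics imports nothing from here

    train = ds.rows("train")
    if ds.split_assignment is None or not np.any(
        np.asarray(ds.split_assignment) == "val"
    ):
        raise MissingSplitError("wrapper fitness needs a validation split")
    val = ds.rows("val")
    pred = knn_predict(
        ds.matrix[np.ix_(train, sel)],
        ds.labels[train],
        ds.matrix[np.ix_(val, sel)],
        k=config.knn_k,
    )
    return float(np.mean(pred == ds.labels[val]))


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one index with probability proportional to fitness.

    Fitness values that are not all positive are first shifted so the
    minimum sits just above zero (filter scores can be arbitrarily scaled
    or negative-shifted); already-positive fitnesses are used as-is so the
    selection probabilities are exactly fitness_i / sum(fitness).
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise GafsError("empty population")
    if not np.all(np.isfinite(f)):
        raise GafsError("fitnesses must be finite")
    lo = f.min()
    if lo <= 0.0:
        f = f - lo + 1e-12
    total = f.sum()
    if total <= 0.0:  # all (shifted) mass identical at the epsilon floor
        return int(rng.integers(f.size))
    cum = np.cumsum(f / total)
    return int(np.searchsorted(cum, rng.random(), side="right").clip(0, f.size - 1))


def crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    crossover_prob: float,
    rng: np.random.Generator,
) -> tuple:
    """Per-gene probabilistic swap: at every position, with probability
    ``crossover_prob`` the parents' values are exchanged in the children.
    The per-position multiset of values is conserved."""
    p1 = np.asarray(p1, dtype=np.int8)
    p2 = np.asarray(p2, dtype=np.int8)
    if p1.shape != p2.shape:
        raise GafsError("parents must have equal length")
    swap = rng.random(p1.size) < crossover_prob
    c1 = np.where(swap, p2, p1).astype(np.int8)
    c2 = np.where(swap, p1, p2).astype(np.int8)
    return repair(c1, rng), repair(c2, rng)


def k_point_crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    n_points: int,
    rng: np.random.Generator,
) -> tuple:
    """Classical k-point crossover (alternating segments between cut points)."""
    p1 = np.asarray(p1, dtype=np.int8)
    p2 = np.asarray(p2, dtype=np.int8)
    if p1.shape != p2.shape:
        raise GafsError("parents must have equal length")
    d = p1.size
    n_points = min(n_points, max(d - 1, 0))
    if n_points == 0:
        return p1.copy(), p2.copy()
    cuts = np.sort(rng.choice(np.arange(1, d), size=n_points, replace=False))
    take_other = np.zeros(d, dtype=bool)
    flip = False
    prev = 0
    for cut in list(cuts) + [d]:
        take_other[prev:cut] = flip
        flip = not flip
        prev = cut
    c1 = np.where(take_other, p2, p1).astype(np.int8)
    c2 = np.where(take_other, p1, p2).astype(np.int8)
    return repair(c1, rng), repair(c2, rng)


def mutation_prob_at(iteration: int, config: GAConfig) -> float:
    """Linearly interpolated flip probability: min at iteration 0, max at
    the last iteration (constant min when there is a single iteration)."""
    if not 0 <= iteration < config.max_iterations:
        raise GafsError(
            f"iteration {iteration} outside [0, {config.max_iterations})"
        )
    if config.max_iterations == 1:
        return config.min_mutation_prob
    span = config.max_mutation_prob - config.min_mutation_prob
    return config.min_mutation_prob + span * iteration / (config.max_iterations - 1)


def mutate(genes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip every gene independently with probability p; repair to non-empty."""
    if not 0.0 <= p <= 1.0:
        raise GafsError("mutation probability must be in [0, 1]")
    genes = np.asarray(genes, dtype=np.int8)
    flips = rng.random(genes.size) < p
    return repair(np.where(flips, 1 - genes, genes).astype(np.int8), rng)


# ---------------------------------------------------------------- main loop


def _sort_population(pop: np.ndarray, fits: np.ndarray):
    """Descending fitness; ties by popcount ascending, then lexicographic."""
    popcounts = pop.sum(axis=1)
    keys = sorted(
        range(pop.shape[0]),
        key=lambda i: (-fits[i], popcounts[i], tuple(pop[i])),
    )
    order = np.array(keys, dtype=int)
    return pop[order], fits[order]


def run_ga(
    ds: FeatureDataset,
    config: GAConfig,
    scores: Optional[FilterScores] = None,
) -> FSResult:
    """Run the adaptive GA on a dataset and return the best feature subset.

    The filter score vector is computed once on the training rows. Every
    generation: evaluate fitness, re-inject the global best over the worst
    member if it vanished, update the global best, sort the population,
    draw roulette parents, cross over, and mutate with the
    generation-dependent flip probability. Deterministic per config seed.
    """
    rng = np.random.default_rng(config.seed)
    d = ds.n_features
    if scores is None:
        scores = get_filter(config.filter_name)(ds, split="train")

    pop = initialize_population(d, config, rng)
    best_genes: Optional[np.ndarray] = None
    best_fit = -np.inf
    trajectory: List[float] = []
    evaluations = 0

    for t in range(config.max_iterations):
        fits = np.array([fitness(c, ds, scores, config) for c in pop])
        evaluations += len(pop)

        if best_genes is not None and not np.any(np.all(pop == best_genes, axis=1)):
            worst = int(np.argmin(fits))
            pop[worst] = best_genes
            fits[worst] = best_fit

        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genes = pop[gen_best].copy()
        trajectory.append(best_fit)

        pop, fits = _sort_population(pop, fits)
        p_mut = mutation_prob_at(t, config)
        logger.info(
            "generation %d: best=%.6f mean=%.6f mutation_prob=%.4f",
            t, best_fit, float(fits.mean()), p_mut,
        )

        children = []
        while len(children) < config.population_size:
            i = roulette_select(fits, rng)
            j = roulette_select(fits, rng)
            if config.crossover_op == "uniform":
                c1, c2 = crossover(pop[i], pop[j], config.crossover_prob, rng)
            else:
                c1, c2 = k_point_crossover(
                    pop[i], pop[j], config.n_crossover_points, rng
                )
            children.append(mutate(c1, p_mut, rng))
            children.append(mutate(c2, p_mut, rng))
        pop = np.array(children[: config.population_size], dtype=np.int8)

    assert best_genes is not None
    return FSResult(
        best_chromosome=best_genes,
        best_fitness=best_fit,
        trajectory=trajectory,
        selected_indices=np.flatnonzero(best_genes),
        evaluations=evaluations,
    )
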