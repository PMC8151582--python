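"""Genetic-algorithm wrapper feature selection.

A chromosome is a binary inclusion mask over the feature set.  Its fitness
is the mean validation F1 of the wrapped classifier across the holdout
partitions, multiplied by the feature-reduction term:

    fitness = mean_val_F1 * (NFeat - NCFeat)

where NFeat is the genome length and NCFeat the number of selected
features, so equal-performing smaller subsets always win and selecting
everything scores zero.  Operators follow the reference toolbox setup:
tournament selection of size 2, elite count 2, arithmetic crossover with
probability 0.8, uniform mutation at rate 0.01, termination when the best
fitness improves by less than 1e-6 over 150 consecutive generations.

Arithmetic crossover draws a single convex weight u per child and rounds
the blend ``u*p1 + (1-u)*p2`` back to binary, which for binary genomes
returns the nearer parent's value on every gene (the toolbox operator's
behaviour when genes are restricted to {0, 1}); population diversity is
maintained by the Bernoulli(0.5) initialization and the mutation children.

Fitness evaluations only ever touch the training and validation thirds of
each partition; the testing third is reserved for the final generalization
estimate and is never seen during selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS
from .models import POSITIVE_LABEL, ClassifierSpec, fit_predict

__all__ = [
    "GAConfig",
    "Chromosome",
    "FitnessEvaluation",
    "make_partitions",
    "evaluate_fitness",
    "tournament_select",
    "arithmetic_crossover",
    "uniform_mutation",
    "run_ga",
    "GAResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 203
    crossover_prob: float = 0.8
    mutation_rate: float = 0.01
    tournament_size: int = 2
    elite_count: int = 2
    stall_generations: int = 150
    fitness_tolerance: float = 1e-6
    max_generations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError(
                f"population_size must be >= 4, got {self.population_size}"
            )
        for name in ("crossover_prob", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class Chromosome:
    """Binary inclusion mask over the feature set, with cached fitness."""

    mask: np.ndarray
    fitness: float | None = None

    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class FitnessEvaluation:
    mean_val_f1: float
    nfeat: int
    ncfeat: int

    @property
    def fitness(self) -> float:
        return self.mean_val_f1 * (self.nfeat - self.ncfeat)


def make_partitions(
    labels, n_partitions: int = 30, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Stratified random train/validation/test thirds of the balanced table.

    Within each partition the three index sets are disjoint, cover every
    row, and hold each class in equal proportion (to within one row).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    by_class = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    partitions = []
    for _ in range(n_partitions):
        thirds: list[list[int]] = [[], [], []]
        for idx in by_class:
            perm = rng.permutation(idx)
            cuts = [len(idx) // 3, 2 * len(idx) // 3]
            thirds[0].extend(perm[: cuts[0]])
            thirds[1].extend(perm[cuts[0] : cuts[1]])
            thirds[2].extend(perm[cuts[1] :])
        partitions.append(tuple(np.sort(np.array(t, dtype=int)) for t in thirds))
    return partitions


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in table.columns
            if c not in META_COLUMNS and c != "is_synthetic"]
    X = table[cols].to_numpy(dtype=np.float64)
    y = (table["label"].to_numpy() == POSITIVE_LABEL).astype(int)
    return X, y


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    den = 2 * tp + fp + fn
    return float(2 * tp / den) if den > 0 else 0.0


def evaluate_fitness(
    mask: np.ndarray,
    classifier_spec: ClassifierSpec,
    table: pd.DataFrame,
    partitions,
) -> FitnessEvaluation:
    """Mean validation F1 of the masked classifier over the partitions.

    For each partition the classifier is fit on the masked training rows and
    scored (F1, preterm positive) on the validation rows; the testing third
    is untouched.  Raises ValueError for an all-zero mask (callers assign
    such chromosomes the minimal fitness instead of evaluating them).
    """
    mask = np.asarray(mask, dtype=bool)
    ncfeat = int(mask.sum())
    if ncfeat == 0:
        raise ValueError("mask selects no features")
    X, y = _split_xy(table)
    Xm = X[:, mask]
    f1s = []
    for train_idx, val_idx, _test_idx in partitions:
        pred, _ = fit_predict(classifier_spec, Xm[train_idx], y[train_idx],
                              Xm[val_idx])
        f1s.append(_f1(y[val_idx], pred))
    return FitnessEvaluation(
        mean_val_f1=float(np.mean(f1s)), nfeat=mask.size, ncfeat=ncfeat
    )


def tournament_select(
    population: list[Chromosome], rng: np.random.Generator, size: int = 2
) -> Chromosome:
    """Best of ``size`` uniformly drawn candidates; ties broken uniformly."""
    if not population:
        raise ValueError("empty population")
    if any(c.fitness is None for c in population):
        raise ValueError("population must be fully evaluated before selection")
    picks = rng.integers(0, len(population), size=size)
    best = [picks[0]]
    for i in picks[1:]:
        if population[i].fitness > population[best[0]].fitness:
            best = [i]
        elif population[i].fitness == population[best[0]].fitness:
            best.append(i)
    return population[best[rng.integers(0, len(best))]]


def arithmetic_crossover(
    p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Round the convex blend u*p1 + (1-u)*p2 (one u per child) to binary.

    Genes where the parents agree keep the shared value; an exact 0.5 blend
    is resolved by a fair coin per gene.
    """
    p1 = np.asarray(p1, dtype=np.int8)
    p2 = np.asarray(p2, dtype=np.int8)
    if p1.shape != p2.shape:
        raise ValueError(f"parent length mismatch: {p1.shape} vs {p2.shape}")
    u = rng.uniform()
    blend = u * p1 + (1.0 - u) * p2
    child = np.where(blend > 0.5, 1, 0).astype(np.int8)
    halves = blend == 0.5
    if halves.any():
        child[halves] = rng.integers(0, 2, size=int(halves.sum()))
    return child


def uniform_mutation(
    mask: np.ndarray, rng: np.random.Generator, rate: float = 0.01
) -> np.ndarray:
    """Independently redraw each gene uniformly from {0, 1} with prob. ``rate``."""
    mask = np.asarray(mask, dtype=np.int8).copy()
    hit = rng.random(mask.size) < rate
    mask[hit] = rng.integers(0, 2, size=int(hit.sum()), dtype=np.int8)
    return mask


@dataclass
class GAResult:
    best: Chromosome
    best_eval: FitnessEvaluation
    best_history: list[float] = field(default_factory=list)
    mean_history: list[float] = field(default_factory=list)
    generations: int = 0
    converged: bool = False


def run_ga(
    table: pd.DataFrame,
    classifier_spec: ClassifierSpec,
    cfg: GAConfig,
    partitions,
    genome_length: int | None = None,
) -> GAResult:
    """Generational GA returning the best-ever chromosome and fitness history.

    Per generation the ``elite_count`` best chromosomes are copied unchanged;
    of the remaining children, a ``crossover_prob`` fraction comes from
    arithmetic crossover of tournament parents and the rest are
    mutation-only copies of tournament parents.  Identical masks are
    evaluated once (fitness cache).  Deterministic under ``cfg.seed``.
    """
    n_features = genome_length
    if n_features is None:
        n_features = len(
            [c for c in table.columns
             if c not in META_COLUMNS and c != "is_synthetic"]
        )
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}
    eval_cache: dict[bytes, FitnessEvaluation] = {}

    def fitness_of(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            if mask.sum() == 0:
                logger.warning("all-zero chromosome: assigned minimal fitness")
                cache[key] = -np.inf
            else:
                ev = evaluate_fitness(mask, classifier_spec, table, partitions)
                eval_cache[key] = ev
                cache[key] = ev.fitness
        return cache[key]

    population = [
        Chromosome(mask=rng.integers(0, 2, size=n_features, dtype=np.int8))
        for _ in range(cfg.population_size)
    ]
    best_ever: Chromosome | None = None
    best_history: list[float] = []
    mean_history: list[float] = []
    stall = 0
    gen = 0
    converged = False
    for gen in range(1, cfg.max_generations + 1):
        for chrom in population:
            chrom.fitness = fitness_of(chrom.mask)
        population.sort(key=lambda c: c.fitness, reverse=True)
        gen_best = population[0]
        finite = [c.fitness for c in population if np.isfinite(c.fitness)]
        mean_history.append(float(np.mean(finite)) if finite else -np.inf)
        if best_ever is None or gen_best.fitness > best_ever.fitness:
            improvement = (
                np.inf if best_ever is None
                else gen_best.fitness - best_ever.fitness
            )
            best_ever = Chromosome(gen_best.mask.copy(), gen_best.fitness)
            stall = 0 if improvement >= cfg.fitness_tolerance else stall + 1
        else:
            stall += 1
        best_history.append(best_ever.fitness)
        if stall >= cfg.stall_generations:
            converged = True
            break
        # next generation
        elites = [Chromosome(c.mask.copy(), c.fitness)
                  for c in population[: cfg.elite_count]]
        n_children = cfg.population_size - cfg.elite_count
        n_cross = int(round(cfg.crossover_prob * n_children))
        children: list[Chromosome] = []
        for _ in range(n_cross):
            pa = tournament_select(population, rng, cfg.tournament_size)
            pb = tournament_select(population, rng, cfg.tournament_size)
            children.append(Chromosome(arithmetic_crossover(pa.mask, pb.mask, rng)))
        for _ in range(n_children - n_cross):
            parent = tournament_select(population, rng, cfg.tournament_size)
            children.append(
                Chromosome(uniform_mutation(parent.mask, rng, cfg.mutation_rate))
            )
        population = elites + children
    else:
        logger.warning(
            "GA reached max_generations=%d without meeting the stall "
            "criterion; returning best-so-far", cfg.max_generations,
        )

    key = best_ever.mask.tobytes()
    best_eval = eval_cache.get(key)
    if best_eval is None:  # best was an all-zero guard case (degenerate run)
        raise RuntimeError("GA produced no evaluable chromosome")
    return GAResult(
        best=best_ever,
        best_eval=best_eval,
        best_history=best_history,
        mean_history=mean_history,
        generations=gen,
        converged=converged,
    )
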