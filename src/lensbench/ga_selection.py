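"""GA-wrapper feature selection with SVM cross-validated accuracy as fitness.

A chromosome is a bit mask over the feature vector (bit 0 = feature dropped).
Fitness is the stratified k-fold cross-validated accuracy of a linear SVM
restricted to the selected features, evaluated inside the training data only
so that selection never sees the outer test fold. The GA is generational
with tournament selection (size 2), single-point crossover, per-bit flip
mutation at rate mutation_rate / length, and elitism of one, so the
best-ever fitness is non-decreasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import svm_train

__all__ = ["GAConfig", "Chromosome", "ga_select", "report_selection"]


@dataclass(frozen=True)
class GAConfig:
    population: int = 30
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    max_generations: int = 200
    seed: int = 0
    fitness_folds: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be even and >= 2")
        if self.fitness_folds < 2:
            raise ValueError("fitness_folds must be >= 2")


@dataclass
class Chromosome:
    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, mask: np.ndarray, folds: int, seed: int) -> float:
    Xm = X[:, mask]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(Xm, y):
        model = svm_train(Xm[train_idx], y[train_idx], kernel="linear")
        correct += int((model.predict(Xm[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


def ga_select(
    X: np.ndarray, y: np.ndarray, cfg: GAConfig = GAConfig()
) -> tuple[Chromosome, np.ndarray]:
    """Run the GA; returns the best-ever chromosome and per-generation best fitness."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    dim = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def repair(bits: np.ndarray) -> np.ndarray:
        if not bits.any():
            bits = bits.copy()
            bits[rng.integers(dim)] = True
        return bits

    def fitness(bits: np.ndarray) -> float:
        key = np.packbits(bits).tobytes()
        if key not in cache:
            cache[key] = _cv_accuracy(X, y, bits, cfg.fitness_folds, cfg.seed)
        return cache[key]

    population = [repair(rng.random(dim) < 0.5) for _ in range(cfg.population)]
    scores = np.array([fitness(b) for b in population])
    best = Chromosome(population[int(scores.argmax())].copy(), float(scores.max()))
    history = np.empty(cfg.max_generations)

    p_flip = cfg.mutation_rate / dim
    for gen in range(cfg.max_generations):
        # tournament selection, size 2
        parents = []
        for _ in range(cfg.population):
            a, b = rng.integers(cfg.population, size=2)
            parents.append(population[a] if scores[a] >= scores[b] else population[b])
        # single-point crossover on consecutive pairs
        children: list[np.ndarray] = []
        for a, b in zip(parents[0::2], parents[1::2]):
            if rng.random() < cfg.crossover_rate and dim > 1:
                cut = int(rng.integers(1, dim))
                children.append(np.concatenate([a[:cut], b[cut:]]))
                children.append(np.concatenate([b[:cut], a[cut:]]))
            else:
                children.append(a.copy())
                children.append(b.copy())
        # per-bit flip mutation + all-zero repair
        for i, child in enumerate(children):
            flips = rng.random(dim) < p_flip
            child ^= flips
            children[i] = repair(child)
        child_scores = np.array([fitness(b) for b in children])
        # elitism of one: the best-ever replaces the worst child
        worst = int(child_scores.argmin())
        children[worst] = best.bits.copy()
        child_scores[worst] = best.fitness
        population, scores = children, child_scores
        top = int(scores.argmax())
        if scores[top] > best.fitness:
            best = Chromosome(population[top].copy(), float(scores[top]))
        history[gen] = best.fitness

    return best, history


def report_selection(chromosome: Chromosome, block_map: dict[str, tuple[int, int]]) -> dict[str, int]:
    """Count selected features per named block."""
    return {
        name: int(chromosome.bits[start:stop].sum())
        for name, (start, stop) in block_map.items()
    }
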