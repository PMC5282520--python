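"""Sparse-representation classification with a differential-evolution L1 solver.

A query sample y is expressed as a sparse linear combination of the columns
of an over-complete dictionary A = [A_neg | A_pos] built from training
samples. Sparsity is sought by minimizing ||x||_1 subject to the residual
constraint ||A x - y||_2 <= eps; the constrained problem is attacked with
differential evolution (DE/rand/1/bin) whose greedy replacement step uses
Deb's feasibility rules:

* two feasible candidates -> keep the one with the better objective;
* two infeasible candidates -> keep the smaller constraint violation;
* feasible vs infeasible -> keep the feasible one.

Class assignment then compares per-class reconstruction residuals
r_i = ||y - A delta_i(x)||_2, where delta_i zeroes the coefficients outside
class i; the query is assigned the class with the smallest residual (ties
to the negative class), and r_neg - r_pos serves as the ROC score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prep import resize, to_gray
from .synthetic import LabeledImageSet

__all__ = ["SRCProblem", "DEConfig", "DEResult", "build_dictionary", "de_solve_l1", "src_classify"]


@dataclass
class SRCProblem:
    """Over-complete dictionary with class partition and feasibility tolerance."""

    A: np.ndarray  # m x n, unit-norm columns
    class_slices: dict[int, slice]  # label -> column range
    epsilon_rel: float = 0.05  # eps = epsilon_rel * ||y||_2

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2:
            raise ValueError("dictionary must be a 2-D matrix")
        n = sum(s.stop - s.start for s in self.class_slices.values())
        if n != self.A.shape[1]:
            raise ValueError("class slices must partition the dictionary columns")
        if self.epsilon_rel <= 0:
            raise ValueError("epsilon_rel must be positive")

    def epsilon(self, y: np.ndarray) -> float:
        return self.epsilon_rel * float(np.linalg.norm(y))


@dataclass(frozen=True)
class DEConfig:
    population: int = 50
    scale_factor: float = 0.4  # F in the rand/1 mutation
    crossover_rate: float = 0.7
    max_iterations: int = 500
    seed: int = 0
    ls_anchor: bool = True  # seed one individual at the clipped least-squares solution

    def __post_init__(self) -> None:
        if not 0 < self.crossover_rate <= 1:
            raise ValueError("crossover_rate must lie in (0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.population < 4:
            raise ValueError("population must be >= 4")


@dataclass
class DEResult:
    x: np.ndarray
    objective: float  # ||x||_1
    violation: float  # max(0, ||Ax-y|| - eps)
    feasible: bool
    trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _prepare_sample(img: np.ndarray, sample_size: tuple[int, int]) -> np.ndarray:
    gray = to_gray(img) if img.ndim == 3 else np.asarray(img)
    # unit-normalized like the dictionary columns, so residual comparisons do
    # not reduce to overall image brightness
    return _unit(resize(gray, *sample_size).astype(np.float64).ravel())


def build_dictionary(
    train: LabeledImageSet | tuple[np.ndarray, np.ndarray],
    n_neg: int,
    n_pos: int,
    sample_size: tuple[int, int] | None = (5, 10),
    seed: int = 0,
) -> tuple[SRCProblem, callable, np.ndarray]:
    """Draw a class-partitioned dictionary from training data.

    ``train`` is either a labeled image set (columns are resized, grayscale,
    flattened pixel vectors — ``sample_size`` required) or a pre-computed
    ``(X, y)`` feature matrix (``sample_size`` ignored). Returns the problem,
    a ``transform(sample) -> m-vector`` closure for queries, and the indices
    of the training samples absorbed into the dictionary.
    """
    if isinstance(train, LabeledImageSet):
        if sample_size is None:
            raise ValueError("sample_size is required when building from images")
        X = np.stack([_prepare_sample(img, sample_size) for img in train.images])
        y = train.labels
        transform = lambda img: _prepare_sample(img, sample_size)  # noqa: E731
    else:
        X, y = train
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        transform = lambda v: _unit(np.asarray(v, dtype=np.float64))  # noqa: E731

    rng = np.random.default_rng(seed)
    neg_idx = np.flatnonzero(y == 0)
    pos_idx = np.flatnonzero(y == 1)
    if n_neg > len(neg_idx) or n_pos > len(pos_idx):
        raise ValueError(
            f"requested {n_neg} negatives / {n_pos} positives but only "
            f"{len(neg_idx)} / {len(pos_idx)} available"
        )
    chosen_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    chosen_pos = rng.choice(pos_idx, size=n_pos, replace=False)
    columns = np.concatenate([X[chosen_neg], X[chosen_pos]]).T
    norms = np.linalg.norm(columns, axis=0)
    norms[norms == 0] = 1.0
    A = columns / norms
    problem = SRCProblem(A, {0: slice(0, n_neg), 1: slice(n_neg, n_neg + n_pos)})
    return problem, transform, np.concatenate([chosen_neg, chosen_pos])


def _deb_better(obj_a: float, viol_a: float, obj_b: float, viol_b: float) -> bool:
    """True if candidate a is preferred over b under Deb's rules."""
    if viol_a == 0 and viol_b == 0:
        return obj_a < obj_b
    if viol_a > 0 and viol_b > 0:
        return viol_a < viol_b
    return viol_a == 0


def de_solve_l1(problem: SRCProblem, y: np.ndarray, cfg: DEConfig = DEConfig()) -> DEResult:
    """Minimize ||x||_1 s.t. ||Ax - y||_2 <= eps by DE/rand/1/bin with Deb selection."""
    A = problem.A
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (A.shape[0],):
        raise ValueError(f"query shape {y.shape} does not match dictionary rows {A.shape[0]}")
    eps = problem.epsilon(y)
    n = A.shape[1]
    rng = np.random.default_rng(cfg.seed)

    # population seeded inside the least-squares affine subspace {x: Ax ~ y}:
    # rand/1 mutation is an affine combination, so mutants inherit (near-)
    # feasibility and selection can concentrate on descending the L1 objective
    if cfg.ls_anchor:
        ls, *_ = np.linalg.lstsq(A, y, rcond=None)
        _, s, vt = np.linalg.svd(A, full_matrices=True)
        rank = int((s > s.max() * max(A.shape) * np.finfo(float).eps).sum()) if s.size else 0
        null_basis = vt[rank:].T  # n x (n - rank)
        scales = np.linspace(0.0, 1.0, cfg.population)[:, None]
        if null_basis.shape[1] > 0:
            drift = rng.normal(size=(cfg.population, null_basis.shape[1])) @ null_basis.T
        else:
            drift = np.zeros((cfg.population, n))
        pop = ls[None, :] + scales * drift
    else:
        pop = rng.uniform(-1.0, 1.0, size=(cfg.population, n))

    def evaluate(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        obj = np.abs(P).sum(axis=1)
        viol = np.maximum(0.0, np.linalg.norm(P @ A.T - y, axis=1) - eps)
        return obj, viol

    obj, viol = evaluate(pop)
    trace = np.empty(cfg.max_iterations + 1)

    def best_index() -> int:
        best = 0
        for i in range(1, cfg.population):
            if _deb_better(obj[i], viol[i], obj[best], viol[best]):
                best = i
        return best

    b = best_index()
    trace[0] = obj[b] if viol[b] == 0 else np.inf

    idx = np.arange(cfg.population)
    for it in range(cfg.max_iterations):
        # rand/1 mutation: r1, r2, r3 distinct from each other and the target
        r = np.empty((cfg.population, 3), dtype=int)
        for i in range(cfg.population):
            r[i] = rng.choice(np.delete(idx, i), size=3, replace=False)
        v = pop[r[:, 0]] + cfg.scale_factor * (pop[r[:, 1]] - pop[r[:, 2]])
        # binomial crossover with a forced component per individual
        mask = rng.random((cfg.population, n)) < cfg.crossover_rate
        mask[idx, rng.integers(0, n, size=cfg.population)] = True
        trial = np.where(mask, v, pop)

        t_obj, t_viol = evaluate(trial)
        # vectorized Deb replacement
        both_feas = (t_viol == 0) & (viol == 0)
        both_infeas = (t_viol > 0) & (viol > 0)
        accept = (
            (both_feas & (t_obj < obj))
            | (both_infeas & (t_viol < viol))
            | ((t_viol == 0) & (viol > 0))
        )
        pop[accept] = trial[accept]
        obj[accept] = t_obj[accept]
        viol[accept] = t_viol[accept]
        b = best_index()
        trace[it + 1] = obj[b] if viol[b] == 0 else np.inf

    b = best_index()
    return DEResult(
        x=pop[b].copy(),
        objective=float(obj[b]),
        violation=float(viol[b]),
        feasible=bool(viol[b] == 0),
        trace=trace,
    )


def src_classify(problem: SRCProblem, y: np.ndarray, x: np.ndarray) -> tuple[int, dict[int, float], float]:
    """Assign the class with the smallest class-restricted reconstruction residual.

    Returns ``(label, residuals, score)`` where ``score = r_neg - r_pos`` (a
    larger score favors the positive class). A residual tie goes to the
    negative class.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    residuals: dict[int, float] = {}
    for label, cols in problem.class_slices.items():
        restricted = np.zeros_like(x)
        restricted[cols] = x[cols]
        residuals[label] = float(np.linalg.norm(y - problem.A @ restricted))
    label = min(sorted(residuals), key=lambda c: (residuals[c], c))
    score = residuals[0] - residuals[1]
    return label, residuals, score
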