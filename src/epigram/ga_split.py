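"""Stage-1 genetic algorithm: train/test partition search by inter-class variance.

A candidate partition assigns an equal number of training rows to each class
(``tr`` fixes the training-set size). Its fitness is the class-averaged
inter-class deviation: per feature dimension, the sample standard deviation
of one class's training values *around the other class's sample standard
deviation*, averaged over dimensions and then over the two directions. The
mark/regenerate GA keeps high-fitness partitions and resamples the rest,
returning the maximum-fitness partition found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .config import GAConfig
from .types import FeatureTable


def _moments(X, X2, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column sums of x and x^2 over the selected rows (dense 1-D arrays)."""
    if sp.issparse(X):
        s1 = np.asarray(X[idx].sum(axis=0)).ravel()
        s2 = np.asarray(X2[idx].sum(axis=0)).ravel()
    else:
        s1 = X[idx].sum(axis=0)
        s2 = X2[idx].sum(axis=0)
    return s1, s2


def _directed_from_moments(
    s1a: np.ndarray, s2a: np.ndarray, m: int,
    s1b: np.ndarray, s2b: np.ndarray, n: int,
) -> float:
    """Per-dimension deviation of class a around class b's sample std, averaged.

    Uses only first and second moments, so it works identically for sparse
    and dense inputs. Tiny negative values from cancellation are clipped.
    """
    var_b = (s2b - s1b * s1b / n) / (n - 1)
    s_b = np.sqrt(np.clip(var_b, 0.0, None))
    dev = s2a - 2.0 * s_b * s1a + m * s_b * s_b
    per_dim = np.sqrt(np.clip(dev / (m - 1), 0.0, None))
    return float(per_dim.mean())


def average_variance(class_a: np.ndarray, class_b: np.ndarray) -> float:
    """Directed inter-class deviation of ``class_a`` relative to ``class_b``.

    Per feature dimension: the (m-1)-denominator standard deviation of
    ``class_a``'s values around the center given by ``class_b``'s sample
    standard deviation (ddof=1); the per-dimension values are averaged.
    Inputs are ``(m, d)`` and ``(n, d)`` arrays (1-D inputs are treated as
    single-dimension samples). Requires m >= 2 and n >= 2.
    """
    A = np.atleast_2d(np.asarray(class_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(class_b, dtype=np.float64))
    if A.shape[0] == 1 and A.shape[1] > 1 and np.ndim(class_a) == 1:
        A = A.T
    if B.shape[0] == 1 and B.shape[1] > 1 and np.ndim(class_b) == 1:
        B = B.T
    m, n = A.shape[0], B.shape[0]
    if m < 2 or n < 2:
        raise ValueError(f"need >= 2 samples per class, got m={m}, n={n}")
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ between classes")
    return _directed_from_moments(
        A.sum(axis=0), (A * A).sum(axis=0), m,
        B.sum(axis=0), (B * B).sum(axis=0), n,
    )


def solution_fitness(table: FeatureTable, train_indices: np.ndarray) -> float:
    """Class-averaged fitness of a candidate training partition.

    The mean, over the k classes, of the directed inter-class deviation of
    each class's training rows against the other classes' training rows.
    """
    train_indices = np.asarray(train_indices, dtype=np.intp)
    y = table.y[train_indices]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training partition must contain every class")
    X = table.X
    X2 = X.multiply(X).tocsr() if sp.issparse(X) else X * X
    vals = []
    for c in classes:
        a_idx = train_indices[y == c]
        b_idx = train_indices[y != c]
        if a_idx.size < 2 or b_idx.size < 2:
            raise ValueError("each class needs >= 2 training samples")
        s1a, s2a = _moments(X, X2, a_idx)
        s1b, s2b = _moments(X, X2, b_idx)
        vals.append(
            _directed_from_moments(s1a, s2a, a_idx.size, s1b, s2b, b_idx.size)
        )
    return float(np.mean(vals))


def mutation_threshold(fitnesses, mu: float) -> float:
    """Survival threshold: mean of the population fitnesses times ``mu``."""
    fitnesses = np.asarray(list(fitnesses), dtype=np.float64)
    if fitnesses.size == 0:
        raise ValueError("fitness collection is empty")
    return float(fitnesses.mean() * mu)


@dataclass
class SplitSolution:
    """A candidate (or final) train/test partition with its fitness."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fitness: float
    trace: list[float] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "n_train": int(self.train_indices.size),
            "n_test": int(self.test_indices.size),
            "fitness": self.fitness,
            "fitness_trace": self.trace,
        }


class VarianceMaxSplitter:
    """GA search for the maximum-variance train/test partition.

    After :meth:`fit`, exposes ``train_indices_``, ``test_indices_``,
    ``best_fitness_`` and the per-iteration best-so-far ``trace_``.

    Parameters
    ----------
    config : GAConfig, optional
        GA tunables; defaults to :class:`GAConfig` defaults.
    seed : int, optional
        Overrides ``config.seed`` when given.
    """

    def __init__(self, config: GAConfig | None = None, seed: int | None = None):
        self.config = config
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "seed": self.seed}

    def set_params(self, **params) -> "VarianceMaxSplitter":
        for k, v in params.items():
            if k not in ("config", "seed"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _resolved(self) -> tuple[GAConfig, int]:
        cfg = self.config if self.config is not None else GAConfig()
        seed = self.seed if self.seed is not None else cfg.seed
        return cfg, seed

    @staticmethod
    def _per_class_train_count(y: np.ndarray, tr: float) -> int:
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least two classes to split")
        k = classes.size
        per_class = int(round(tr * y.size / k))
        if per_class < 2:
            raise ValueError(
                f"tr={tr} gives {per_class} training samples per class; need >= 2"
            )
        if per_class > counts.min() - 1:
            raise ValueError(
                f"tr={tr} needs {per_class} training samples per class but the "
                f"smallest class has only {counts.min()} rows (one must remain "
                "for testing)"
            )
        return per_class

    def fit(self, X, y=None) -> "VarianceMaxSplitter":
        """Run the GA on a feature table (or matrix + labels)."""
        table = X if isinstance(X, FeatureTable) else FeatureTable(
            X=sp.csr_matrix(X), y=np.asarray(y)
        )
        cfg, seed = self._resolved()
        rng = np.random.default_rng(seed)
        y_all = table.y
        per_class = self._per_class_train_count(y_all, cfg.tr)
        classes = np.unique(y_all)
        class_rows = [np.flatnonzero(y_all == c) for c in classes]
        all_rows = np.arange(table.n)

        Xm = table.X
        X2 = Xm.multiply(Xm).tocsr() if sp.issparse(Xm) else Xm * Xm

        def sample_partition() -> np.ndarray:
            parts = [rng.choice(rows, size=per_class, replace=False) for rows in class_rows]
            return np.sort(np.concatenate(parts))

        def fitness_of(train_idx: np.ndarray) -> float:
            vals = []
            for c in classes:
                mask = y_all[train_idx] == c
                a_idx, b_idx = train_idx[mask], train_idx[~mask]
                s1a, s2a = _moments(Xm, X2, a_idx)
                s1b, s2b = _moments(Xm, X2, b_idx)
                vals.append(
                    _directed_from_moments(s1a, s2a, a_idx.size, s1b, s2b, b_idx.size)
                )
            return float(np.mean(vals))

        population: list[np.ndarray | None] = [None] * cfg.ns
        fitnesses = np.zeros(cfg.ns)
        modify = np.ones(cfg.ns, dtype=bool)
        cvv = 0.0  # running best fitness (variance is non-negative)
        best_idx: np.ndarray | None = None
        best_fit = -np.inf
        trace: list[float] = []

        for _ in range(cfg.ni):
            for s in range(cfg.ns):
                if not modify[s] and population[s] is not None:
                    continue
                cand_best: tuple[float, np.ndarray] | None = None
                for _attempt in range(cfg.max_regen):
                    idx = sample_partition()
                    f = fitness_of(idx)
                    if cand_best is None or f > cand_best[0]:
                        cand_best = (f, idx)
                    if f > cvv:
                        cvv = f
                        break
                fitnesses[s], population[s] = cand_best
            m_th = mutation_threshold(fitnesses, cfg.mu)
            modify = ~(fitnesses > m_th)
            it_best = int(np.argmax(fitnesses))
            if fitnesses[it_best] > best_fit:
                best_fit = float(fitnesses[it_best])
                best_idx = population[it_best].copy()
            trace.append(best_fit)

        self.train_indices_ = best_idx
        self.test_indices_ = np.setdiff1d(all_rows, best_idx)
        self.best_fitness_ = best_fit
        self.trace_ = trace
        self.config_ = cfg
        self.seed_ = seed
        return self

    def split(self, X, y=None):
        """scikit-learn CV-splitter style accessor: yields one (train, test)."""
        if not hasattr(self, "train_indices_"):
            self.fit(X, y)
        yield self.train_indices_, self.test_indices_


def run_split_ga(table: FeatureTable, cfg: GAConfig) -> SplitSolution:
    """Run the stage-1 GA and return the best partition found."""
    splitter = VarianceMaxSplitter(config=cfg).fit(table)
    return SplitSolution(
        train_indices=splitter.train_indices_,
        test_indices=splitter.test_indices_,
        fitness=splitter.best_fitness_,
        trace=splitter.trace_,
    )
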