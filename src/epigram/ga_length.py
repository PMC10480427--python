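"""Stage-2 genetic algorithm: sequence-length selection scored by a linear SVC.

Candidate solutions are truncation lengths drawn between the shortest and
longest sequence across the train and test partitions. Scoring a length means
truncating every sequence to that prefix, re-extracting the full n-gram
feature set, fitting a linear-kernel support vector classifier on the
training partition and measuring test accuracy. The same mark/regenerate GA
loop as stage 1 then keeps high-accuracy lengths and resamples the rest.

Note that scoring on the stage-1 test partition (the published procedure)
selects the length on the same data later used for evaluation, which is
optimistic; ``inner_split`` carves a validation set out of the training
partition instead for an unbiased selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .config import GAConfig
from .features import NGramFeaturizer
from .types import FeatureTable, LabeledSequence


def truncate_sequences(
    seqs: Sequence[LabeledSequence], sl_sel: int
) -> list[LabeledSequence]:
    """Keep the first ``sl_sel`` residues of each sequence (shorter ones pass
    through whole); labels and order are preserved."""
    if sl_sel < 1:
        raise ValueError(f"sl_sel must be >= 1, got {sl_sel}")
    return [
        LabeledSequence(id=s.id, residues=s.residues[:sl_sel], label=s.label)
        for s in seqs
    ]


def fitness_threshold(accuracies, mu: float) -> float:
    """Survival threshold: mean accuracy of the population times ``mu``."""
    accuracies = np.asarray(list(accuracies), dtype=np.float64)
    if accuracies.size == 0:
        raise ValueError("accuracy collection is empty")
    return float(accuracies.mean() * mu)


def _make_lsvc(seed: int) -> LinearSVC:
    # Linear kernel, default C=1.0; the procedure specifies nothing further.
    return LinearSVC(C=1.0, dual="auto", random_state=seed, max_iter=5000)


def evaluate_length_solution(
    sl_sel: int,
    train: Sequence[LabeledSequence],
    test: Sequence[LabeledSequence],
    seed: int = 0,
    residue_policy: str = "skip",
) -> float:
    """Test accuracy of a linear SVC trained on length-``sl_sel`` prefixes."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    feat = NGramFeaturizer(residue_policy=residue_policy)
    tr = feat.build_table(truncate_sequences(train, sl_sel))
    te = feat.build_table(truncate_sequences(test, sl_sel))
    if np.unique(tr.y).size < 2:
        raise ValueError("training set contains a single class")
    clf = _make_lsvc(seed).fit(tr.X, tr.y)
    return float((clf.predict(te.X) == te.y).mean())


@dataclass
class LengthSelectionResult:
    """Outcome of the stage-2 GA."""

    best_length: int
    best_fitness: float
    sl_min: int
    sl_max: int
    train_table: FeatureTable
    test_table: FeatureTable
    trace: list[float] = field(default_factory=list)
    svc_seed: int = 0  # seed of the scoring classifier, for exact refits

    def report(self) -> dict:
        return {
            "sl_min": self.sl_min,
            "sl_max": self.sl_max,
            "best_length": self.best_length,
            "best_fitness": self.best_fitness,
            "fitness_trace": self.trace,
        }


class PrefixLengthSelector:
    """GA search for the prefix length maximizing linear-SVC accuracy.

    After :meth:`fit`, exposes ``best_length_``, ``best_score_``,
    ``sl_min_``/``sl_max_`` and the per-iteration best-so-far ``trace_``;
    :meth:`transform` truncates sequences to the selected length.

    Parameters
    ----------
    config : GAConfig, optional
    seed : int, optional
        Overrides ``config.seed``.
    inner_split : float, optional
        When set (e.g. 0.25), candidate lengths are scored on a validation
        subset carved from the training partition rather than on the test
        partition, avoiding selection-on-test optimism.
    residue_policy : str
        Passed to the featurizer.
    """

    def __init__(
        self,
        config: GAConfig | None = None,
        seed: int | None = None,
        inner_split: float | None = None,
        residue_policy: str = "skip",
    ):
        self.config = config
        self.seed = seed
        self.inner_split = inner_split
        self.residue_policy = residue_policy

    def get_params(self, deep: bool = True) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "inner_split": self.inner_split,
            "residue_policy": self.residue_policy,
        }

    def set_params(self, **params) -> "PrefixLengthSelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        train: Sequence[LabeledSequence],
        test: Sequence[LabeledSequence],
    ) -> "PrefixLengthSelector":
        cfg = self.config if self.config is not None else GAConfig()
        seed = self.seed if self.seed is not None else cfg.seed
        rng = np.random.default_rng(seed)
        lengths = [len(s) for s in train] + [len(s) for s in test]
        sl_min, sl_max = min(lengths), max(lengths)
        if sl_min < 1:
            raise ValueError("sequences must have length >= 1")

        fit_train: Sequence[LabeledSequence] = train
        score_set: Sequence[LabeledSequence] = test
        if self.inner_split is not None:
            if not (0.0 < self.inner_split < 1.0):
                raise ValueError("inner_split must lie in (0, 1)")
            n_val = max(1, int(round(self.inner_split * len(train))))
            perm = rng.permutation(len(train))
            val_idx = set(perm[:n_val].tolist())
            fit_train = [s for i, s in enumerate(train) if i not in val_idx]
            score_set = [s for i, s in enumerate(train) if i in val_idx]

        svc_seed = int(rng.integers(0, 2**31 - 1))
        cache: dict[int, float] = {}

        def score(sl: int) -> float:
            if sl not in cache:
                cache[sl] = evaluate_length_solution(
                    sl, fit_train, score_set, seed=svc_seed,
                    residue_policy=self.residue_policy,
                )
            return cache[sl]

        solutions = np.zeros(cfg.ns, dtype=np.int64)
        fitnesses = np.zeros(cfg.ns)
        modify = np.ones(cfg.ns, dtype=bool)
        filled = np.zeros(cfg.ns, dtype=bool)
        ca = 0.0  # running best accuracy
        best_len, best_fit = sl_max, -np.inf
        trace: list[float] = []

        for _ in range(cfg.ni):
            for s in range(cfg.ns):
                if not modify[s] and filled[s]:
                    continue
                cand_best: tuple[float, int] | None = None
                for _attempt in range(cfg.max_regen):
                    sl = int(rng.integers(sl_min, sl_max + 1))
                    acc = score(sl)
                    if cand_best is None or acc > cand_best[0]:
                        cand_best = (acc, sl)
                    if acc > ca:
                        ca = acc
                        break
                fitnesses[s], solutions[s] = cand_best
                filled[s] = True
            f_th = fitness_threshold(fitnesses, cfg.mu)
            modify = ~(fitnesses > f_th)
            it_best = int(np.argmax(fitnesses))
            if fitnesses[it_best] > best_fit:
                best_fit = float(fitnesses[it_best])
                best_len = int(solutions[it_best])
            trace.append(best_fit)

        self.best_length_ = best_len
        self.best_score_ = best_fit
        self.sl_min_ = sl_min
        self.sl_max_ = sl_max
        self.trace_ = trace
        self.config_ = cfg
        self.seed_ = seed
        self._svc_seed_ = svc_seed
        return self

    def transform(self, seqs: Sequence[LabeledSequence]) -> list[LabeledSequence]:
        return truncate_sequences(seqs, self.best_length_)


def run_length_ga(
    train: Sequence[LabeledSequence],
    test: Sequence[LabeledSequence],
    cfg: GAConfig,
    inner_split: float | None = None,
    residue_policy: str = "skip",
) -> LengthSelectionResult:
    """Run the stage-2 GA and return the selected length with its tables."""
    sel = PrefixLengthSelector(
        config=cfg, inner_split=inner_split, residue_policy=residue_policy
    ).fit(train, test)
    feat = NGramFeaturizer(residue_policy=residue_policy)
    return LengthSelectionResult(
        best_length=sel.best_length_,
        best_fitness=sel.best_score_,
        sl_min=sel.sl_min_,
        sl_max=sel.sl_max_,
        train_table=feat.build_table(sel.transform(train)),
        test_table=feat.build_table(sel.transform(test)),
        trace=sel.trace_,
        svc_seed=sel._svc_seed_,
    )
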