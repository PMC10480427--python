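"""Instance-based four-classifier ensemble with correlation routing.

Four base classifiers — 1-nearest-neighbor, a 100-tree random forest,
logistic regression (L-BFGS solver) and a support vector machine with
stopping tolerance 1e-4 — are fitted independently on the training
partition. On a calibration set, the indices each classifier gets right are
recorded; their deduplicated union gives the oracle-style "union accuracy".
A new peptide is then *routed*: its feature vector is correlated against
every stored correctly-classified instance, and the classifier holding the
best-matching instance makes the final call. When the best correlation
exceeds 0.999 the new instance (with its predicted label) is absorbed into
the training pool (self-augmentation).

The printed pairwise correlation, sum(diff)/sqrt(sum(diff^2)), is not
bounded to [-1, 1]; Pearson correlation is therefore the default routing
statistic, with the printed form selectable via ``correlation_mode``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

#: Fixed routing priority; ties in the maximum correlation resolve to the
#: earliest classifier in this order.
CLASSIFIER_ORDER = ("knn", "rf", "lr", "svm")


def correlation(test_vec, new_vec, mode: str = "pearson") -> float:
    """Pairwise similarity between a stored instance and a new feature vector.

    ``mode='as_printed'`` evaluates sum(diff) / sqrt(sum(diff^2)) with the
    0/0 case (identical vectors) defined as 1.0; ``mode='pearson'`` is the
    standard Pearson coefficient, with a constant vector giving 0.0 unless
    the vectors are identical (1.0).
    """
    u = np.asarray(test_vec, dtype=np.float64).ravel()
    v = np.asarray(new_vec, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    if u.shape[0] < 1:
        raise ValueError("vectors must have at least one element")
    if mode == "as_printed":
        d = u - v
        den = float(np.sqrt((d * d).sum()))
        if den == 0.0:
            return 1.0
        return float(d.sum() / den)
    if mode == "pearson":
        if np.array_equal(u, v):
            return 1.0
        du, dv = u - u.mean(), v - v.mean()
        nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
        if nu == 0.0 or nv == 0.0:
            return 0.0
        return float(du @ dv / (nu * nv))
    raise ValueError(f"unknown correlation mode {mode!r}")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)


def _corr_matrix(new: np.ndarray, stored: np.ndarray, mode: str) -> np.ndarray:
    """All pairwise correlations, shape (n_new, n_stored)."""
    if mode == "pearson":
        zn = new - new.mean(axis=1, keepdims=True)
        zs = stored - stored.mean(axis=1, keepdims=True)
        nn = np.linalg.norm(zn, axis=1)
        ns = np.linalg.norm(zs, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = (zn @ zs.T) / np.outer(nn, ns)
        P = np.nan_to_num(P, nan=0.0, posinf=0.0, neginf=0.0)
        # constant vectors: 0 unless exactly identical, then 1
        bad_n, bad_s = np.flatnonzero(nn == 0), np.flatnonzero(ns == 0)
        for i in bad_n:
            P[i, :] = np.all(stored == new[i], axis=1).astype(float)
        for j in bad_s:
            P[:, j] = np.maximum(
                P[:, j], np.all(new == stored[j], axis=1).astype(float)
            )
        return P
    if mode == "as_printed":
        sn, ss = new.sum(axis=1), stored.sum(axis=1)
        n2 = (new * new).sum(axis=1)
        s2 = (stored * stored).sum(axis=1)
        den2 = n2[:, None] - 2.0 * (new @ stored.T) + s2[None, :]
        den = np.sqrt(np.clip(den2, 0.0, None))
        num = ss[None, :] - sn[:, None]  # sum over i of (F_test_i - F_new_i)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = num / den
        P[den == 0] = 1.0  # identical vectors
        return np.nan_to_num(P, nan=1.0)
    raise ValueError(f"unknown correlation mode {mode!r}")


class CorrelationRoutedEnsemble(BaseEstimator, ClassifierMixin):
    """Four-classifier instance ensemble with correlation-based routing.

    Usage: :meth:`fit` on the training partition, :meth:`calibrate` on a
    labeled set to record each classifier's correctly-classified instances,
    then :meth:`predict` (routing) or :meth:`union_accuracy` (the printed
    oracle-style metric) on new data.

    Parameters
    ----------
    seed : int
        Seeds the random forest and the SVM.
    correlation_mode : {"pearson", "as_printed"}
        Routing statistic; see :func:`correlation`.
    augment_threshold : float
        Self-augmentation gate: a routed instance whose maximum correlation
        strictly exceeds this joins the training pool. Default 0.999.
    knn_k, rf_estimators, lr_solver, svm_tol :
        The published base-classifier hyperparameters (1, 100, "lbfgs",
        1e-4).
    """

    def __init__(
        self,
        seed: int = 0,
        correlation_mode: str = "pearson",
        augment_threshold: float = 0.999,
        knn_k: int = 1,
        rf_estimators: int = 100,
        lr_solver: str = "lbfgs",
        svm_tol: float = 1e-4,
    ):
        self.seed = seed
        self.correlation_mode = correlation_mode
        self.augment_threshold = augment_threshold
        self.knn_k = knn_k
        self.rf_estimators = rf_estimators
        self.lr_solver = lr_solver
        self.svm_tol = svm_tol

    def _make_classifiers(self) -> dict:
        return {
            "knn": KNeighborsClassifier(n_neighbors=self.knn_k),
            "rf": RandomForestClassifier(
                n_estimators=self.rf_estimators,
                random_state=self.seed,
                n_jobs=1,
            ),
            "lr": LogisticRegression(solver=self.lr_solver, max_iter=1000),
            "svm": SVC(tol=self.svm_tol, random_state=self.seed),
        }

    def fit(self, X, y) -> "CorrelationRoutedEnsemble":
        y = np.asarray(y, dtype=np.int64)
        if np.unique(y).size < 2:
            raise ValueError("training set contains a single class")
        X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        self.classes_ = np.unique(y)
        self.X_pool_ = X
        self.y_pool_ = y
        self.classifiers_ = self._make_classifiers()
        for clf in self.classifiers_.values():
            clf.fit(X, y)
        self.stale_ = False
        self.n_features_in_ = X.shape[1]
        return self

    def refit(self) -> "CorrelationRoutedEnsemble":
        """Refit the base classifiers on the (possibly augmented) pool."""
        for clf in self.classifiers_.values():
            clf.fit(self.X_pool_, self.y_pool_)
        self.stale_ = False
        return self

    # -- calibration: record each classifier's correct instances ------------

    def calibrate(self, X, y) -> "CorrelationRoutedEnsemble":
        """Record correctly-classified instance sets on a labeled set.

        Populates ``correct_sets_`` (per classifier), ``union_indices_``
        (their deduplicated union), ``union_accuracy_`` and the stored
        instance matrices used for routing.
        """
        if not hasattr(self, "classifiers_"):
            raise ValueError("fit must be called before calibrate")
        y = np.asarray(y, dtype=np.int64)
        if y.size == 0:
            raise ValueError("calibration set is empty")
        Xd = _dense(X)
        self.correct_sets_ = {}
        self._stored_ = {}
        self._stored_labels_ = {}
        self.individual_accuracy_ = {}
        for name, clf in self.classifiers_.items():
            pred = clf.predict(X)
            correct = np.flatnonzero(pred == y)
            self.correct_sets_[name] = correct
            self._stored_[name] = Xd[correct]
            self._stored_labels_[name] = y[correct]
            self.individual_accuracy_[name] = float(correct.size / y.size)
        union = np.unique(np.concatenate(list(self.correct_sets_.values())))
        self.union_indices_ = union
        self.union_accuracy_ = float(union.size / y.size)
        return self

    # -- routing -------------------------------------------------------------

    def route(self, X) -> tuple[np.ndarray, list[str], np.ndarray]:
        """Route each row to its best-matching classifier.

        Returns ``(predictions, chosen_classifier_names, max_correlations)``.
        A classifier with no stored correct instances is never chosen; exact
        correlation ties resolve in the fixed order knn > rf > lr > svm.
        """
        if not hasattr(self, "correct_sets_"):
            raise ValueError("calibrate must be called before routing")
        if all(v.size == 0 for v in self.correct_sets_.values()):
            raise ValueError("no classifier has any correctly classified instance")
        Xd = _dense(X)
        n = Xd.shape[0]
        corr = np.full((n, len(CLASSIFIER_ORDER)), -np.inf)
        for j, name in enumerate(CLASSIFIER_ORDER):
            stored = self._stored_[name]
            if stored.shape[0] == 0:
                continue
            corr[:, j] = _corr_matrix(Xd, stored, self.correlation_mode).max(axis=1)
        chosen_idx = np.argmax(corr, axis=1)  # first max wins the tie
        max_corr = corr[np.arange(n), chosen_idx]
        Xs = sp.csr_matrix(Xd)
        preds = np.empty(n, dtype=np.int64)
        chosen = [CLASSIFIER_ORDER[j] for j in chosen_idx]
        for name in set(chosen):
            rows = np.flatnonzero(chosen_idx == CLASSIFIER_ORDER.index(name))
            preds[rows] = self.classifiers_[name].predict(Xs[rows])
        return preds, chosen, max_corr

    def predict(self, X) -> np.ndarray:
        return self.route(X)[0]

    def decision_scores(self, X) -> np.ndarray:
        """Per-row score from each row's routed classifier.

        Probability of the positive class where the classifier exposes one
        (random forest, logistic regression, 1-NN), otherwise the decision
        function (SVM); used for ROC/AUC construction.
        """
        _, chosen, _ = self.route(X)
        Xs = sp.csr_matrix(_dense(X))
        chosen_idx = np.array([CLASSIFIER_ORDER.index(c) for c in chosen])
        scores = np.zeros(len(chosen))
        for name in set(chosen):
            rows = np.flatnonzero(chosen_idx == CLASSIFIER_ORDER.index(name))
            clf = self.classifiers_[name]
            if hasattr(clf, "predict_proba"):
                scores[rows] = clf.predict_proba(Xs[rows])[:, -1]
            else:
                scores[rows] = clf.decision_function(Xs[rows])
        return scores

    # -- self-augmentation ---------------------------------------------------

    def maybe_augment(self, x_vec, predicted_label: int, max_corr: float) -> bool:
        """Absorb a routed instance into the training pool when its maximum
        correlation strictly exceeds the augmentation threshold.

        Uses the *predicted* label (self-training); marks the model stale —
        call :meth:`refit` before further accuracy claims. Returns whether
        the pool grew.
        """
        if not (max_corr > self.augment_threshold):
            return False
        row = sp.csr_matrix(np.asarray(x_vec, dtype=np.float64).reshape(1, -1))
        self.X_pool_ = sp.vstack([self.X_pool_, row]).tocsr()
        self.y_pool_ = np.append(self.y_pool_, int(predicted_label))
        self.stale_ = True
        return True

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Serialize the fitted ensemble as a directory bundle."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifiers_, d / "classifiers.joblib")
        joblib.dump(
            {
                "X_pool": self.X_pool_,
                "y_pool": self.y_pool_,
                "stored": getattr(self, "_stored_", None),
                "stored_labels": getattr(self, "_stored_labels_", None),
            },
            d / "instances.joblib",
        )
        manifest = {
            "params": self.get_params(),
            "correct_sets": {
                k: v.tolist() for k, v in getattr(self, "correct_sets_", {}).items()
            },
            "union_indices": getattr(self, "union_indices_", np.array([])).tolist(),
            "union_accuracy": getattr(self, "union_accuracy_", None),
            "stale": getattr(self, "stale_", False),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "CorrelationRoutedEnsemble":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        model = cls(**manifest["params"])
        model.classifiers_ = joblib.load(d / "classifiers.joblib")
        inst = joblib.load(d / "instances.joblib")
        model.X_pool_, model.y_pool_ = inst["X_pool"], inst["y_pool"]
        model.stale_ = manifest["stale"]
        model.classes_ = np.unique(model.y_pool_)
        if manifest["correct_sets"]:
            model.correct_sets_ = {
                k: np.asarray(v, dtype=np.intp)
                for k, v in manifest["correct_sets"].items()
            }
            model.union_indices_ = np.asarray(manifest["union_indices"], dtype=np.intp)
            model.union_accuracy_ = manifest["union_accuracy"]
            model._stored_ = inst["stored"]
            model._stored_labels_ = inst["stored_labels"]
        return model


def correct_instance_union(
    model: CorrelationRoutedEnsemble, X, y
) -> tuple[np.ndarray, float]:
    """Deduplicated union of each classifier's correct instances and the
    resulting union accuracy |union| / |test| on the given labeled set."""
    model.calibrate(X, y)
    return model.union_indices_, model.union_accuracy_


def fit_base_classifiers(X, y, seed: int = 0) -> dict:
    """Fit the four base classifiers with the published hyperparameters."""
    model = CorrelationRoutedEnsemble(seed=seed).fit(X, y)
    return model.classifiers_
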