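"""Core domain containers: labeled peptide sequences and n-gram feature tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: The 20 standard amino acids, in fixed alphabetical order. Column layouts of
#: every feature matrix in this package are derived from this ordering.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

N_UNI = 20
N_BI = 400
N_TRI = 8000
#: unigram + bigram + trigram counts, plus the binary epitope label.
N_FEATURES = N_UNI + N_BI + N_TRI  # 8420
N_TOTAL = N_FEATURES + 1  # 8421


@dataclass(frozen=True)
class LabeledSequence:
    """One peptide with a binary linear B-cell epitope label.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header token or a synthetic name).
    residues : str
        Upper-case residue string. Standard residues come from
        :data:`ALPHABET`; nonstandard symbols (X, B, Z, U, O, J, ``*``) may be
        present and are handled by the featurizer's residue policy.
    label : int
        1 if the peptide carries a linear B-cell epitope, 0 otherwise.
        ``-1`` marks an unlabeled sequence at prediction time.
    """

    id: str
    residues: str
    label: int = -1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        if self.residues != self.residues.upper():
            object.__setattr__(self, "residues", self.residues.upper())
        if self.label not in (-1, 0, 1):
            raise ValueError(
                f"sequence {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def kmer_column_names() -> list[str]:
    """Column names of the 8420 feature columns, in matrix order.

    Unigrams first (alphabetical), then the 400 dipeptides row-major
    (first residue slowest), then the 8000 tripeptides row-major.
    """
    names = list(ALPHABET)
    names += [a + b for a in ALPHABET for b in ALPHABET]
    names += [a + b + c for a in ALPHABET for b in ALPHABET for c in ALPHABET]
    return names


@dataclass
class FeatureTable:
    """An n-gram count matrix with aligned identifiers and labels.

    ``X`` is a sparse CSR matrix with 8420 columns (unigram, dipeptide,
    tripeptide counts in the documented column order); ``y`` holds the binary
    labels; ``ids`` the sequence identifiers. ``labeled_width`` is always 8421
    (the count columns plus the label).
    """

    X: sp.csr_matrix
    y: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must have {N_FEATURES} columns")
        if not self.ids:
            self.ids = [f"seq_{i}" for i in range(self.X.shape[0])]
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids and X row counts differ")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def labeled_width(self) -> int:
        return self.X.shape[1] + 1

    def subset(self, indices: np.ndarray) -> "FeatureTable":
        indices = np.asarray(indices, dtype=np.intp)
        return FeatureTable(
            X=self.X[indices],
            y=self.y[indices],
            ids=[self.ids[i] for i in indices],
        )

    def labeled_matrix(self) -> np.ndarray:
        """Dense ``(n, 8421)`` array: counts followed by the label column."""
        return np.hstack(
            [self.X.toarray(), self.y.reshape(-1, 1).astype(self.X.dtype)]
        )
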