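"""Amino-acid n-gram composition features.

Each peptide is converted to counts of its unigrams (20 columns), dipeptides
(400 columns, adjacent residue pairs) and tripeptides (8000 columns, adjacent
triples) over the standard 20-letter alphabet. Together with the binary
epitope label this yields the 8421-value labeled feature vector the rest of
the pipeline consumes.

Column order is fixed: alphabetical residues, k-mers flattened row-major with
the first residue varying slowest. :func:`epigram.types.kmer_column_names`
gives the exact column ↔ k-mer mapping.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    ALPHABET,
    ALPHABET_INDEX,
    N_BI,
    N_FEATURES,
    N_TRI,
    N_UNI,
    FeatureTable,
    LabeledSequence,
)

logger = logging.getLogger(__name__)

#: Policies for residues outside the 20-letter alphabet (X, B, Z, U, O, J, *):
#: ``skip`` drops any n-gram window containing the symbol (counts stay
#: consistent over the scanned windows), ``error`` raises, ``drop-sequence``
#: removes the whole record from the table.
RESIDUE_POLICIES = ("skip", "error", "drop-sequence")


def _encode(residues: str, policy: str, seq_id: str = "?") -> np.ndarray:
    """Map residues to integer codes 0..19; nonstandard symbols become -1."""
    codes = np.fromiter(
        (ALPHABET_INDEX.get(ch, -1) for ch in residues),
        dtype=np.int64,
        count=len(residues),
    )
    if (codes < 0).any():
        if policy == "error":
            bad = sorted({ch for ch in residues if ch not in ALPHABET_INDEX})
            raise ValueError(
                f"sequence {seq_id!r} contains nonstandard residues {bad}"
            )
        logger.warning(
            "sequence %r: %d nonstandard residue(s) skipped",
            seq_id,
            int((codes < 0).sum()),
        )
    return codes


def _as_residues(seq: LabeledSequence | str) -> tuple[str, str]:
    if isinstance(seq, LabeledSequence):
        return seq.residues, seq.id
    return str(seq).upper(), "?"


def extract_unigram(seq: LabeledSequence | str, policy: str = "skip") -> np.ndarray:
    """Count each of the 20 amino acids in the sequence (20-vector)."""
    residues, seq_id = _as_residues(seq)
    codes = _encode(residues, policy, seq_id)
    return np.bincount(codes[codes >= 0], minlength=N_UNI).astype(np.int64)


def extract_bigram(seq: LabeledSequence | str, policy: str = "skip") -> np.ndarray:
    """Count adjacent residue pairs; flattened row-major 400-vector."""
    residues, seq_id = _as_residues(seq)
    codes = _encode(residues, policy, seq_id)
    if len(codes) < 2:
        return np.zeros(N_BI, dtype=np.int64)
    a, b = codes[:-1], codes[1:]
    ok = (a >= 0) & (b >= 0)
    return np.bincount(a[ok] * 20 + b[ok], minlength=N_BI).astype(np.int64)


def extract_trigram(seq: LabeledSequence | str, policy: str = "skip") -> np.ndarray:
    """Count adjacent residue triples; flattened row-major 8000-vector."""
    residues, seq_id = _as_residues(seq)
    codes = _encode(residues, policy, seq_id)
    if len(codes) < 3:
        return np.zeros(N_TRI, dtype=np.int64)
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    ok = (a >= 0) & (b >= 0) & (c >= 0)
    return np.bincount(a[ok] * 400 + b[ok] * 20 + c[ok], minlength=N_TRI).astype(
        np.int64
    )


def featurize_sequence(seq: LabeledSequence | str, policy: str = "skip") -> np.ndarray:
    """Full 8420-value count vector (unigram ++ dipeptide ++ tripeptide)."""
    return np.concatenate(
        [
            extract_unigram(seq, policy),
            extract_bigram(seq, policy),
            extract_trigram(seq, policy),
        ]
    )


class NGramFeaturizer(BaseEstimator, TransformerMixin):
    """Transform peptides into sparse 8420-column n-gram count matrices.

    Stateless apart from its parameters (``fit`` only validates them), so it
    slots into scikit-learn pipelines. ``transform`` accepts residue strings
    or :class:`~epigram.types.LabeledSequence` objects.

    Parameters
    ----------
    residue_policy : {"skip", "error", "drop-sequence"}
        Handling of nonstandard residues; with ``drop-sequence``,
        :meth:`transform` raises (rows must stay aligned) — use
        :meth:`build_table`, which may drop records.
    """

    def __init__(self, residue_policy: str = "skip"):
        self.residue_policy = residue_policy

    def _validate(self) -> None:
        if self.residue_policy not in RESIDUE_POLICIES:
            raise ValueError(
                f"residue_policy must be one of {RESIDUE_POLICIES}, "
                f"got {self.residue_policy!r}"
            )

    def fit(self, X: Iterable[LabeledSequence | str], y=None) -> "NGramFeaturizer":
        self._validate()
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[LabeledSequence | str]) -> sp.csr_matrix:
        self._validate()
        if self.residue_policy == "drop-sequence":
            raise ValueError(
                "transform cannot drop rows; use build_table with "
                "residue_policy='drop-sequence'"
            )
        return self._matrix(X)

    def _matrix(self, seqs: Sequence[LabeledSequence | str]) -> sp.csr_matrix:
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        data: list[np.ndarray] = []
        for r, seq in enumerate(seqs):
            residues, seq_id = _as_residues(seq)
            codes = _encode(residues, self.residue_policy, seq_id)
            parts = []
            ok1 = codes >= 0
            parts.append(codes[ok1])
            if len(codes) >= 2:
                a, b = codes[:-1], codes[1:]
                ok = (a >= 0) & (b >= 0)
                parts.append(N_UNI + a[ok] * 20 + b[ok])
            if len(codes) >= 3:
                a, b, c = codes[:-2], codes[1:-1], codes[2:]
                ok = (a >= 0) & (b >= 0) & (c >= 0)
                parts.append(N_UNI + N_BI + a[ok] * 400 + b[ok] * 20 + c[ok])
            flat = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
            uniq, cnt = np.unique(flat, return_counts=True)
            rows.append(np.full(uniq.shape, r, dtype=np.int64))
            cols.append(uniq)
            data.append(cnt)
        n = len(seqs)
        mat = sp.csr_matrix(
            (
                np.concatenate(data) if data else np.empty(0),
                (np.concatenate(rows) if rows else np.empty(0),
                 np.concatenate(cols) if cols else np.empty(0)),
            ),
            shape=(n, N_FEATURES),
            dtype=np.float64,
        )
        return mat

    def build_table(self, seqs: Sequence[LabeledSequence]) -> FeatureTable:
        """Featurize labeled sequences into a :class:`FeatureTable`.

        Honors ``residue_policy='drop-sequence'`` by removing offending
        records (with a logged warning) before building the matrix.
        """
        self._validate()
        if len(seqs) == 0:
            raise ValueError("cannot build a feature table from zero sequences")
        kept = list(seqs)
        if self.residue_policy == "drop-sequence":
            bad = [
                s for s in kept
                if any(ch not in ALPHABET_INDEX for ch in s.residues)
            ]
            for s in bad:
                logger.warning("dropping sequence %r (nonstandard residues)", s.id)
            kept = [s for s in kept if s not in bad]
            if not kept:
                raise ValueError("all sequences dropped by residue policy")
        policy = "skip" if self.residue_policy == "drop-sequence" else self.residue_policy
        feat = NGramFeaturizer(residue_policy=policy)
        X = feat._matrix(kept)
        y = np.array([s.label for s in kept], dtype=np.int64)
        return FeatureTable(X=X, y=y, ids=[s.id for s in kept])


def build_feature_table(
    seqs: Sequence[LabeledSequence], residue_policy: str = "skip"
) -> FeatureTable:
    """Build the full labeled feature table (rows of width 8421 with label)."""
    return NGramFeaturizer(residue_policy=residue_policy).build_table(seqs)
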