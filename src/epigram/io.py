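"""Readers and writers for labeled peptide data and feature tables.

FASTA headers carry the binary label either as ``>id label=1`` (default) or
as a ``>id|1`` suffix dialect. TSV files are two columns,
``sequence<TAB>label``, with an optional header row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO

from .types import FeatureTable, LabeledSequence, kmer_column_names


def _parse_label(token: str, where: str) -> int:
    token = token.strip()
    if token not in ("0", "1"):
        raise ValueError(f"{where}: label must be 0 or 1, got {token!r}")
    return int(token)


def _label_from_fasta_header(record_id: str, description: str, index: int) -> tuple[str, int]:
    """Extract (id, label) from a FASTA header under either dialect."""
    where = f"FASTA record {index} ({record_id!r})"
    for token in description.split():
        if token.startswith("label="):
            return record_id, _parse_label(token[len("label="):], where)
    if "|" in record_id:
        head, _, tail = record_id.rpartition("|")
        if tail.strip() in ("0", "1"):
            return head, int(tail)
        raise ValueError(f"{where}: label token after '|' must be 0 or 1, got {tail!r}")
    raise ValueError(f"{where}: no label token (expected 'label=0|1' or 'id|0|1')")


def read_fasta(path: str | Path) -> list[LabeledSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or unparseable FASTA file")
    out = []
    for i, rec in enumerate(records):
        seq_id, label = _label_from_fasta_header(rec.id, rec.description, i)
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"FASTA record {i} ({rec.id!r}): empty sequence")
        out.append(LabeledSequence(id=seq_id, residues=residues, label=label))
    return out


def read_tsv(path: str | Path) -> list[LabeledSequence]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i + 1}: expected 2 tab-separated columns")
            seq, label = parts
            if i == 0 and label.strip().lower() in ("label", "class", "y"):
                continue  # header row
            out.append(
                LabeledSequence(
                    id=f"row_{len(out)}",
                    residues=seq.strip().upper(),
                    label=_parse_label(label, f"{path}: line {i + 1}"),
                )
            )
    if not out:
        raise ValueError(f"{path}: no sequences found")
    return out


def read_labeled_sequences(path: str | Path, format: str = "auto") -> list[LabeledSequence]:
    """Read labeled peptides from FASTA or two-column TSV.

    ``format='auto'`` decides by file extension (.fa/.fasta/.faa → FASTA,
    anything else → TSV).
    """
    if format == "auto":
        format = "fasta" if Path(path).suffix.lower() in (".fa", ".fasta", ".faa") else "tsv"
    if format == "fasta":
        return read_fasta(path)
    if format == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'tsv')")


def write_fasta(seqs: Sequence[LabeledSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id} label={s.label}\n{s.residues}\n")


def write_tsv(seqs: Sequence[LabeledSequence], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for s in seqs:
            w.writerow([s.residues, s.label])


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    """Write the labeled feature matrix as CSV: id, 8420 k-mer columns, label."""
    df = pd.DataFrame(
        table.X.toarray().astype(np.int64), columns=kmer_column_names()
    )
    df.insert(0, "id", table.ids)
    df["label"] = table.y
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> FeatureTable:
    """Read a feature CSV written by :func:`write_feature_csv` (lossless)."""
    df = pd.read_csv(path)
    expected = ["id"] + kmer_column_names() + ["label"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: unexpected column layout for a feature CSV")
    X = sp.csr_matrix(df[kmer_column_names()].to_numpy(dtype=np.float64))
    return FeatureTable(X=X, y=df["label"].to_numpy(), ids=df["id"].astype(str).tolist())
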