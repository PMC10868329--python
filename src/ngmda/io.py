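"""Labeled-matrix TSV I/O and output artifact writers.

All matrices travel as tab-separated text with a header row of column
identifiers and a first column of row identifiers.  Association entries
are strictly 0/1; similarity entries are decimals in [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .heterograph import AssociationMatrix, SimilarityMatrix

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_association_tsv",
    "read_similarity_tsv",
    "write_dataset",
    "write_scores_tsv",
    "write_prediction_tsv",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labeled numeric matrix; duplicate or ragged rows are errors."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row label {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column label {dup!r} in {path}")
    if df.isna().any().any():
        row, col = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing/non-numeric value at row {df.index[row]!r}, "
            f"column {df.columns[col]!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from None
    return pd.DataFrame(values, index=df.index.astype(str),
                        columns=df.columns.astype(str))


def write_matrix_tsv(path: str | Path, values: np.ndarray,
                     row_ids, col_ids, fmt: str = "%.12g") -> None:
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", float_format=fmt)


def read_association_tsv(path: str | Path) -> AssociationMatrix:
    df = read_matrix_tsv(path)
    return AssociationMatrix(df.to_numpy(), list(df.index), list(df.columns))


def read_similarity_tsv(path: str | Path, node_type: str) -> SimilarityMatrix:
    df = read_matrix_tsv(path)
    if list(df.index) != list(df.columns):
        raise ValueError(f"similarity matrix in {path} must have matching row/column labels")
    return SimilarityMatrix(df.to_numpy(), node_type, ids=list(df.index))


def write_dataset(out_dir: str | Path, assoc: AssociationMatrix,
                  drug_sim: SimilarityMatrix, microbe_sim: SimilarityMatrix,
                  microbe_attributes: np.ndarray | None = None,
                  provenance: dict | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(out_dir / "associations.tsv", assoc.values,
                     assoc.drug_ids, assoc.microbe_ids)
    write_matrix_tsv(out_dir / "drug_similarity.tsv", drug_sim.values,
                     assoc.drug_ids, assoc.drug_ids)
    write_matrix_tsv(out_dir / "microbe_similarity.tsv", microbe_sim.values,
                     assoc.microbe_ids, assoc.microbe_ids)
    if microbe_attributes is not None:
        cols = [f"attr_{k}" for k in range(np.asarray(microbe_attributes).shape[1])]
        write_matrix_tsv(out_dir / "microbe_attributes.tsv", microbe_attributes,
                         assoc.microbe_ids, cols)
    if provenance is not None:
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                            sort_keys=True))


def write_scores_tsv(path: str | Path, assoc: AssociationMatrix,
                     scores: np.ndarray, fold) -> None:
    """Long-format test scores: drug_id, microbe_id, score, label, fold, split."""
    rows = []
    for (d, m), label in ((tuple(p), 1) for p in fold.test_pos):
        rows.append((assoc.drug_ids[d], assoc.microbe_ids[m],
                     scores[d, m], label, fold.fold_id, "test"))
    for d, m in fold.test_neg:
        rows.append((assoc.drug_ids[d], assoc.microbe_ids[m],
                     scores[d, m], 0, fold.fold_id, "test"))
    df = pd.DataFrame(rows, columns=["drug_id", "microbe_id", "score",
                                     "label", "fold", "split"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_prediction_tsv(path: str | Path, assoc: AssociationMatrix,
                         scores: np.ndarray) -> None:
    """Per-drug ranked candidate list: drug_id, microbe_id, probability, rank."""
    rows = []
    for d, drug_id in enumerate(assoc.drug_ids):
        order = np.lexsort((np.arange(assoc.n_microbes), -scores[d]))
        for rank, m in enumerate(order, start=1):
            rows.append((drug_id, assoc.microbe_ids[m], scores[d, m], rank))
    df = pd.DataFrame(rows, columns=["drug_id", "microbe_id",
                                     "association_probability", "rank"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
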