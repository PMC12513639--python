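"""Readers and writers for the formats sites exchange on disk.

Matrices are features x cells. MTX directories follow the usual
single-cell layout: matrix.mtx + features.tsv + barcodes.tsv.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def write_dense_csv(path, X: np.ndarray, feature_names, cell_ids) -> None:
    pd.DataFrame(X, index=list(feature_names), columns=list(cell_ids)).to_csv(path)


def read_dense_csv(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str))


def write_mtx(directory, X: np.ndarray, feature_names, cell_ids) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", scipy.sparse.csc_matrix(X))
    pd.Series(list(feature_names)).to_csv(directory / "features.tsv", sep="\t",
                                          index=False, header=False)
    pd.Series(list(cell_ids)).to_csv(directory / "barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_mtx(directory) -> tuple[np.ndarray, list[str], list[str]]:
    directory = Path(directory)
    X = np.asarray(scipy.io.mmread(directory / "matrix.mtx").todense(), dtype=float)
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    return X, features, barcodes


def write_labels_tsv(path, cell_ids, labels) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_embedding_csv(path, Z: np.ndarray, cell_ids=None) -> None:
    """d x N embedding written as one row per cell, keyed by cell id."""
    ids = list(cell_ids) if cell_ids is not None else [f"cell{i}" for i in range(Z.shape[1])]
    cols = [f"dim{j}" for j in range(Z.shape[0])]
    pd.DataFrame(Z.T, index=ids, columns=cols).rename_axis("cell_id").to_csv(path)


def read_embedding_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float).T, list(df.index.astype(str))
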