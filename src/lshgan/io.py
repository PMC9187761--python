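"""Readers and writers for expression matrices and labelled benchmarks.

Dense matrices travel as CSV/TSV (cells x genes, header row of gene names,
first column of cell ids); sparse matrices as Matrix Market ``.mtx`` with
``genes.tsv`` / ``barcodes.tsv`` sidecars next to the file.  Labelled
synthetic benchmarks use CSV with the label in the first data column.
All values are written at full precision so round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .scrna_pipeline import ExpressionMatrix
from .synthetic_data import LabeledMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_labeled_csv",
    "write_labeled_csv",
]


def write_labeled_csv(data: LabeledMatrix, path: str | Path) -> None:
    """samples x features CSV: first column ``label``, then feature columns."""
    frame = pd.DataFrame(data.values, columns=data.feature_names)
    frame.insert(0, "label", data.labels)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_labeled_csv(path: str | Path) -> LabeledMatrix:
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise ValueError(f"{path}: expected a 'label' column")
    labels = frame.pop("label").to_numpy()
    return LabeledMatrix(values=frame.to_numpy(dtype=float),
                         labels=labels, feature_names=list(frame.columns))


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    """Write CSV/TSV (by suffix) or MTX + genes.tsv/barcodes.tsv sidecars."""
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(path, sparse.csr_matrix(X.values))
        pd.Series(X.gene_names).to_csv(path.with_name("genes.tsv"),
                                       index=False, header=False)
        pd.Series(X.cell_ids).to_csv(path.with_name("barcodes.tsv"),
                                     index=False, header=False)
        return
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    frame = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_names)
    frame.to_csv(path, sep=sep, index_label="cell_id", float_format="%.17g")


def read_expression(path: str | Path, layer: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression`."""
    path = Path(path)
    if path.suffix == ".mtx":
        values = np.asarray(spio.mmread(path).todense(), dtype=float)
        genes = pd.read_csv(path.with_name("genes.tsv"), header=None)[0].tolist()
        cells = pd.read_csv(path.with_name("barcodes.tsv"), header=None)[0].tolist()
        return ExpressionMatrix(values=values, gene_names=[str(g) for g in genes],
                                cell_ids=[str(c) for c in cells], layer=layer)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        gene_names=[str(g) for g in frame.columns],
        cell_ids=[str(c) for c in frame.index],
        layer=layer,
    )
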