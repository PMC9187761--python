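"""scRNA-seq preprocessing, augmentation and gene selection.

The downstream use of the generative model: a cells x genes matrix is
quality-filtered (cells with more than 1000 expressed genes; then genes
with a read count above 5 in at least 10% of the retained cells),
log2(x + 1)-normalised, augmented with generated cells until the
sample:feature ratio reaches a target (default 1.5), and scored per gene
with variability statistics — Fano factor (variance/mean), CV^2
(variance/mean^2), or binned standardised dispersion for highly variable
gene (HVG) selection.  Selected genes are validated by clustering the
cells and comparing against ground-truth labels with ARI and NMI.

Variances use the unbiased (n - 1) denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .gan_core import TrainedLshGan, generate

__all__ = [
    "ExpressionMatrix",
    "GeneScoreTable",
    "qc_filter",
    "log_normalize",
    "fano_factor",
    "cv2_index",
    "hvg_dispersion",
    "augment_to_ratio",
    "cluster_and_score",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix with names, optional labels and a layer tag."""

    values: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        c, g = self.values.shape
        if not self.gene_names:
            self.gene_names = [f"gene{j}" for j in range(g)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(c)]
        if len(self.gene_names) != g or len(self.cell_ids) != c:
            raise ValueError("gene_names/cell_ids lengths must match the matrix")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != c:
                raise ValueError("labels length must equal the number of cells")
        if self.layer not in ("counts", "lognorm"):
            raise ValueError("layer must be 'counts' or 'lognorm'")
        if self.layer == "counts" and np.any(self.values < 0):
            raise ValueError("counts layer must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cells: np.ndarray | None = None,
               genes: np.ndarray | None = None) -> "ExpressionMatrix":
        cells = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        genes = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        return ExpressionMatrix(
            values=self.values[np.ix_(cells, genes)],
            gene_names=[self.gene_names[j] for j in genes],
            cell_ids=[self.cell_ids[i] for i in cells],
            labels=None if self.labels is None else self.labels[cells],
            layer=self.layer,
        )


@dataclass
class GeneScoreTable:
    """Per-gene variability scores with a descending-score ranking."""

    gene_names: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if len(self.gene_names) != self.scores.shape[0]:
            raise ValueError("gene_names length must match scores")

    @property
    def order(self) -> np.ndarray:
        """Gene indices ranked by descending score; ties break by index."""
        return np.lexsort((np.arange(len(self.scores)), -self.scores))

    def top(self, n: int) -> list[str]:
        return [self.gene_names[j] for j in self.order[:n]]

    def to_frame(self) -> pd.DataFrame:
        rank = np.empty(len(self.scores), dtype=int)
        rank[self.order] = np.arange(1, len(self.scores) + 1)
        return pd.DataFrame({
            "gene": self.gene_names, "score": self.scores,
            "rank": rank, "method": self.method,
        })


class EmptyAfterFilterError(ValueError):
    """Raised when a QC threshold removes every cell or every gene."""


def qc_filter(
    raw: ExpressionMatrix,
    min_genes_per_cell: int = 1000,
    min_count: float = 5,
    min_cell_fraction: float = 0.10,
) -> ExpressionMatrix:
    """Keep cells with > ``min_genes_per_cell`` expressed (nonzero) genes,
    then genes with count > ``min_count`` in >= ``min_cell_fraction`` of the
    retained cells.

    Cells are filtered first; the gene fraction is computed on the surviving
    cells.  Idempotent: a matrix that passes once passes unchanged again.
    """
    if raw.layer != "counts":
        raise ValueError("qc_filter expects a counts layer")
    cells = np.flatnonzero((raw.values > 0).sum(axis=1) > min_genes_per_cell)
    if cells.size == 0:
        raise EmptyAfterFilterError(
            f"no cell has more than {min_genes_per_cell} expressed genes"
        )
    kept = raw.values[cells]
    frac = (kept > min_count).mean(axis=0)
    genes = np.flatnonzero(frac >= min_cell_fraction)
    if genes.size == 0:
        raise EmptyAfterFilterError(
            f"no gene has counts > {min_count} in >= {min_cell_fraction:.0%} of cells"
        )
    return raw.subset(cells, genes)


def log_normalize(X: ExpressionMatrix, library_size: bool = False) -> ExpressionMatrix:
    """log2(x + 1) transform; optionally scale libraries to the median first.

    ``library_size=True`` rescales each cell's counts so all libraries match
    the median library size before the log — a plain substitute for
    model-based normalisation, off by default.
    """
    if X.layer != "counts":
        raise ValueError("log_normalize expects a counts layer (already lognorm?)")
    if np.any(X.values < 0):
        raise ValueError("counts must be non-negative")
    vals = X.values
    if library_size:
        lib = vals.sum(axis=1)
        if np.any(lib == 0):
            raise ValueError("library-size scaling requires nonzero cell totals")
        vals = vals * (np.median(lib) / lib)[:, None]
    return ExpressionMatrix(
        values=np.log2(vals + 1.0), gene_names=list(X.gene_names),
        cell_ids=list(X.cell_ids), labels=X.labels, layer="lognorm",
    )


def _moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if values.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    return values.mean(axis=0), values.var(axis=0, ddof=1)


def fano_factor(X: ExpressionMatrix) -> GeneScoreTable:
    """Per-gene Fano factor variance/mean; zero-mean genes score 0."""
    mean, var = _moments(X.values)
    scores = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return GeneScoreTable(list(X.gene_names), scores, "fano")


def cv2_index(X: ExpressionMatrix) -> GeneScoreTable:
    """Per-gene squared coefficient of variation variance/mean^2."""
    mean, var = _moments(X.values)
    scores = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0) ** 2, 0.0)
    return GeneScoreTable(list(X.gene_names), scores, "cv2")


def hvg_dispersion(
    X: ExpressionMatrix, n_bins: int = 20, n_top: int = 500
) -> GeneScoreTable:
    """Mean-binned standardised dispersion for highly-variable-gene selection.

    Dispersion (variance/mean) is z-scored within ``n_bins`` equal-frequency
    bins of the per-gene mean, so the score measures excess variability at a
    given expression level.  Bins with no spread contribute z-scores of 0.
    ``.top(n_top)`` gives the selected genes.
    """
    if X.layer != "lognorm":
        raise ValueError("hvg_dispersion expects a lognorm layer")
    if X.n_genes < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes")
    mean, var = _moments(X.values)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.lexsort((np.arange(len(mean)), mean))
    z = np.zeros_like(disp)
    for bin_idx in np.array_split(order, n_bins):
        d = disp[bin_idx]
        sd = d.std(ddof=1) if d.size > 1 else 0.0
        if sd > 0:
            z[bin_idx] = (d - d.mean()) / sd
    return GeneScoreTable(list(X.gene_names), z, "hvg_dispersion")


def augment_to_ratio(
    X: ExpressionMatrix,
    model: TrainedLshGan,
    ratio: float = 1.5,
    seed: int = 0,
    prefix: str = "gen_",
) -> ExpressionMatrix:
    """Append generated cells until cells/genes >= ``ratio``.

    Real cells are preserved bit-for-bit at the top of the matrix; generated
    cells get ``prefix``-tagged ids.  If the matrix already meets the ratio
    the input is returned unchanged with a warning.
    """
    c, g = X.n_cells, X.n_genes
    target = ceil(ratio * g)
    if target <= c:
        warnings.warn(
            f"sample:feature ratio already {c / g:.2f} >= {ratio}; nothing to add",
            stacklevel=2,
        )
        return X
    if model.n_features != g:
        raise ValueError(
            f"model feature dimension {model.n_features} != n_genes {g}"
        )
    new = generate(model, target - c, seed=seed)
    return ExpressionMatrix(
        values=np.vstack([X.values, new]),
        gene_names=list(X.gene_names),
        cell_ids=list(X.cell_ids) + [f"{prefix}{i}" for i in range(target - c)],
        labels=None,
        layer=X.layer,
    )


def cluster_and_score(
    X: ExpressionMatrix,
    selected_genes: Sequence[str],
    n_clusters: int,
    truth: np.ndarray,
    method: str = "kmeans",
    seed: int = 0,
) -> tuple[float, float]:
    """Cluster cells on the selected genes and score against ``truth``.

    Returns (ARI, NMI).  ``method`` is 'kmeans' (default) or 'spectral'.
    """
    truth = np.asarray(truth)
    if truth.shape[0] != X.n_cells:
        raise ValueError("truth length must equal the number of cells")
    name_to_idx = {g: j for j, g in enumerate(X.gene_names)}
    missing = [g for g in selected_genes if g not in name_to_idx]
    if missing:
        raise ValueError(f"unknown gene identifiers: {missing[:5]}")
    cols = np.asarray([name_to_idx[g] for g in selected_genes])
    sub = X.values[:, cols]
    if method == "kmeans":
        pred = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(sub)
    elif method == "spectral":
        pred = SpectralClustering(
            n_clusters=n_clusters, random_state=seed, assign_labels="discretize"
        ).fit_predict(sub)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return (
        float(adjusted_rand_score(truth, pred)),
        float(normalized_mutual_info_score(truth, pred)),
    )
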