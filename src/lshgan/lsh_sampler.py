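"""Locality-sensitive-hashing subsampling of the training data.

The generator of the model is fed a subsample of the real data chosen to be
non-redundant and widely spread.  The subsample is produced in three steps:

1. a random-hyperplane hash forest is built over the samples — each of
   ``n_tables`` tables assigns every sample a ``hash_bits``-bit code from the
   signs of random Gaussian projections, so nearby points share long code
   prefixes with high probability;
2. approximate k-nearest neighbours are read off the forest: a query's
   candidate set is the union of its buckets across tables, widened by
   truncating trailing hash bits until at least ``k`` candidates (or all
   points) are in view, then ranked by exact Euclidean distance;
3. a greedy scan visits samples in row order, keeps each sample not yet
   discarded, and discards its k neighbours; optionally the whole procedure
   is repeated ``t`` times on the survivors.

Steps are deterministic given the forest seed; candidate-distance ties break
toward the smaller row index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "HashForestConfig",
    "HashForest",
    "NeighborList",
    "SamplerConfig",
    "LshSample",
    "build_hash_forest",
    "query_knn",
    "exact_knn",
    "greedy_subsample",
    "lsh_sampling",
]


@dataclass(frozen=True)
class HashForestConfig:
    n_tables: int = 8
    hash_bits: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tables < 1:
            raise ValueError("n_tables must be >= 1")
        if not 1 <= self.hash_bits <= 62:
            raise ValueError("hash_bits must be in [1, 62]")


@dataclass(frozen=True)
class SamplerConfig:
    """k nearest neighbours to discard per kept sample, and t greedy passes."""

    k: int = 5
    t: int = 1
    forest: HashForestConfig = field(default_factory=HashForestConfig)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")


@dataclass
class HashForest:
    """Random-hyperplane hash tables over the rows of a matrix.

    ``codes[tbl, i]`` packs the sign bits of the projections of row ``i``
    onto the table's hyperplanes, most significant bit first, so that
    integer right-shifts expose code prefixes.
    """

    projections: np.ndarray  # (n_tables, hash_bits, p)
    codes: np.ndarray  # (n_tables, n) int64
    X: np.ndarray
    config: HashForestConfig

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def buckets(self, table: int) -> dict[int, np.ndarray]:
        """Bucket key -> sample indices for one table (full-length codes)."""
        out: dict[int, list[int]] = {}
        for i, c in enumerate(self.codes[table]):
            out.setdefault(int(c), []).append(i)
        return {key: np.asarray(v) for key, v in out.items()}


class NeighborList(NamedTuple):
    """Per-sample neighbour indices and Euclidean distances, nearest first."""

    indices: np.ndarray  # (n, k) int
    distances: np.ndarray  # (n, k) float

    @property
    def k(self) -> int:
        return self.indices.shape[1]


class LshSample(NamedTuple):
    values: np.ndarray
    indices: np.ndarray


def build_hash_forest(X: np.ndarray, cfg: HashForestConfig | None = None) -> HashForest:
    """Hash every row of ``X`` into one bucket per table."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    cfg = cfg or HashForestConfig()
    rng = np.random.default_rng(cfg.seed)
    proj = rng.standard_normal((cfg.n_tables, cfg.hash_bits, X.shape[1]))
    # bits[tbl, i, b] = 1 iff row i lies on the positive side of hyperplane b
    bits = (np.einsum("tbp,ip->tib", proj, X) > 0).astype(np.int64)
    weights = 1 << np.arange(cfg.hash_bits - 1, -1, -1, dtype=np.int64)
    codes = bits @ weights
    return HashForest(projections=proj, codes=codes, X=X, config=cfg)


def _candidates(forest: HashForest, i: int, k: int) -> np.ndarray:
    """Candidate neighbours of sample ``i``: bucket union with prefix widening."""
    n = forest.n_samples
    bits = forest.config.hash_bits
    codes = forest.codes
    for drop in range(bits + 1):
        if drop < bits:
            mask = np.any((codes >> drop) == (codes[:, i, None] >> drop), axis=0)
        else:
            mask = np.ones(n, dtype=bool)
        mask[i] = False
        if mask.sum() >= k or drop == bits:
            return np.flatnonzero(mask)
    raise AssertionError("unreachable")


def query_knn(forest: HashForest, k: int) -> NeighborList:
    """Approximate k nearest neighbours of every indexed sample.

    Distance ties break toward the smaller sample index.
    """
    n = forest.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples n={n}")
    idx_out = np.empty((n, k), dtype=int)
    dist_out = np.empty((n, k), dtype=float)
    X = forest.X
    for i in range(n):
        cand = _candidates(forest, i, k)
        d = np.linalg.norm(X[cand] - X[i], axis=1)
        order = np.lexsort((cand, d))[:k]
        idx_out[i] = cand[order]
        dist_out[i] = d[order]
    return NeighborList(indices=idx_out, distances=dist_out)


def exact_knn(X: np.ndarray, k: int) -> NeighborList:
    """Brute-force exact k-NN (the oracle the hash forest approximates)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples n={n}")
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    idx_out = np.empty((n, k), dtype=int)
    dist_out = np.empty((n, k), dtype=float)
    all_idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((all_idx, d[i]))[:k]
        idx_out[i] = order
        dist_out[i] = d[i, order]
    return NeighborList(indices=idx_out, distances=dist_out)


def greedy_subsample(
    neighbors: NeighborList | Sequence[Sequence[int]],
    order: Sequence[int],
) -> list[int]:
    """Greedy scan: keep a sample not yet discarded, discard its neighbours.

    ``order`` must be a permutation of all sample indices; the kept indices
    are returned in scan order.  The first index of the scan is always kept.
    """
    if isinstance(neighbors, NeighborList):
        lists: Sequence[Sequence[int]] = neighbors.indices
    else:
        lists = neighbors
    order = np.asarray(order, dtype=int)
    n = len(lists)
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError("order must be a permutation of range(n)")
    discarded = np.zeros(n, dtype=bool)
    kept = np.zeros(n, dtype=bool)
    selected: list[int] = []
    for i in order:
        if discarded[i]:
            continue
        selected.append(int(i))
        kept[i] = True
        for j in lists[i]:
            if not kept[j]:  # a sample already kept stays kept
                discarded[j] = True
    return selected


def lsh_sampling(X: np.ndarray, cfg: SamplerConfig | None = None) -> LshSample:
    """Subsample rows of ``X`` by t rounds of hash-forest k-NN greedy selection.

    Each round rebuilds the forest on the survivors (with a round-specific
    seed offset) and recomputes neighbours, so later rounds see the thinned
    geometry.  If fewer than ``k + 1`` survivors remain before a round,
    iteration stops early with a warning.
    """
    X = np.asarray(X, dtype=float)
    cfg = cfg or SamplerConfig()
    if X.shape[0] <= cfg.k:
        raise ValueError(f"need more than k={cfg.k} samples, got {X.shape[0]}")
    idx = np.arange(X.shape[0])
    for round_no in range(cfg.t):
        if len(idx) < cfg.k + 1 and round_no > 0:
            warnings.warn(
                f"stopping after {round_no} of {cfg.t} rounds: only {len(idx)} "
                f"samples left (need > k+1 = {cfg.k + 1})",
                stacklevel=2,
            )
            break
        forest_cfg = HashForestConfig(
            n_tables=cfg.forest.n_tables,
            hash_bits=cfg.forest.hash_bits,
            seed=cfg.forest.seed + round_no,
        )
        forest = build_hash_forest(X[idx], forest_cfg)
        nl = query_knn(forest, cfg.k)
        kept = greedy_subsample(nl, np.arange(len(idx)))
        idx = idx[kept]
    return LshSample(values=X[idx], indices=idx)
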