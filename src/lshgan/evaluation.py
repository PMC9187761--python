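"""Quality metrics and experiment protocols for generated samples.

Two complementary views of generation quality:

* distributional — the mean over features of the 1-D empirical order-1
  Wasserstein distance between the feature marginals of two sample sets
  (a sliced variant over random projections is available for sensitivity
  analysis);
* discriminative — the cross-validated AUC of a random forest trained to
  tell real rows from generated rows; indistinguishable samples drive the
  AUC toward 0.5.

On top of the metrics sit the benchmark protocols: the (k, t, epoch) grid
search that picks the sampler setting and epoch with minimal holdout
Wasserstein distance, and the simulated-data experiment that trains the
subsample-augmented model at several k alongside a pure-noise baseline GAN
on the 2-class Gaussian mixture (80:20 split) and tabulates the holdout
Wasserstein distance at a series of epoch checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .gan_core import TrainConfig, train_lsh_gan, train_vanilla_gan
from .lsh_sampler import SamplerConfig
from .synthetic_data import MixtureSpec, make_gaussian_mixture

__all__ = [
    "EvalReport",
    "ParamSelection",
    "BenchmarkGrid",
    "wasserstein_metric",
    "discriminability_auc",
    "evaluate_generated",
    "select_sampling_params",
    "simulation_benchmark",
    "stratified_split",
]


@dataclass(frozen=True)
class EvalReport:
    wasserstein: float
    auc_mean: float
    auc_sd: float
    n_real: int
    n_generated: int
    settings: dict

    def __post_init__(self) -> None:
        if self.wasserstein < 0:
            raise ValueError("wasserstein must be >= 0")
        if not 0.0 <= self.auc_mean <= 1.0:
            raise ValueError("auc_mean must lie in [0, 1]")


@dataclass(frozen=True)
class ParamSelection:
    """Argmin of the (k, t, epoch) -> Wasserstein grid, plus the full grid."""

    k_star: int
    t_star: int
    e_opt: int
    grid: pd.DataFrame  # columns: k, t, epoch, wasserstein


@dataclass(frozen=True)
class BenchmarkGrid:
    """Model x epoch-checkpoint grid of holdout Wasserstein distances."""

    frame: pd.DataFrame  # index: model label, columns: epoch
    seed: int


def wasserstein_metric(
    A: np.ndarray,
    B: np.ndarray,
    method: str = "per_feature",
    n_projections: int = 50,
    seed: int = 0,
) -> float:
    """Order-1 Wasserstein distance between two sample sets.

    ``per_feature`` (default) averages the 1-D empirical W1 distance of the
    feature marginals over all features; ``sliced`` averages the W1 of the
    two sets projected onto ``n_projections`` random unit directions.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}"
        )
    if A.shape[0] < 1 or B.shape[0] < 1:
        raise ValueError("both sample sets must be non-empty")
    if method == "per_feature":
        return float(np.mean([
            wasserstein_distance(A[:, j], B[:, j]) for j in range(A.shape[1])
        ]))
    if method == "sliced":
        rng = np.random.default_rng(seed)
        dirs = rng.standard_normal((A.shape[1], n_projections))
        dirs /= np.linalg.norm(dirs, axis=0, keepdims=True)
        pa, pb = A @ dirs, B @ dirs
        return float(np.mean([
            wasserstein_distance(pa[:, j], pb[:, j]) for j in range(n_projections)
        ]))
    raise ValueError(f"unknown method {method!r}")


def discriminability_auc(
    real: np.ndarray,
    generated: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> tuple[float, float]:
    """Real-vs-generated random-forest AUC, stratified k-fold CV.

    Real rows are labelled 1, generated rows 0.  Returns (mean, sd) of the
    per-fold AUROC; values near 0.5 mean the forest cannot separate the two
    sets.
    """
    real = np.atleast_2d(np.asarray(real, dtype=float))
    generated = np.atleast_2d(np.asarray(generated, dtype=float))
    if min(real.shape[0], generated.shape[0]) < folds:
        raise ValueError(f"each class needs at least folds={folds} samples")
    X = np.vstack([real, generated])
    y = np.concatenate([np.ones(real.shape[0]), np.zeros(generated.shape[0])])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        aucs.append(roc_auc_score(y[test_idx], clf.predict_proba(X[test_idx])[:, 1]))
    return float(np.mean(aucs)), float(np.std(aucs))


def evaluate_generated(
    real: np.ndarray,
    generated: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Bundle the distributional and discriminative metrics into one report."""
    w = wasserstein_metric(real, generated)
    auc_mean, auc_sd = discriminability_auc(real, generated, folds=folds, seed=seed)
    return EvalReport(
        wasserstein=w, auc_mean=auc_mean, auc_sd=auc_sd,
        n_real=int(np.atleast_2d(real).shape[0]),
        n_generated=int(np.atleast_2d(generated).shape[0]),
        settings={"folds": folds, "seed": seed},
    )


def stratified_split(
    X: np.ndarray,
    labels: np.ndarray | None,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded row split; per-class proportional when labels are given.

    Returns (train_idx, test_idx).
    """
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = rng.permutation(n)
        n_test = max(int(round(test_fraction * n)), 1)
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    labels = np.asarray(labels)
    test_parts = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(cls_idx)
        n_test = max(int(round(test_fraction * len(cls_idx))), 1)
        test_parts.append(perm[:n_test])
    test_idx = np.sort(np.concatenate(test_parts))
    mask = np.ones(n, dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


def select_sampling_params(
    X: np.ndarray,
    k_grid: Sequence[int] = (5, 10, 15, 20),
    t_grid: Sequence[int] = (1, 2),
    epochs: int = 2000,
    cfg: TrainConfig | None = None,
    labels: np.ndarray | None = None,
) -> ParamSelection:
    """Grid-search (k, t) and the epoch with minimal holdout Wasserstein.

    One model is trained per (k, t) on an 80% split; each model's training
    history supplies the Wasserstein distance to the held-out 20% at every
    checkpoint, and the overall argmin (k*, t*, e_opt) is returned with the
    full grid.  Ties resolve to the first grid cell in (k, t, epoch) order.
    """
    if not k_grid or not t_grid:
        raise ValueError("k_grid and t_grid must be non-empty")
    cfg = cfg or TrainConfig()
    cfg = replace(cfg, epochs=epochs)
    X = np.asarray(X, dtype=float)
    train_idx, test_idx = stratified_split(X, labels, 0.2, cfg.seed)
    rows = []
    for k in k_grid:
        for t in t_grid:
            sampler = SamplerConfig(k=k, t=t, forest=cfg.sampler.forest)
            try:
                model = train_lsh_gan(X[train_idx], replace(cfg, sampler=sampler),
                                      holdout=X[test_idx])
            except Exception as exc:
                raise RuntimeError(f"training failed at (k={k}, t={t})") from exc
            for rec in model.history:
                rows.append({"k": k, "t": t, "epoch": rec["epoch"],
                             "wasserstein": rec["wasserstein"]})
    grid = pd.DataFrame(rows)
    best = grid.loc[grid["wasserstein"].idxmin()]
    return ParamSelection(k_star=int(best["k"]), t_star=int(best["t"]),
                          e_opt=int(best["epoch"]), grid=grid)


def simulation_benchmark(
    spec: MixtureSpec | None = None,
    k_grid: Sequence[int] = (5, 10, 15, 20),
    epoch_checkpoints: Sequence[int] = (10_000, 15_000, 20_000, 25_000),
    cfg: TrainConfig | None = None,
) -> BenchmarkGrid:
    """Simulated-data benchmark: subsample-augmented model vs pure-noise GAN.

    Generates the 2-class Gaussian mixture, splits it 80:20 (stratified),
    trains one model per k in ``k_grid`` (t = 1) plus the vanilla baseline,
    and records the Wasserstein distance between a generated sample and the
    test split at each epoch checkpoint of a single training trajectory.
    """
    checkpoints = tuple(sorted(int(e) for e in epoch_checkpoints))
    if len(checkpoints) == 0 or any(e < 1 for e in checkpoints):
        raise ValueError("epoch_checkpoints must be positive and non-empty")
    spec = spec or MixtureSpec()
    cfg = cfg or TrainConfig()
    cfg = replace(cfg, epochs=checkpoints[-1], checkpoints=checkpoints,
                  checkpoint_every=None)
    data = make_gaussian_mixture(spec)
    train_idx, test_idx = stratified_split(data.values, data.labels, 0.2, cfg.seed)
    X_train, X_test = data.values[train_idx], data.values[test_idx]

    rows: dict[str, list[float]] = {}
    for k in k_grid:
        sampler = SamplerConfig(k=k, t=1, forest=cfg.sampler.forest)
        model = train_lsh_gan(X_train, replace(cfg, sampler=sampler), holdout=X_test)
        rows[f"LSH-GAN k={k}"] = [rec["wasserstein"] for rec in model.history]
    baseline = train_vanilla_gan(X_train, cfg, holdout=X_test)
    rows["GAN"] = [rec["wasserstein"] for rec in baseline.history]

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(checkpoints))
    return BenchmarkGrid(frame=frame, seed=cfg.seed)
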