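"""Synthetic benchmarks for the generative model.

Two generators are provided:

* a 2-class non-overlapping Gaussian mixture in the high-dimension /
  small-sample (HDSS) regime — by default 100 samples x 1000 features,
  class-1 per-feature means drawn uniformly from [5, 15], class-2 from
  [-15, -5], and a Kac-Murdock-Szegő (KMS) covariance ``Sigma_ij =
  rho^|i-j|`` with ``rho = 0.5`` shared by both classes;
* a 2-D correlated Gaussian "toy" distribution used to visualise how fast a
  generative model recovers a known density.

Both are deterministic given their seed and are the fixtures every training
and evaluation test in this package runs on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixtureSpec",
    "LabeledMatrix",
    "kms_covariance",
    "make_gaussian_mixture",
    "make_toy_2d",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of the 2-class HDSS Gaussian mixture benchmark.

    Per-feature class means are drawn once, uniformly and independently,
    from the class's mean range; both classes share the KMS covariance.
    The disjoint mean ranges alone make the classes non-overlapping — no
    rejection step is applied.
    """

    n_samples: int = 100
    n_features: int = 1000
    mean_range_class1: tuple[float, float] = (5.0, 15.0)
    mean_range_class2: tuple[float, float] = (-15.0, -5.0)
    rho: float = 0.5
    class_proportions: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        p1, p2 = self.class_proportions
        if not (0 < p1 < 1 and 0 < p2 < 1) or abs(p1 + p2 - 1) > 1e-9:
            raise ValueError("class_proportions must lie in (0,1) and sum to 1")
        for lo, hi in (self.mean_range_class1, self.mean_range_class2):
            if hi < lo:
                raise ValueError("mean range must satisfy lo <= hi")


@dataclass
class LabeledMatrix:
    """A samples x features matrix with per-sample class labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must equal number of rows")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def kms_covariance(p: int, rho: float) -> np.ndarray:
    """KMS (AR(1)-type) covariance matrix with entries ``rho^|i-j|``.

    Positive definite for any |rho| < 1 and p >= 1.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(p)
    return np.asarray(rho, dtype=float) ** np.abs(idx[:, None] - idx[None, :])


def make_gaussian_mixture(spec: MixtureSpec) -> LabeledMatrix:
    """Draw the 2-class Gaussian mixture defined by ``spec``.

    Rows of class c follow N(mu_c, Sigma) where the entries of mu_c are
    uniform draws from the class's mean range and Sigma is the KMS matrix.
    Rows are ordered class 1 first, then class 2; a downstream train/test
    split should therefore shuffle (the evaluation module uses stratified
    seeded splits).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    mu1 = rng.uniform(*spec.mean_range_class1, size=p)
    mu2 = rng.uniform(*spec.mean_range_class2, size=p)
    n1 = int(round(spec.n_samples * spec.class_proportions[0]))
    n1 = min(max(n1, 1), spec.n_samples - 1)
    n2 = spec.n_samples - n1
    chol = np.linalg.cholesky(kms_covariance(p, spec.rho))
    z = rng.standard_normal((spec.n_samples, p))
    correlated = z @ chol.T
    values = np.empty_like(correlated)
    values[:n1] = correlated[:n1] + mu1
    values[n1:] = correlated[n1:] + mu2
    labels = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    return LabeledMatrix(values=values, labels=labels)


def make_toy_2d(
    n: int,
    center: tuple[float, float] = (0.0, 0.0),
    rho: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n`` points from a correlated bivariate normal.

    Unit marginal variances, correlation ``rho``, mean ``center``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal(np.asarray(center, dtype=float), cov, size=n,
                                   method="cholesky")
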