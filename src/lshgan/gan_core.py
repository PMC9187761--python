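"""Adversarial training with an LSH-subsample-augmented generator input.

A standard GAN feeds its generator pure noise z ~ p_z and plays the minimax
game

    min_G max_D  E_{x~p_data} log D(x) + E_{z~p_z} log(1 - D(G(z))).

Here the generator input distribution is replaced by p_zhat, a mixture on
the batch axis: a fraction ``mix_fraction`` of generator-input rows are
standard-normal noise vectors and the rest are rows of the LSH subsample
x_s of the real data (see :mod:`lshgan.lsh_sampler`).  Noise lives in the
same space as the data (noise_dim = n_features), so the generator maps
data space to data space and sees concrete examples of real structure in
its input from the first epoch — this is what lets it match the data
distribution in far fewer iterations than a pure-noise GAN.

Networks are 2-hidden-layer MLPs (default widths 16, 16; leaky-ReLU 0.2),
sigmoid output for the discriminator, identity output for the generator
(expression values are unbounded log-scale numbers).  The per-batch update
values are exactly

    delta_d = sum_i log D(x_i) + log(1 - D(G(zhat)_i))   (ascended by D)
    delta_g = sum_i log(1 - D(G(zhat)_i))                (descended by G)

with an optional non-saturating generator objective (ascend
sum_i log D(G(zhat)_i)) that is the package default because the saturating
form stalls against an early-winning discriminator.

Optimisation follows the practice that makes small adversarial games
converge rather than cycle: ADAM with beta1 = 0.5, small resampled
minibatches, a short discriminator warm-up before the first generator
step, an exponentially averaged (EMA) copy of the generator used for
sampling, and a few independent restarts from which the run with the best
final Wasserstein fit to the training data is kept (adversarial training
of tiny MLPs is bistable; restarts + the method's own Wasserstein model
selection resolve it).  Everything is plain numpy with manual
backpropagation and is bit-reproducible given the config seed on a single
thread.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .lsh_sampler import LshSample, SamplerConfig, lsh_sampling

__all__ = [
    "NetworkSpec",
    "GeneratorInputSpec",
    "TrainConfig",
    "TrainedLshGan",
    "augment_generator_input",
    "discriminator_update_value",
    "generator_update_value",
    "train_lsh_gan",
    "train_vanilla_gan",
    "generate",
]

#: discriminator outputs are clamped to [PROB_EPS, 1 - PROB_EPS] inside logs
PROB_EPS = 1e-7


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    input_dim: int
    hidden_dims: tuple[int, ...] = (16, 16)
    output_dim: int = 1
    hidden_activation: str = "leaky_relu"
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        dims = (self.input_dim, *self.hidden_dims, self.output_dim)
        if any(d < 1 for d in dims):
            raise ValueError("all network dimensions must be >= 1")
        if self.hidden_activation != "leaky_relu":
            raise ValueError("only leaky_relu hidden activations are supported")
        if self.output_activation not in ("sigmoid", "identity"):
            raise ValueError("output activation must be 'sigmoid' or 'identity'")


_LEAK = 0.2


class _MLP:
    """Minimal fully-connected net with manual backprop.

    ``backward`` takes the loss gradient with respect to the *pre-activation*
    of the output layer, which keeps the sigmoid/log algebra exact for the
    discriminator and is a no-op distinction for the identity-output
    generator.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden_dims, spec.output_dim]
        self.W = [
            rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / dims[i])
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._inputs: list[np.ndarray] = []
        self._preacts: list[np.ndarray] = []

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        h = X
        inputs, preacts = [], []
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            inputs.append(h)
            a = h @ W + b
            preacts.append(a)
            if i < last:
                h = np.where(a > 0, a, _LEAK * a)
            elif self.spec.output_activation == "sigmoid":
                h = _sigmoid(a)
            else:
                h = a
        if cache:
            self._inputs, self._preacts = inputs, preacts
        return h

    def backward(self, d_preact_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Return (param gradients aligned with ``params``, gradient wrt input)."""
        gW: list[np.ndarray] = [np.empty(0)] * len(self.W)
        gb: list[np.ndarray] = [np.empty(0)] * len(self.b)
        grad = d_preact_out
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = self._inputs[i].T @ grad
            gb[i] = grad.sum(axis=0)
            grad = grad @ self.W[i].T
            if i > 0:
                a = self._preacts[i - 1]
                grad = grad * np.where(a > 0, 1.0, _LEAK)
        return gW + gb, grad


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, betas: tuple[float, float]):
        self.lr = lr
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + 1e-8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorInputSpec:
    """How generator-input batches mix prior noise with subsample rows.

    ``mix_fraction`` is the fraction of rows that are iid N(0, noise_sd^2)
    noise; 1.0 reduces to the pure-noise (vanilla) generator input, 0.0
    feeds only subsample rows.  ``noise_dim`` must equal the data feature
    dimension (None means "infer from the data").
    """

    noise_dim: int | None = None
    noise_sd: float = 1.0
    mix_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError("mix_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and optimiser settings.

    ``batch_size`` rows of real data and generator input are resampled per
    epoch (None = full batch).  ``d_warmup`` discriminator-only steps
    precede the first generator update so the generator's very first
    gradients already point at the data region.  ``ema_decay`` controls the
    averaged generator used for sampling (None = use the last iterate).
    ``restarts`` independent initialisations are trained and the one whose
    final generated sample is closest (Wasserstein) to the training data is
    returned.
    """

    epochs: int = 2000
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    gen_input: GeneratorInputSpec = field(default_factory=GeneratorInputSpec)
    hidden_dims: tuple[int, ...] = (16, 16)
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int | None = 32
    d_warmup: int = 500
    d_steps_per_epoch: int = 1
    g_steps_per_epoch: int = 1
    non_saturating: bool = True
    ema_decay: float | None = 0.999
    restarts: int = 3
    checkpoint_every: int | None = None
    checkpoints: tuple[int, ...] | None = None
    eval_size: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.d_steps_per_epoch < 1 or self.g_steps_per_epoch < 1:
            raise ValueError("step counts must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.ema_decay is not None and not 0.0 < self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in (0, 1)")

    def checkpoint_epochs(self) -> list[int]:
        """Epochs at which history is recorded; always includes the last."""
        if self.checkpoints is not None:
            eps = sorted(set(int(e) for e in self.checkpoints))
            if any(e < 1 or e > self.epochs for e in eps):
                raise ValueError("checkpoints must lie in [1, epochs]")
            return eps
        every = self.checkpoint_every or max(self.epochs // 10, 1)
        eps = list(range(every, self.epochs + 1, every))
        if not eps or eps[-1] != self.epochs:
            eps.append(self.epochs)
        return eps


@dataclass
class TrainedLshGan:
    """A trained generator/discriminator pair plus its training history.

    ``generator`` is the EMA-averaged network used for sampling (equal to
    the last iterate when ``ema_decay`` is None).  ``history`` holds one
    record per checkpoint of the selected restart: epoch, the batch sums
    delta_d and delta_g, and (when a holdout was supplied) the mean
    per-feature Wasserstein distance from a generated sample to the
    holdout.
    """

    generator: _MLP
    discriminator: _MLP
    config: TrainConfig
    subsample: LshSample | None
    history: list[dict]
    train_fit: float = float("nan")  # final Wasserstein to the training data
    restart_fits: tuple[float, ...] = ()

    @property
    def n_features(self) -> int:
        return self.generator.spec.input_dim


# ---------------------------------------------------------------------------
# batch construction and update values
# ---------------------------------------------------------------------------

def augment_generator_input(
    x_s: np.ndarray | None,
    batch_size: int,
    spec: GeneratorInputSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a generator-input batch zhat from the mixture p_zhat.

    ``round(mix_fraction * batch_size)`` rows are iid noise; the remainder
    are drawn uniformly with replacement from the rows of ``x_s``; row order
    is then shuffled.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_noise = int(round(spec.mix_fraction * batch_size))
    n_real = batch_size - n_noise
    if n_real > 0:
        if x_s is None:
            raise ValueError("mix_fraction < 1 requires a subsample x_s")
        x_s = np.asarray(x_s, dtype=float)
        if x_s.ndim != 2 or x_s.shape[0] < 1:
            raise ValueError("x_s must be a non-empty 2-D matrix")
        p = x_s.shape[1]
        if spec.noise_dim is not None and spec.noise_dim != p:
            raise ValueError(
                f"noise_dim={spec.noise_dim} does not match x_s feature dim {p}"
            )
    else:
        p = spec.noise_dim
        if p is None:
            if x_s is None:
                raise ValueError("noise_dim must be given when x_s is absent")
            p = np.asarray(x_s).shape[1]
    noise = rng.normal(scale=spec.noise_sd, size=(n_noise, p))
    if n_real > 0:
        picks = rng.integers(0, x_s.shape[0], size=n_real)
        batch = np.vstack([noise, x_s[picks]])
    else:
        batch = noise
    return batch[rng.permutation(batch_size)]


def _check_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError(f"{name} must be probabilities in [0, 1]")
    return np.clip(p, PROB_EPS, 1 - PROB_EPS)


def discriminator_update_value(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Batch sum delta_d = sum log D(x_i) + log(1 - D(G(zhat)_i))."""
    d_real = _check_probs(d_real, "d_real")
    d_fake = _check_probs(d_fake, "d_fake")
    return float(np.sum(np.log(d_real)) + np.sum(np.log1p(-d_fake)))


def generator_update_value(d_fake: np.ndarray, non_saturating: bool = False) -> float:
    """Batch sum delta_g = sum log(1 - D(G(zhat)_i)).

    With ``non_saturating`` the returned value is -sum log D(G(zhat)_i),
    whose descent is the standard stabilised generator objective.
    """
    d_fake = _check_probs(d_fake, "d_fake")
    if non_saturating:
        return float(-np.sum(np.log(d_fake)))
    return float(np.sum(np.log1p(-d_fake)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _eval_wasserstein(
    gen_net: _MLP,
    x_s: np.ndarray | None,
    cfg: TrainConfig,
    reference: np.ndarray,
    tag: int,
) -> float:
    # local import: evaluation depends on this module for training helpers
    from .evaluation import wasserstein_metric

    eval_rng = np.random.default_rng((cfg.seed * 1_000_003 + tag) % (2**31))
    zhat = augment_generator_input(x_s, cfg.eval_size, cfg.gen_input, eval_rng)
    return wasserstein_metric(gen_net.forward(zhat), reference)


def _train_single(
    X: np.ndarray,
    cfg: TrainConfig,
    x_s: np.ndarray | None,
    restart: int,
    holdout: np.ndarray | None,
) -> tuple[_MLP, _MLP, list[dict], float]:
    """One adversarial run; returns (EMA generator, discriminator, history,
    final Wasserstein fit to the training data)."""
    n, p = X.shape
    init_rng = np.random.default_rng([cfg.seed, restart])
    gen = _MLP(
        NetworkSpec(p, cfg.hidden_dims, p, output_activation="identity"), init_rng
    )
    disc = _MLP(NetworkSpec(p, cfg.hidden_dims, 1, output_activation="sigmoid"),
                init_rng)
    adam_g = _Adam(gen.params, cfg.learning_rate, cfg.adam_betas)
    adam_d = _Adam(disc.params, cfg.learning_rate, cfg.adam_betas)
    ema = copy.deepcopy(gen) if cfg.ema_decay is not None else gen

    train_rng = np.random.default_rng([cfg.seed + 1, restart])
    batch = cfg.batch_size or n
    checkpoints = set(cfg.checkpoint_epochs())
    history: list[dict] = []
    delta_d = delta_g = float("nan")

    def d_step() -> float:
        real = X[train_rng.integers(0, n, size=batch)] if cfg.batch_size else X
        zhat = augment_generator_input(x_s, batch, cfg.gen_input, train_rng)
        fake = gen.forward(zhat)
        d_real = disc.forward(real, cache=True)
        # gradient of -delta_d wrt real-batch output logits: sigma(a) - 1
        grads_real, _ = disc.backward(d_real - 1.0)
        d_fake = disc.forward(fake, cache=True)
        grads_fake, _ = disc.backward(d_fake.copy())
        value = discriminator_update_value(d_real.ravel(), d_fake.ravel())
        adam_d.step(disc.params, [a + b for a, b in zip(grads_real, grads_fake)])
        return value

    def g_step() -> float:
        zhat = augment_generator_input(x_s, batch, cfg.gen_input, train_rng)
        fake = gen.forward(zhat, cache=True)
        d_fake = disc.forward(fake, cache=True)
        if cfg.non_saturating:
            # ascend sum log D: d(-loss)/dlogit = sigma(a) - 1
            _, d_input = disc.backward(d_fake - 1.0)
        else:
            # descend sum log(1 - D): d loss/dlogit = -sigma(a)
            _, d_input = disc.backward(-d_fake)
        grads, _ = gen.backward(d_input)
        value = generator_update_value(d_fake.ravel(), cfg.non_saturating)
        adam_g.step(gen.params, grads)
        return value

    for _ in range(cfg.d_warmup):
        d_step()

    for epoch in range(1, cfg.epochs + 1):
        for _ in range(cfg.d_steps_per_epoch):
            delta_d = d_step()
        for _ in range(cfg.g_steps_per_epoch):
            delta_g = g_step()
        if cfg.ema_decay is not None:
            for pe, pg in zip(ema.params, gen.params):
                pe *= cfg.ema_decay
                pe += (1 - cfg.ema_decay) * pg
        if not (np.isfinite(delta_d) and np.isfinite(delta_g)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: delta_d={delta_d}, "
                f"delta_g={delta_g}"
            )
        if epoch in checkpoints:
            rec = {"epoch": epoch, "delta_d": delta_d, "delta_g": delta_g}
            if holdout is not None:
                rec["wasserstein"] = _eval_wasserstein(ema, x_s, cfg, holdout, epoch)
            history.append(rec)

    fit = _eval_wasserstein(ema, x_s, cfg, X, 0)
    return ema, disc, history, fit


def train_lsh_gan(
    X: np.ndarray,
    cfg: TrainConfig | None = None,
    holdout: np.ndarray | None = None,
) -> TrainedLshGan:
    """Train the subsample-augmented GAN on the rows of ``X``.

    The LSH subsample is computed once up front (the procedure is
    deterministic given its seed, so recomputing it inside the epoch loop
    would be a no-op).  ``cfg.restarts`` independent runs are trained; the
    returned model is the restart whose final generated sample is closest
    to the training data in mean per-feature Wasserstein distance — the
    same criterion the evaluation protocol uses for epoch and (k, t)
    selection.  History (and, when ``holdout`` is given, the per-checkpoint
    holdout Wasserstein distance) is that of the selected restart; holdout
    evaluation uses checkpoint-specific RNG streams and never perturbs the
    training trajectory.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n, p = X.shape
    if cfg.gen_input.noise_dim is not None and cfg.gen_input.noise_dim != p:
        raise ValueError("gen_input.noise_dim must equal the feature dimension")
    if cfg.gen_input.noise_dim is None:
        cfg = replace(cfg, gen_input=replace(cfg.gen_input, noise_dim=p))

    subsample: LshSample | None = None
    x_s: np.ndarray | None = None
    if cfg.gen_input.mix_fraction < 1.0:
        subsample = lsh_sampling(X, cfg.sampler)
        x_s = subsample.values

    best: tuple[_MLP, _MLP, list[dict], float] | None = None
    fits: list[float] = []
    for restart in range(cfg.restarts):
        result = _train_single(X, cfg, x_s, restart, holdout)
        fits.append(result[3])
        if best is None or result[3] < best[3]:
            best = result

    gen, disc, history, fit = best
    return TrainedLshGan(
        generator=gen, discriminator=disc, config=cfg, subsample=subsample,
        history=history, train_fit=fit, restart_fits=tuple(fits),
    )


def train_vanilla_gan(
    X: np.ndarray,
    cfg: TrainConfig | None = None,
    holdout: np.ndarray | None = None,
) -> TrainedLshGan:
    """Baseline GAN: identical networks and schedule, pure-noise input."""
    cfg = cfg or TrainConfig()
    cfg = replace(cfg, gen_input=replace(cfg.gen_input, mix_fraction=1.0))
    return train_lsh_gan(X, cfg, holdout)


def generate(model: TrainedLshGan, n: int, seed: int = 0) -> np.ndarray:
    """Generate ``n`` samples: draw zhat from p_zhat and map through G."""
    if n < 1:
        raise ValueError("n must be >= 1")
    x_s = model.subsample.values if model.subsample is not None else None
    zhat = augment_generator_input(x_s, n, model.config.gen_input,
                                   np.random.default_rng(seed))
    out = model.generator.forward(zhat)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("generator produced non-finite values")
    return out
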