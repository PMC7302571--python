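"""Stepwise (stacked) autoencoder for spectral feature reduction.

A spectrum with D features (1851 after preprocessing) is compressed to a
small code (10 by default) through a sequence of single-hidden-layer
autoencoders trained greedily: step 1 learns to reconstruct the input,
step 2 learns to reconstruct step 1's codes, and so on.  Taking several
steps loses very little information compared with a single large jump.
Once trained, the decoders are only used to report reconstruction error;
the classifier consumes the encoder outputs.

Encoder units are logistic by default (inputs must be scaled to [0, 1]);
decoder outputs are linear.  Both are configurable — linear/linear steps
make a single step equivalent to an (unregularised) PCA projection, which
the test-suite exploits as an optimality oracle.

Training is full-batch gradient descent with momentum and a multiplicative
step-size adaptation: an epoch that increases the loss is rolled back and
the learning rate halved, otherwise the rate grows slightly.  This keeps
the recorded loss trace monotone non-increasing and makes runs reproducible
from a seed alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .dataset import EncodedDataset, SpectralDataset, as_matrix
from .errors import (
    ConfigError,
    DimensionMismatchError,
    ScalingRangeError,
    StepDimensionError,
    TrainingDivergedError,
)

__all__ = [
    "AeConfig",
    "AutoencoderStep",
    "AutoencoderStack",
    "train_autoencoder",
    "encode",
    "encode_matrix",
    "reconstruct",
]

DEFAULT_STEP_DIMS = (256, 64, 10)


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return _logistic(z)
    if kind == "linear":
        return z
    raise ConfigError(f"unknown activation {kind!r}")


def _activation_grad(a: np.ndarray, kind: str) -> np.ndarray:
    """d activation / d pre-activation, expressed through the output a."""
    if kind == "logistic":
        return a * (1.0 - a)
    return np.ones_like(a)


@dataclass
class AeConfig:
    """Training settings for each autoencoder step.

    ``epochs`` is the full-batch epoch budget per step; ``learning_rate``
    is only the initial value — it adapts multiplicatively during
    training (halved on a rejected epoch, grown by ``lr_grow`` on an
    accepted one).
    """

    epochs: int = 1000
    learning_rate: float = 0.1
    momentum: float = 0.9
    lr_grow: float = 1.02
    lr_shrink: float = 0.5
    encoder_activation: str = "logistic"
    decoder_activation: str = "linear"
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        problems = []
        if self.epochs < 0:
            problems.append("epochs must be >= 0")
        if not (0 < self.learning_rate):
            problems.append("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            problems.append("momentum must lie in [0, 1)")
        for name in ("encoder_activation", "decoder_activation"):
            if getattr(self, name) not in ("logistic", "linear"):
                problems.append(f"{name} must be 'logistic' or 'linear'")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class AutoencoderStep:
    """One encoder/decoder pair of the stack."""

    W_enc: np.ndarray  # (code_dim, input_dim)
    b_enc: np.ndarray  # (code_dim,)
    W_dec: np.ndarray  # (input_dim, code_dim)
    b_dec: np.ndarray  # (input_dim,)
    encoder_activation: str = "logistic"
    decoder_activation: str = "linear"

    @property
    def input_dim(self) -> int:
        return self.W_enc.shape[1]

    @property
    def code_dim(self) -> int:
        return self.W_enc.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        return _activate(X @ self.W_enc.T + self.b_enc, self.encoder_activation)

    def decode(self, H: np.ndarray) -> np.ndarray:
        return _activate(H @ self.W_dec.T + self.b_dec, self.decoder_activation)


@dataclass
class AutoencoderStack:
    """Ordered encoder/decoder pairs plus per-step reconstruction error.

    ``step_mse[i]`` is the mean-square error of reconstructing the
    original training matrix after encoding through steps ``0..i`` and
    decoding back — the per-step reconstruction-accuracy report.
    """

    steps: list[AutoencoderStep]
    step_mse: list[float] = field(default_factory=list)
    loss_traces: list[np.ndarray] = field(default_factory=list)
    training_config: AeConfig | None = None
    seed: int | None = None

    @property
    def input_dim(self) -> int:
        return self.steps[0].input_dim

    @property
    def code_dim(self) -> int:
        return self.steps[-1].code_dim

    @property
    def step_dims(self) -> tuple[int, ...]:
        return tuple(s.code_dim for s in self.steps)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for s in self.steps:
            for arr in (s.W_enc, s.b_enc, s.W_dec, s.b_dec):
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


def _check_step_dims(input_dim: int, step_dims) -> tuple[int, ...]:
    dims = tuple(int(k) for k in step_dims)
    if not dims:
        raise StepDimensionError("step_dims must list at least one code size")
    previous = input_dim
    for k in dims:
        # equality is allowed so a single identity-capable step is expressible
        if k > previous or k < 1:
            raise StepDimensionError(
                f"step dimensions must be non-increasing from the input "
                f"dimension {input_dim}; got {dims}"
            )
        previous = k
    return dims


def _train_step(
    X: np.ndarray,
    code_dim: int,
    config: AeConfig,
    rng: np.random.Generator,
) -> tuple[AutoencoderStep, np.ndarray]:
    """Train one autoencoder step on X; returns the step and its loss trace."""
    n, d = X.shape
    s = config.init_scale
    W_enc = rng.uniform(-s, s, size=(code_dim, d))
    b_enc = np.zeros(code_dim)
    W_dec = rng.uniform(-s, s, size=(d, code_dim))
    b_dec = np.zeros(d)
    step = AutoencoderStep(W_enc, b_enc, W_dec, b_dec,
                           config.encoder_activation, config.decoder_activation)

    params = [W_enc, b_enc, W_dec, b_dec]
    velocity = [np.zeros_like(p) for p in params]
    lr = config.learning_rate
    scale = 1.0 / (n * d)

    def loss() -> float:
        err = step.decode(step.encode(X)) - X
        return float(np.mean(err * err))

    prev_loss = loss()
    trace = [prev_loss]
    for _ in range(config.epochs):
        H = step.encode(X)
        Xhat = step.decode(H)
        E = Xhat - X
        dZd = (2.0 * scale) * E * _activation_grad(Xhat, step.decoder_activation)
        g_Wd = dZd.T @ H
        g_bd = dZd.sum(axis=0)
        dH = dZd @ step.W_dec
        dZe = dH * _activation_grad(H, step.encoder_activation)
        g_We = dZe.T @ X
        g_be = dZe.sum(axis=0)
        grads = [g_We, g_be, g_Wd, g_bd]

        backup = [p.copy() for p in params]
        for p, v, g in zip(params, velocity, grads):
            v *= config.momentum
            v -= lr * g
            p += v
        new_loss = loss()
        if not np.isfinite(new_loss):
            raise TrainingDivergedError(
                f"autoencoder step loss became non-finite "
                f"(lr={lr:.3g}, epoch={len(trace)}, prev loss={prev_loss:.3g})"
            )
        if new_loss <= prev_loss:
            prev_loss = new_loss
            lr *= config.lr_grow
        else:  # roll back the epoch, damp the step size
            for p, b, v in zip(params, backup, velocity):
                p[...] = b
                v[...] = 0.0
            lr *= config.lr_shrink
        trace.append(prev_loss)
    return step, np.asarray(trace)


def train_autoencoder(
    train,
    step_dims=DEFAULT_STEP_DIMS,
    config: AeConfig | None = None,
    seed: int = 0,
) -> AutoencoderStack:
    """Greedy layer-wise training of the compression stack.

    Step ``i`` is trained to reconstruct the codes emitted by step
    ``i - 1`` (step 1 reconstructs the input matrix).  With logistic
    encoder units the input must be scaled to [0, 1].  Deterministic
    under a fixed seed.
    """
    config = config if config is not None else AeConfig()
    X = as_matrix(train)
    dims = _check_step_dims(X.shape[1], step_dims)
    if config.encoder_activation == "logistic":
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise ScalingRangeError(
                f"logistic encoder units require inputs in [0, 1]; data range "
                f"is [{X.min():.4g}, {X.max():.4g}] — apply the min-max scaler"
            )

    steps: list[AutoencoderStep] = []
    traces: list[np.ndarray] = []
    current = X
    for i, k in enumerate(dims):
        rng = np.random.default_rng([int(seed), i])
        step, trace = _train_step(current, k, config, rng)
        steps.append(step)
        traces.append(trace)
        current = step.encode(current)

    stack = AutoencoderStack(steps=steps, loss_traces=traces,
                             training_config=config, seed=int(seed))
    stack.step_mse = [
        reconstruct(stack, X, through_step=i + 1)[1] for i in range(len(steps))
    ]
    return stack


def encode_matrix(stack: AutoencoderStack, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != stack.input_dim:
        raise DimensionMismatchError(
            f"stack expects {stack.input_dim} features, got {X.shape[1]}"
        )
    for step in stack.steps:
        X = step.encode(X)
    return X


def encode(stack: AutoencoderStack, dataset: SpectralDataset) -> EncodedDataset:
    """Apply all encoder halves in order; labels and metadata untouched."""
    codes = encode_matrix(stack, as_matrix(dataset))
    return EncodedDataset(
        codes=codes,
        sample_ids=list(dataset.sample_ids),
        labels=None if dataset.labels is None else dataset.labels.copy(),
        cohort=None if getattr(dataset, "cohort", None) is None else dataset.cohort.copy(),
        encoder_fingerprint=stack.fingerprint(),
        split_id=getattr(dataset, "split_id", None),
        partition=getattr(dataset, "partition", None),
    )


def reconstruct(
    stack: AutoencoderStack,
    dataset,
    through_step: int | None = None,
) -> tuple[np.ndarray, float]:
    """Encode through ``through_step`` steps, decode back, return (X̂, MSE).

    MSE is the mean over all matrix entries of the squared reconstruction
    error against the input.
    """
    X = as_matrix(dataset)
    if X.shape[1] != stack.input_dim:
        raise DimensionMismatchError(
            f"stack expects {stack.input_dim} features, got {X.shape[1]}"
        )
    k = len(stack.steps) if through_step is None else int(through_step)
    if not (1 <= k <= len(stack.steps)):
        raise IndexError(
            f"through_step must lie in [1, {len(stack.steps)}], got {k}"
        )
    H = X
    for step in stack.steps[:k]:
        H = step.encode(H)
    for step in reversed(stack.steps[:k]):
        H = step.decode(H)
    mse = float(np.mean((H - X) ** 2))
    return H, mse
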