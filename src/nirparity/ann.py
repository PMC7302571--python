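"""Feed-forward parity classifier trained by Levenberg-Marquardt.

The classifier is a one-hidden-layer network with ten logistic hidden
units and a logistic output unit producing a parity score in (0, 1);
a sample is called parous when its score strictly exceeds the decision
threshold (0.5 by default, so a score of exactly 0.5 is nulliparous).

Training minimises the sum of squared residuals e_i = y_i - f(x_i) with
the Levenberg-Marquardt update

    (JᵀJ + μI) δ = Jᵀe,

where J is the N x P Jacobian of the network output with respect to all
weights and biases, assembled by backpropagation.  A step is accepted
(and the damping μ decreased) only if it reduces the sum of squares;
otherwise it is rejected and μ increased, interpolating between
Gauss-Newton (μ → 0) and small-step gradient descent (μ large).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import as_matrix, get_labels
from .errors import (
    ConfigError,
    DimensionMismatchError,
    LabelValueError,
    TrainingInputError,
    TrainingSingularError,
)

__all__ = ["AnnClassifier", "LinearUnit", "LmConfig", "LmTrace", "lm_fit", "predict"]

MU_MIN = 1e-12
MU_MAX = 1e12


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class AnnClassifier:
    """One-hidden-layer logistic network for binary parity scoring.

    Parameters are ``W1`` (hidden x input), ``b1``, ``W2`` (1 x hidden),
    ``b2``.  ``threshold`` is the decision cutoff applied to the output
    score (strict inequality).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=np.float64))
        self.b1 = np.asarray(self.b1, dtype=np.float64).ravel()
        self.W2 = np.atleast_2d(np.asarray(self.W2, dtype=np.float64))
        self.b2 = np.asarray(self.b2, dtype=np.float64).ravel()
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (1, h) or self.b2.shape != (1,):
            raise ConfigError("inconsistent classifier parameter shapes")

    # ------------------------------------------------------------------
    @classmethod
    def initialize(cls, n_inputs: int, hidden_units: int = 10, seed: int = 0,
                   threshold: float = 0.5) -> "AnnClassifier":
        """Seeded uniform(-0.5, 0.5)/sqrt(fan-in) weight initialisation."""
        rng = np.random.default_rng(int(seed))
        W1 = rng.uniform(-0.5, 0.5, size=(hidden_units, n_inputs)) / np.sqrt(n_inputs)
        b1 = rng.uniform(-0.5, 0.5, size=hidden_units) / np.sqrt(n_inputs)
        W2 = rng.uniform(-0.5, 0.5, size=(1, hidden_units)) / np.sqrt(hidden_units)
        b2 = rng.uniform(-0.5, 0.5, size=1) / np.sqrt(hidden_units)
        return cls(W1, b1, W2, b2, threshold=threshold)

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_units(self) -> int:
        return self.W1.shape[0]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def with_params(self, theta: np.ndarray) -> "AnnClassifier":
        h, d = self.W1.shape
        i = 0
        W1 = theta[i:i + h * d].reshape(h, d); i += h * d
        b1 = theta[i:i + h]; i += h
        W2 = theta[i:i + h].reshape(1, h); i += h
        b2 = theta[i:i + 1]
        return AnnClassifier(W1, b1, W2, b2, threshold=self.threshold)

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        A1 = _logistic(X @ self.W1.T + self.b1)
        return _logistic(A1 @ self.W2.T + self.b2).ravel()

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """N x P Jacobian of the output score w.r.t. all parameters."""
        X = self._check(X)
        n = X.shape[0]
        A1 = _logistic(X @ self.W1.T + self.b1)          # N x h
        s = _logistic(A1 @ self.W2.T + self.b2).ravel()  # N
        ds = s * (1.0 - s)                               # N
        # output layer
        J_W2 = ds[:, None] * A1                          # N x h
        J_b2 = ds[:, None]                               # N x 1
        # hidden layer
        dA1 = ds[:, None] * self.W2                      # N x h
        dZ1 = dA1 * A1 * (1.0 - A1)                      # N x h
        J_W1 = dZ1[:, :, None] * X[:, None, :]           # N x h x d
        J_b1 = dZ1                                       # N x h
        return np.concatenate(
            [J_W1.reshape(n, -1), J_b1, J_W2, J_b2], axis=1
        )

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_inputs:
            raise DimensionMismatchError(
                f"classifier expects {self.n_inputs} inputs, got {X.shape[1]}"
            )
        return X


@dataclass
class LinearUnit:
    """Single linear unit (identity activation, no hidden layer).

    A diagnostic/reference configuration: fitting it by Levenberg-
    Marquardt on a regression problem must reach the closed-form
    least-squares solution, which anchors the optimizer's correctness.
    """

    w: np.ndarray
    b: float = 0.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        self.b = float(self.b)

    @property
    def n_inputs(self) -> int:
        return self.w.size

    @property
    def n_params(self) -> int:
        return self.w.size + 1

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w, [self.b]])

    def with_params(self, theta: np.ndarray) -> "LinearUnit":
        return LinearUnit(theta[:-1], float(theta[-1]), threshold=self.threshold)

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return X @ self.w + self.b

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.hstack([X, np.ones((X.shape[0], 1))])


@dataclass
class LmConfig:
    """Levenberg-Marquardt settings.

    μ starts at ``mu_init``, is multiplied by ``mu_up`` on a rejected
    step and by ``mu_down`` on an accepted one, and must stay within
    [1e-12, 1e12]; training stops with a recorded reason when it would
    leave that range upward.
    """

    mu_init: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    max_iterations: int = 200
    gradient_tolerance: float = 1e-7
    min_mse_delta: float = 1e-9

    def __post_init__(self) -> None:
        problems = []
        if not (MU_MIN <= self.mu_init <= MU_MAX):
            problems.append(f"mu_init must lie in [{MU_MIN:g}, {MU_MAX:g}]")
        if self.mu_up <= 1:
            problems.append("mu_up must exceed 1")
        if not (0 < self.mu_down < 1):
            problems.append("mu_down must lie in (0, 1)")
        if self.max_iterations < 0:
            problems.append("max_iterations must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class LmTrace:
    """Per-iteration log: SSE after the iteration, μ used, accept flag."""

    sse: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)
    initial_sse: float = float("nan")
    stop_reason: str = ""

    def accepted_sse(self) -> list[float]:
        """SSE values after each accepted step, in order."""
        return [s for s, a in zip(self.sse, self.accepted) if a]


def lm_fit(model, train, config: LmConfig | None = None,
           targets: np.ndarray | None = None):
    """Fit ``model`` to binary labels (or explicit regression targets).

    ``model`` is any object exposing ``get_params / with_params /
    forward / jacobian`` — the parity network or the linear diagnostic
    unit.  Returns ``(fitted_model, LmTrace)``; the fitted model carries
    the best (lowest-SSE) parameters seen.
    """
    config = config if config is not None else LmConfig()
    X = as_matrix(train)
    if targets is not None:
        y = np.asarray(targets, dtype=np.float64).ravel()
    else:
        y = get_labels(train).astype(np.float64)
    if y.shape[0] != X.shape[0]:
        raise LabelValueError(
            f"{y.shape[0]} labels for {X.shape[0]} samples"
        )
    if not np.isfinite(X).all():
        raise TrainingInputError("training inputs contain non-finite values")

    theta = model.get_params()
    current = model.with_params(theta)
    f = current.forward(X)
    e = y - f
    sse = float(e @ e)
    trace = LmTrace(initial_sse=sse)
    mu = float(config.mu_init)
    n = X.shape[0]

    for _ in range(config.max_iterations):
        J = current.jacobian(X)
        g = J.T @ e  # = -(1/2) grad of SSE
        if np.max(np.abs(g)) < config.gradient_tolerance:
            trace.stop_reason = "gradient_tolerance"
            break
        JtJ = J.T @ J
        accepted = False
        while True:
            A = JtJ + mu * np.eye(JtJ.shape[0])
            try:
                delta = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                mu *= config.mu_up
                if mu > MU_MAX:
                    raise TrainingSingularError(
                        f"normal matrix singular despite damping μ up to "
                        f"{MU_MAX:g} (P={JtJ.shape[0]}, N={n}, SSE={sse:.6g})"
                    ) from None
                continue
            candidate = current.with_params(current.get_params() + delta)
            f_new = candidate.forward(X)
            e_new = y - f_new
            sse_new = float(e_new @ e_new)
            if np.isfinite(sse_new) and sse_new < sse:
                improvement = (sse - sse_new) / n
                current, f, e = candidate, f_new, e_new
                sse = sse_new
                mu = max(mu * config.mu_down, MU_MIN)
                trace.sse.append(sse)
                trace.mu.append(mu)
                trace.accepted.append(True)
                accepted = True
                if improvement < config.min_mse_delta:
                    trace.stop_reason = "min_mse_delta"
                break
            mu *= config.mu_up
            trace.sse.append(sse)
            trace.mu.append(mu)
            trace.accepted.append(False)
            if mu > MU_MAX:
                trace.stop_reason = "mu_out_of_range"
                break
        if trace.stop_reason:
            break
        if not accepted:
            break
    else:
        trace.stop_reason = "max_iterations"
    if not trace.stop_reason:
        trace.stop_reason = "max_iterations"
    return current, trace


def predict(model, data, threshold: float | None = None):
    """Scores in (0, 1) plus hard labels under the strict-> threshold rule.

    Returns ``(scores, labels)``; labels are 1 where score > threshold.
    """
    X = as_matrix(data)
    scores = model.forward(X)
    t = model.threshold if threshold is None else float(threshold)
    return scores, (scores > t).astype(np.int64)
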