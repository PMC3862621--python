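"""Back-propagation neural-network fitting of the temperature-germination
surface, and its projection onto the quintic polynomial basis.

The network is the classic three-layer feed-forward architecture
2 -> hidden -> 1 (sigmoid hidden layer, linear output), trained full-batch
on the sum of squared errors, by default with resilient back-propagation
(Rprop: sign-based per-weight step adaptation), with plain gradient descent
plus momentum available as ``optimizer="gdm"``.
Inputs are the two regime temperatures divided by the design maximum
(40 °C); targets are germination fractions.  After training, the learned
surface is sampled on a regular grid over the cool <= warm triangle and
projected by least squares onto the 21-term degree-5 basis, yielding the
"network-aided quintic equation": a portable polynomial whose shape was
optimized by the network rather than fit directly to the 36 cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .surface import (
    PolynomialSurfaceModel,
    build_basis,
    n_coefficients,
    r_squared,
)

__all__ = [
    "BPANNConfig",
    "BPANNModel",
    "BPANN",
    "BPANNResults",
    "train",
    "network_r2",
    "project_to_quintic",
]


@dataclass(frozen=True)
class BPANNConfig:
    """Training configuration for the back-propagation network.

    Defaults: 10 sigmoid hidden units, 10,000 full-batch epochs, weights
    initialized uniform in ±init_scale, inputs divided by 40 °C, targets as
    fractions in [0, 1].  ``optimizer`` selects the batch trainer:
    ``"rprop"`` (default; per-weight sign-adaptive steps, grows ×1.2 on a
    consistent gradient sign, shrinks ×0.5 on a flip) or ``"gdm"`` (plain
    gradient descent with ``learning_rate`` and ``momentum``).
    """

    hidden_units: int = 10
    optimizer: str = "rprop"
    learning_rate: float = 0.05
    momentum: float = 0.9
    epochs: int = 10000
    seed: int = 42
    input_normalizer: float = 40.0
    target_scale: float = 1.0
    init_scale: float = 0.5
    rprop_step0: float = 0.01
    rprop_step_max: float = 50.0
    rprop_step_min: float = 1e-6

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.optimizer not in ("rprop", "gdm"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class BPANNModel:
    """A trained 2 -> hidden -> 1 feed-forward network."""

    config: BPANNConfig
    w1: np.ndarray  # (2, hidden) input -> hidden weights
    b1: np.ndarray  # (hidden,) hidden biases (thresholds)
    w2: np.ndarray  # (hidden,) hidden -> output weights
    b2: float  # output bias
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def _forward(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.w1 + self.b1) @ self.w2 + self.b2

    def predict(self, cool, warm) -> np.ndarray:
        """Germination fraction (clamped to [0, 1]) at (cool, warm) °C."""
        return np.clip(self.predict_unclamped(cool, warm), 0.0, 1.0)

    def predict_unclamped(self, cool, warm) -> np.ndarray:
        cool = np.asarray(cool, float) / self.config.input_normalizer
        warm = np.asarray(warm, float) / self.config.input_normalizer
        scalar = cool.ndim == 0 and warm.ndim == 0
        X = np.column_stack([np.atleast_1d(cool), np.atleast_1d(warm)])
        y = self._forward(X)
        return y[0] if scalar else y

    def to_dict(self) -> dict:
        return {
            "config": self.config.__dict__.copy(),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": float(self.b2),
            "final_loss": float(self.loss_trace[-1]) if self.loss_trace.size else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BPANNModel":
        return cls(
            config=BPANNConfig(**d["config"]),
            w1=np.asarray(d["w1"], float),
            b1=np.asarray(d["b1"], float),
            w2=np.asarray(d["w2"], float),
            b2=float(d["b2"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "BPANNModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


class BPANN:
    """Network model of a germination matrix; ``fit()`` trains by classic
    back-propagation (full-batch gradient descent + momentum on SSE) and
    returns a :class:`BPANNResults`."""

    def __init__(self, matrix, config: BPANNConfig | None = None, **overrides):
        if config is None:
            config = BPANNConfig(**overrides)
        elif overrides:
            raise TypeError("pass either a config or keyword overrides, not both")
        self.matrix = matrix
        self.config = config
        cool, warm, frac = matrix.arrays()
        self.cool, self.warm = cool, warm
        self.endog = frac * config.target_scale
        self.exog = np.column_stack([cool, warm]) / config.input_normalizer

    def fit(self) -> "BPANNResults":
        cfg = self.config
        X, t = self.exog, self.endog
        if X.shape[0] == 0:
            raise ValueError("empty training matrix")
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_units
        # flat parameter vector: w1 (2h) | b1 (h) | w2 (h) | b2
        params = rng.uniform(-cfg.init_scale, cfg.init_scale, size=4 * h + 1)
        loss_trace = np.empty(cfg.epochs)

        def forward_backward(p):
            w1 = p[: 2 * h].reshape(2, h)
            b1 = p[2 * h: 3 * h]
            w2 = p[3 * h: 4 * h]
            b2 = p[4 * h]
            # forward propagation; overflow on divergence is detected below
            with np.errstate(over="ignore", invalid="ignore"):
                hid = _sigmoid(X @ w1 + b1)  # (n, h)
                err = hid @ w2 + b2 - t
                loss = float(err @ err)
            # backward propagation of the half-SSE gradient
            g_w2 = hid.T @ err
            g_b2 = err.sum()
            delta_hid = np.outer(err, w2) * hid * (1.0 - hid)  # (n, h)
            g_w1 = X.T @ delta_hid
            g_b1 = delta_hid.sum(axis=0)
            grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, [g_b2]])
            return loss, grad

        if cfg.optimizer == "rprop":
            step = np.full_like(params, cfg.rprop_step0)
            prev_grad = np.zeros_like(params)
            for epoch in range(cfg.epochs):
                loss, grad = forward_backward(params)
                loss_trace[epoch] = loss
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss not finite)"
                    )
                sign = np.sign(grad) * np.sign(prev_grad)
                step = np.where(
                    sign > 0, np.minimum(step * 1.2, cfg.rprop_step_max),
                    np.where(sign < 0,
                             np.maximum(step * 0.5, cfg.rprop_step_min), step),
                )
                grad = np.where(sign < 0, 0.0, grad)  # skip update on a flip
                params = params - np.sign(grad) * step
                prev_grad = grad
        else:  # gdm: gradient descent with momentum
            velocity = np.zeros_like(params)
            for epoch in range(cfg.epochs):
                loss, grad = forward_backward(params)
                loss_trace[epoch] = loss
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss not finite); "
                        "try a smaller learning_rate"
                    )
                velocity = cfg.momentum * velocity - cfg.learning_rate * grad
                params = params + velocity

        model = BPANNModel(
            config=cfg,
            w1=params[: 2 * h].reshape(2, h).copy(),
            b1=params[2 * h: 3 * h].copy(),
            w2=params[3 * h: 4 * h].copy(),
            b2=float(params[4 * h]),
            loss_trace=loss_trace,
        )
        return BPANNResults(self, model)


class BPANNResults:
    """Trained-network results: in-sample R², loss trace, predictions, and
    the projection onto the quintic basis."""

    def __init__(self, model: BPANN, network: BPANNModel):
        self.model = model
        self.network = network
        self.loss_trace = network.loss_trace

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.network.predict_unclamped(self.model.cool, self.model.warm)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rsquared(self) -> float:
        return r_squared(self.model.endog, self.fittedvalues)

    def predict(self, cool, warm):
        return self.network.predict(cool, warm)

    def to_quintic(self, grid_density: int = 30) -> PolynomialSurfaceModel:
        surf = project_to_quintic(self.network, grid_density=grid_density)
        surf.cultivar = self.model.matrix.cultivar
        return surf

    def summary(self) -> str:
        cfg = self.network.config
        lines = [
            "BP-ANN fit (2 -> {h} sigmoid -> 1 linear)".format(h=cfg.hidden_units),
            f"  cultivar:      {self.model.matrix.cultivar}",
            f"  optimizer:     {cfg.optimizer}",
            f"  epochs:        {cfg.epochs}",
        ]
        if cfg.optimizer == "gdm":
            lines.append(
                f"  learning rate: {cfg.learning_rate}  momentum: {cfg.momentum}"
            )
        lines += [
            f"  seed:          {cfg.seed}",
            f"  final SSE:     {self.loss_trace[-1]:.6g}",
            f"  network R²:    {self.rsquared:.4f}",
        ]
        return "\n".join(lines)


def train(matrix, config: BPANNConfig | None = None) -> BPANNModel:
    """Train the default network on a germination matrix (deterministic
    given config.seed); returns the trained :class:`BPANNModel`."""
    return BPANN(matrix, config or BPANNConfig()).fit().network


def network_r2(model: BPANNModel, matrix) -> float:
    """In-sample R² of the network's (unclamped) predictions on a matrix."""
    cool, warm, frac = matrix.arrays()
    return r_squared(frac, model.predict_unclamped(cool, warm))


def triangle_grid(grid_density: int, lo: float = 5.0, hi: float = 40.0):
    """Regular grid over the cool <= warm triangle of [lo, hi]² with
    quadrature weights.

    Vertices of a grid_density × grid_density mesh restricted to the
    triangle; each vertex carries a quadrature weight so weighted sums
    approximate uniform integrals over the triangle (cells above the
    diagonal contribute 1/4 per corner; the diagonal half-cells 1/6 per
    vertex).  Without the weights the masked boundary would shift with the
    density and the projection would converge only linearly.
    """
    d = int(grid_density)
    axis = np.linspace(lo, hi, d)
    cool, warm = np.meshgrid(axis, axis, indexing="ij")
    # full-cell indicator on the (d-1)² cells, padded for corner lookups
    ci, cj = np.meshgrid(np.arange(d - 1), np.arange(d - 1), indexing="ij")
    full = (ci < cj).astype(float)
    pad = np.zeros((d + 1, d + 1))
    pad[1:d, 1:d] = full
    weights = 0.25 * (pad[:d, :d] + pad[:d, 1:] + pad[1:, :d] + pad[1:, 1:])
    idx = np.arange(d - 1)
    weights[idx, idx] += 1.0 / 6.0  # diagonal half-cells
    weights[idx + 1, idx + 1] += 1.0 / 6.0
    weights[idx, idx + 1] += 1.0 / 6.0
    keep = weights > 0
    return cool[keep], warm[keep], weights[keep]


def project_to_quintic(model, grid_density: int = 30) -> PolynomialSurfaceModel:
    """Least-squares projection of a learned surface onto the degree-5 basis.

    ``model`` is anything with ``predict_unclamped(cool, warm)`` and a
    ``config.input_normalizer`` (or ``normalizer``) attribute.  The surface
    is sampled on a grid_density × grid_density grid restricted to the
    cool <= warm triangle of [5, 40]², where the training data live.
    """
    if grid_density < 6:
        raise ValueError("grid_density must be >= 6 to support 21 coefficients")
    normalizer = getattr(getattr(model, "config", model), "input_normalizer", None)
    if normalizer is None:
        normalizer = getattr(model, "normalizer", 40.0)
    cool, warm, weights = triangle_grid(grid_density)
    y = np.asarray(model.predict_unclamped(cool, warm), float)
    X = build_basis(cool, warm, degree=5, normalizer=normalizer)
    if np.linalg.matrix_rank(X) < n_coefficients(5):
        raise np.linalg.LinAlgError("degenerate projection grid: rank-deficient basis")
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return PolynomialSurfaceModel(
        degree=5, coefficients=coef, normalizer=float(normalizer),
        orientation="cool_as_t1", backend="bpann_projection",
    )
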