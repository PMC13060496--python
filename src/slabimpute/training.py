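"""Training of the residual slice predictor.

The loss combines (i) the mean absolute error between the min-max
normalized predicted and target slices and (ii) the MAE between their
Sobel gradient magnitudes, weighted by ``grad_loss_weight``.  Triplets
are normalized jointly by the intensity range of their bounding pair
before both the forward pass and the loss, so the network always works
on the unit intensity scale while the linear baseline remains an exact
convex combination.

Optimization uses Adam on minibatches of synthetic slab triplets drawn
from freshly synthesized volumes; convergence is monitored with the MAE
on a frozen, pre-generated validation set, and the parameters with the
best validation MAE are returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .model import ImputationQuery, linear_interpolate, assemble_input
from .nn import UNet, Adam
from .synth import (LabelVolume, SlabTriplet, SynthConfig,
                    generate_synthetic_volume, make_minibatch)

logger = logging.getLogger(__name__)

# standard 3x3 Sobel operators in scipy's correlate orientation:
# derivative along the axis, [1, 2, 1] smoothing across it
_SOBEL_0 = np.outer([-1.0, 0.0, 1.0], [1.0, 2.0, 1.0])
_SOBEL_1 = _SOBEL_0.T


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------


def minmax_normalize(img: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] as (v - min) / (max - min).

    A constant slice has no dynamic range and maps to all zeros (the
    documented degenerate rule).
    """
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def sobel_gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """sqrt(G0^2 + G1^2) with standard 3x3 Sobel kernels, reflected borders."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("expected a 2D slice with dims >= 3")
    g0 = ndimage.sobel(img, axis=0, mode="reflect")
    g1 = ndimage.sobel(img, axis=1, mode="reflect")
    return np.sqrt(g0 * g0 + g1 * g1)


def imputation_loss(y_hat: np.ndarray, y: np.ndarray,
                    grad_loss_weight: float = 1.0, *,
                    normalize: bool = True) -> float:
    """MAE(norm(y_hat), norm(y)) + weight * MAE of Sobel magnitudes.

    Nonnegative, and zero exactly when the normalized slices coincide.
    ``normalize=False`` skips the per-slice min-max step (useful when the
    inputs are already on a common scale).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("shape mismatch between prediction and target")
    if normalize:
        y_hat = minmax_normalize(y_hat)
        y = minmax_normalize(y)
    loss = float(np.mean(np.abs(y_hat - y)))
    if grad_loss_weight:
        gh = sobel_gradient_magnitude(y_hat)
        gt = sobel_gradient_magnitude(y)
        loss += grad_loss_weight * float(np.mean(np.abs(gh - gt)))
    return loss


# -- differentiable internals ---------------------------------------------


def _correlate_batch(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Reflect-padded 'same' correlation of a (B, H, W) stack with a 3x3 kernel."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), mode="symmetric")
    h, w = x.shape[1:]
    out = np.zeros_like(x)
    for i in range(3):
        for j in range(3):
            if kernel[i, j]:
                out += kernel[i, j] * xp[:, i:i + h, j:j + w]
    return out


def _correlate_batch_adjoint(g: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`_correlate_batch`.

    The forward pass reads ``y[x] = sum_k K[k] xp[x + k]``, so the adjoint
    scatter-adds ``g`` back with the *unflipped* kernel, then folds the
    padded-border gradient onto the edges.
    """
    h, w = g.shape[1:]
    gp = np.zeros((g.shape[0], h + 2, w + 2))
    for i in range(3):
        for j in range(3):
            if kernel[i, j]:
                gp[:, i:i + h, j:j + w] += kernel[i, j] * g
    out = gp[:, 1:-1, 1:-1].copy()
    # symmetric padding of width 1 duplicates the edge rows/cols, so the
    # padded-border gradient folds straight back onto the edges
    out[:, 0, :] += gp[:, 0, 1:-1]
    out[:, -1, :] += gp[:, -1, 1:-1]
    out[:, :, 0] += gp[:, 1:-1, 0]
    out[:, :, -1] += gp[:, 1:-1, -1]
    out[:, 0, 0] += gp[:, 0, 0]
    out[:, 0, -1] += gp[:, 0, -1]
    out[:, -1, 0] += gp[:, -1, 0]
    out[:, -1, -1] += gp[:, -1, -1]
    return out


def batch_loss_and_grad(y_hat: np.ndarray, y: np.ndarray,
                        grad_loss_weight: float = 1.0
                        ) -> tuple[float, np.ndarray]:
    """Loss over a (B, H, W) batch of already-normalized slices and dL/dy_hat."""
    diff = y_hat - y
    n = diff.size
    loss = float(np.abs(diff).mean())
    g = np.sign(diff) / n
    if grad_loss_weight:
        g0h = _correlate_batch(y_hat, _SOBEL_0)
        g1h = _correlate_batch(y_hat, _SOBEL_1)
        g0t = _correlate_batch(y, _SOBEL_0)
        g1t = _correlate_batch(y, _SOBEL_1)
        mag_h = np.sqrt(g0h * g0h + g1h * g1h)
        mag_t = np.sqrt(g0t * g0t + g1t * g1t)
        loss += grad_loss_weight * float(np.abs(mag_h - mag_t).mean())
        s = grad_loss_weight * np.sign(mag_h - mag_t) / n
        inv = np.where(mag_h > 0, 1.0 / np.where(mag_h > 0, mag_h, 1.0), 0.0)
        g += _correlate_batch_adjoint(s * g0h * inv, _SOBEL_0)
        g += _correlate_batch_adjoint(s * g1h * inv, _SOBEL_1)
    return loss, g


# ---------------------------------------------------------------------------
# configuration and history
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The defaults mirror the full-scale recipe: Adam at learning rate 1e-6
    on minibatches of 32 triplets, early stopping on the MAE over a
    frozen validation set of 1,000 synthetic slices.  The ``scaled``
    profile is the CPU-sized counterpart used throughout the tests: a
    higher learning rate converges in a few hundred iterations on a
    base-width-8 network.
    """

    learning_rate: float = 1e-6
    batch_size: int = 32
    max_iterations: int = 100_000
    val_size: int = 1000
    val_interval: int = 1000
    patience: int = 10
    min_delta: float = 1e-5
    grad_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning rate and batch size must be positive")
        if self.grad_loss_weight < 0:
            raise ValueError("grad_loss_weight must be nonnegative")

    @classmethod
    def scaled(cls, **overrides) -> "TrainConfig":
        base = dict(learning_rate=3e-4, batch_size=16, max_iterations=300,
                    val_size=100, val_interval=50, seed=0)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainingHistory:
    """Per-iteration training losses and per-checkpoint validation MAEs."""

    train_loss: list[float] = field(default_factory=list)
    val_iterations: list[int] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)

    @property
    def best_val_mae(self) -> float:
        return min(self.val_mae) if self.val_mae else float("nan")

    def to_table(self) -> "object":
        import pandas as pd
        return pd.DataFrame({"iteration": self.val_iterations,
                             "val_mae": self.val_mae})


# ---------------------------------------------------------------------------
# triplet source and tensor assembly
# ---------------------------------------------------------------------------


class SyntheticTripletSource:
    """Streams training minibatches from label volumes.

    Each call synthesizes one fresh domain-randomized volume from a
    randomly chosen label map and cuts the whole minibatch of slab
    triplets out of it (volume-level randomization).
    """

    def __init__(self, label_volumes: list[LabelVolume],
                 synth_config: SynthConfig | None = None):
        if not label_volumes:
            raise ValueError("need at least one label volume")
        self.label_volumes = list(label_volumes)
        self.synth_config = synth_config or SynthConfig()

    def minibatch(self, rng: np.random.Generator,
                  n: int | None = None) -> list[SlabTriplet]:
        cfg = self.synth_config
        vol = self.label_volumes[rng.integers(len(self.label_volumes))]
        img, _ = generate_synthetic_volume(vol, rng, cfg)
        if n is not None and n != cfg.minibatch:
            import dataclasses
            cfg = dataclasses.replace(cfg, minibatch=n)
        return make_minibatch(img, rng, cfg)


def make_validation_set(source: SyntheticTripletSource,
                        rng: np.random.Generator, n_slices: int,
                        batch_per_volume: int = 16) -> list[SlabTriplet]:
    """Pre-generate a frozen validation set of ``n_slices`` triplets."""
    out: list[SlabTriplet] = []
    while len(out) < n_slices:
        out.extend(source.minibatch(rng, min(batch_per_volume,
                                             n_slices - len(out))))
    return out[:n_slices]


def triplet_tensors(triplets: list[SlabTriplet]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack triplets into normalized (input, y_lin, target) training tensors.

    Every triplet is normalized by the min/max over its bounding pair
    (x1, x2); shapes are (B, 4, H, W), (B, H, W), (B, H, W).
    """
    b = len(triplets)
    h, w = triplets[0].x1.shape
    x = np.empty((b, 4, h, w))
    y_lin = np.empty((b, h, w))
    y = np.empty((b, h, w))
    for k, t in enumerate(triplets):
        lo = min(t.x1.min(), t.x2.min())
        hi = max(t.x1.max(), t.x2.max())
        scale = hi - lo if hi > lo else 1.0
        q = ImputationQuery((t.x1 - lo) / scale, (t.x2 - lo) / scale,
                            t.d1, t.d2)
        x[k] = assemble_input(q)
        y_lin[k] = linear_interpolate(q)
        y[k] = (t.y - lo) / scale
    return x, y_lin, y


# ---------------------------------------------------------------------------
# validation and the optimization loop
# ---------------------------------------------------------------------------


def validate(net: UNet, triplets: list[SlabTriplet], *,
             chunk: int = 16) -> float:
    """Mean MAE between per-slice normalized predictions and targets."""
    if not triplets:
        raise ValueError("validation set is empty")
    maes = []
    for start in range(0, len(triplets), chunk):
        part = triplets[start:start + chunk]
        x, y_lin, y = triplet_tensors(part)
        res = np.asarray(net.forward(x), dtype=float)[:, 0]
        y_hat = y_lin + res
        for k in range(len(part)):
            maes.append(float(np.mean(np.abs(minmax_normalize(y_hat[k])
                                             - minmax_normalize(y[k])))))
    return float(np.mean(maes))


def linear_baseline_mae(triplets: list[SlabTriplet]) -> float:
    """Validation MAE of the frozen zero-residual (purely linear) predictor."""
    maes = []
    for t in triplets:
        q = ImputationQuery(t.x1, t.x2, t.d1, t.d2)
        y_lin = linear_interpolate(q)
        maes.append(float(np.mean(np.abs(minmax_normalize(y_lin)
                                         - minmax_normalize(t.y)))))
    return float(np.mean(maes))


def train(source: SyntheticTripletSource, net: UNet,
          config: TrainConfig | None = None,
          validation_triplets: list[SlabTriplet] | None = None
          ) -> tuple[UNet, TrainingHistory]:
    """Optimize the residual predictor; returns the best-validation weights.

    The training stream and, if not supplied, the frozen validation set
    are derived deterministically from ``config.seed``.  Training stops
    at ``max_iterations`` or when the validation MAE has not improved by
    more than ``min_delta`` for ``patience`` consecutive checks.  A
    non-finite loss aborts with a diagnostic error.
    """
    config = config or TrainConfig()
    history = TrainingHistory()
    if config.max_iterations == 0:
        return net, history
    rng = np.random.default_rng(config.seed)
    if validation_triplets is None:
        val_rng = np.random.default_rng((config.seed + 987_654_321) % (2 ** 31))
        validation_triplets = make_validation_set(source, val_rng,
                                                  config.val_size)
    opt = Adam(net, config.learning_rate)
    best_mae = np.inf
    best_state = net.state_dict()
    stale_checks = 0
    for it in range(config.max_iterations):
        batch = source.minibatch(rng, config.batch_size)
        x, y_lin, y = triplet_tensors(batch)
        net.zero_grad()
        res = net.forward(x, train=True)[:, 0]
        y_hat = y_lin + res
        loss, g = batch_loss_and_grad(y_hat, y, config.grad_loss_weight)
        if not np.isfinite(loss):
            logger.error("non-finite loss at iteration %d; aborting. "
                         "|res|max=%g |ylin|max=%g", it,
                         np.abs(res).max(), np.abs(y_lin).max())
            raise FloatingPointError(f"training loss became non-finite at "
                                     f"iteration {it}")
        net.backward(g[:, None])
        opt.step()
        history.train_loss.append(loss)
        last = it == config.max_iterations - 1
        if (it + 1) % config.val_interval == 0 or last:
            mae = validate(net, validation_triplets)
            history.val_iterations.append(it + 1)
            history.val_mae.append(mae)
            logger.info("iter %d: train loss %.5f, val MAE %.5f",
                        it + 1, loss, mae)
            if mae < best_mae - config.min_delta:
                best_mae = mae
                best_state = net.state_dict()
                stale_checks = 0
            else:
                stale_checks += 1
                if stale_checks >= config.patience:
                    logger.info("early stop after %d stale checks", stale_checks)
                    break
    net.load_state_dict(best_state)
    return net, history
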