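"""Minimal NumPy neural-network layer library and the imputation U-Net.

Implements exactly the pieces the residual slice predictor needs — 3x3
convolutions, Group Normalization, Leaky ReLU, 2x2 max-pooling, bilinear
2x upsampling, feature concatenation — each with a hand-written backward
pass, plus the Adam optimizer and a checkpoint format.  Math is
float64 by default (float32 for the training profiles); gradients are
validated against finite differences in the test suite.

Public API uses ``(N, C, H, W)`` activations; internally layers run
channels-first ``(C, N, H, W)`` so each convolution maps onto a single
large contiguous BLAS matmul.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

CHECKPOINT_VERSION = 1


class Conv2d:
    """2D convolution with 'same' zero padding (kernel 3, pad 1) or 1x1."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, *,
                 rng: np.random.Generator, zero_init: bool = False,
                 dtype=np.float64):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        self.pad = ksize // 2
        self.dtype = np.dtype(dtype)
        if zero_init:
            self.W = np.zeros((c_out, c_in, ksize, ksize), dtype=self.dtype)
        else:
            # He initialization, suited to the Leaky ReLU nonlinearity
            fan_in = c_in * ksize * ksize
            self.W = (rng.standard_normal((c_out, c_in, ksize, ksize))
                      * np.sqrt(2.0 / fan_in)).astype(self.dtype)
        self.b = np.zeros(c_out, dtype=self.dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._buf: dict[tuple, np.ndarray] = {}

    def _scratch(self, key: str, shape: tuple) -> np.ndarray:
        """Reusable scratch array; shapes are constant across training steps.

        Zero-filled on (re)allocation only: padded borders stay zero while
        interiors are fully overwritten on every call.
        """
        buf = self._buf.get(key)
        if buf is None or buf.shape != shape:
            buf = np.zeros(shape, dtype=self.dtype)
            self._buf[key] = buf
        return buf

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(C, N, H, W) -> (C*k*k, N*H*W) patch matrix (one BLAS gemm away)."""
        c, n, h, w = x.shape
        if self.ksize == 1:
            return x.reshape(c, n * h * w)
        p = self.pad
        xp = self._scratch("xp", (c, n, h + 2 * p, w + 2 * p))
        xp[:, :, p:p + h, p:p + w] = x
        cols = self._scratch("cols", (c, self.ksize * self.ksize, n, h, w))
        for i in range(self.ksize):
            for j in range(self.ksize):
                cols[:, i * self.ksize + j] = xp[:, :, i:i + h, j:j + w]
        return cols.reshape(c * self.ksize * self.ksize, n * h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        self._cols = self._im2col(x)
        self._nhw = (n, h, w)
        wm = self.W.reshape(self.c_out, -1)
        y = np.matmul(wm, self._cols)  # (c_out, N*H*W)
        return y.reshape(self.c_out, n, h, w) + self.b[:, None, None, None]

    def backward(self, gy: np.ndarray, *, input_grad: bool = True):
        n, h, w = self._nhw
        gym = gy.reshape(self.c_out, n * h * w)
        self.gW += np.matmul(gym, self._cols.T).reshape(self.W.shape)
        self.gb += gy.sum(axis=(1, 2, 3))
        if not input_grad:
            return None
        if self.ksize == 1:
            wm = self.W.reshape(self.c_out, -1)
            return np.matmul(wm.T, gym).reshape(self.c_in, n, h, w)
        # input gradient as a same-pad convolution of gy with the flipped,
        # transposed kernel (avoids materializing the k^2-redundant col grad)
        k = self.ksize
        p = self.pad
        gyp = self._scratch("gyp", (self.c_out, n, h + 2 * p, w + 2 * p))
        gyp[:, :, p:p + h, p:p + w] = gy
        gycols = self._scratch("gycols", (self.c_out, k * k, n, h, w))
        for i in range(k):
            for j in range(k):
                gycols[:, i * k + j] = gyp[:, :, i:i + h, j:j + w]
        wt = np.ascontiguousarray(
            self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)).reshape(self.c_in, -1)
        gx = np.matmul(wt, gycols.reshape(self.c_out * k * k, n * h * w))
        return gx.reshape(self.c_in, n, h, w)


class GroupNorm:
    """Group Normalization with per-channel affine parameters."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5,
                 dtype=np.float64):
        g = min(groups, channels)
        while channels % g:
            g -= 1
        self.channels, self.groups, self.eps = channels, g, eps
        self.dtype = np.dtype(dtype)
        self.gamma = np.ones(channels, dtype=self.dtype)
        self.beta = np.zeros(channels, dtype=self.dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        xg = x.reshape(self.groups, c // self.groups, n, h * w)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        xc = xg - mu
        var = np.einsum("gcnp,gcnp->gn", xc, xc,
                        optimize=True)[:, None, :, None] / (c // self.groups * h * w)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xc *= inv
        xhat = xc.reshape(c, n, h, w)
        self._cache = (xhat, inv)
        return self.gamma[:, None, None, None] * xhat + self.beta[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        c, n, h, w = gy.shape
        cg = c // self.groups
        self.ggamma += (gy * xhat).sum(axis=(1, 2, 3))
        self.gbeta += gy.sum(axis=(1, 2, 3))
        dxhat = (gy * self.gamma[:, None, None, None]) \
            .reshape(self.groups, cg, n, h * w)
        xh = xhat.reshape(self.groups, cg, n, h * w)
        m1 = dxhat.mean(axis=(1, 3), keepdims=True)
        m2 = (dxhat * xh).mean(axis=(1, 3), keepdims=True)
        gx = inv * (dxhat - m1 - xh * m2)
        return gx.reshape(c, n, h, w)


class LeakyReLU:
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.slope * gy)


class MaxPool2:
    """2x2 max pooling with stride 2 over the trailing two (spatial) axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._idx = win.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g4, self._idx[..., None], gy[..., None], axis=-1)
        g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


def _upsample_matrix(n_in: int) -> np.ndarray:
    """1D bilinear 2x upsampling operator (align-corners=False), edge-clamped."""
    u = np.zeros((2 * n_in, n_in))
    for i in range(n_in):
        u[2 * i, i] += 0.75
        u[2 * i, max(i - 1, 0)] += 0.25
        u[2 * i + 1, i] += 0.75
        u[2 * i + 1, min(i + 1, n_in - 1)] += 0.25
    return u


class Upsample2:
    """Separable bilinear 2x upsampling; backward is the exact adjoint."""

    _cache: dict[tuple, np.ndarray] = {}

    def __init__(self, dtype=np.float64):
        self.dtype = np.dtype(dtype)

    def _mat(self, n: int) -> np.ndarray:
        key = (n, self.dtype.str)
        if key not in self._cache:
            self._cache[key] = _upsample_matrix(n).astype(self.dtype)
        return self._cache[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        uh, uw = self._mat(x.shape[2]), self._mat(x.shape[3])
        y = np.tensordot(x, uh, axes=([2], [1])).transpose(0, 1, 3, 2)  # up along H
        y = np.tensordot(y, uw, axes=([3], [1]))                        # up along W
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        uh, uw = self._mat(self._hw[0]), self._mat(self._hw[1])
        g = np.tensordot(gy, uw, axes=([3], [0]))                       # adjoint along W
        g = np.tensordot(g, uh, axes=([2], [0])).transpose(0, 1, 3, 2)  # adjoint along H
        return np.ascontiguousarray(g)


class ConvUnit:
    """One encoder/decoder unit: GroupNorm -> 3x3 conv -> Leaky ReLU.

    The very first unit of the network skips the normalization
    (``normalize=False``): group-normalizing the raw 4-channel input
    would wipe out the constant distance-conditioning planes (a
    zero-variance channel normalizes to zero), leaving the predictor
    blind to d1 and d2.
    """

    def __init__(self, c_in: int, c_out: int, *, groups: int, slope: float,
                 rng: np.random.Generator, dtype=np.float64,
                 normalize: bool = True):
        self.gn = GroupNorm(c_in, groups, dtype=dtype) if normalize else None
        self.conv = Conv2d(c_in, c_out, 3, rng=rng, dtype=dtype)
        self.act = LeakyReLU(slope)

    def forward(self, x):
        if self.gn is not None:
            x = self.gn.forward(x)
        return self.act.forward(self.conv.forward(x))

    def backward(self, gy, *, input_grad: bool = True):
        g = self.conv.backward(self.act.backward(gy),
                               input_grad=input_grad or self.gn is not None)
        if g is None or self.gn is None:
            return g if input_grad else None
        return self.gn.backward(g)


@dataclass
class UNetConfig:
    """Architecture hyperparameters of the residual predictor.

    The defaults follow the published architecture: four resolution levels,
    base width 64, hence a 64/128/256/512 encoder schedule and a
    1024-channel bottleneck.  ``base_channels`` is exposed so tests and
    CPU-scale experiments can shrink the network (base 8 -> 128-channel
    bottleneck) without changing its shape contract.
    """

    in_channels: int = 4
    base_channels: int = 64
    depth: int = 4
    groups: int = 8
    negative_slope: float = 0.01
    dtype: str = "float64"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class UNet:
    """2D U-Net mapping a 4-channel (x1, x2, d1, d2) stack to a 1-channel residual.

    Encoder stages halve resolution (2x2 max-pool) and double channels;
    the decoder mirrors them with bilinear upsampling and concatenated
    skip connections; a final 1x1 convolution (zero-initialized, no
    activation) produces the residual, which may be negative.
    """

    def __init__(self, config: UNetConfig | None = None, *, seed: int = 0):
        self.config = config or UNetConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        dt = np.dtype(cfg.dtype)
        self.dtype = dt
        mk = lambda ci, co, **kw: ConvUnit(ci, co, groups=cfg.groups,
                                           slope=cfg.negative_slope, rng=rng,
                                           dtype=dt, **kw)
        self.enc_widths = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.bottleneck_width = cfg.base_channels * 2 ** cfg.depth

        self.enc = []
        c = cfg.in_channels
        for i, w in enumerate(self.enc_widths):
            self.enc.append([mk(c, w, normalize=i > 0), mk(w, w)])
            c = w
        self.pools = [MaxPool2() for _ in self.enc_widths]
        self.bottleneck = [mk(c, self.bottleneck_width),
                           mk(self.bottleneck_width, self.bottleneck_width)]
        self.ups = [Upsample2(dt) for _ in self.enc_widths]
        self.dec = []
        c = self.bottleneck_width
        for w in reversed(self.enc_widths):
            self.dec.append([mk(w + c, w), mk(w, w)])
            c = w
        self.head = Conv2d(c, 1, 1, rng=rng, zero_init=True, dtype=dt)
        self._pad = None

    # -- parameter bookkeeping -------------------------------------------------

    def named_parameters(self) -> dict[str, tuple[object, str]]:
        """Ordered mapping name -> (owner object, attribute name)."""
        out: dict[str, tuple[object, str]] = {}

        def unit(prefix, u: ConvUnit):
            if u.gn is not None:
                out[f"{prefix}.gn.gamma"] = (u.gn, "gamma")
                out[f"{prefix}.gn.beta"] = (u.gn, "beta")
            out[f"{prefix}.conv.W"] = (u.conv, "W")
            out[f"{prefix}.conv.b"] = (u.conv, "b")

        for i, blk in enumerate(self.enc):
            for j, u in enumerate(blk):
                unit(f"enc{i}.u{j}", u)
        for j, u in enumerate(self.bottleneck):
            unit(f"bottleneck.u{j}", u)
        for i, blk in enumerate(self.dec):
            for j, u in enumerate(blk):
                unit(f"dec{i}.u{j}", u)
        out["head.W"] = (self.head, "W")
        out["head.b"] = (self.head, "b")
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(o, a).copy() for k, (o, a) in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named_parameters()
        missing = set(named) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:3]} ...")
        for k, (o, a) in named.items():
            cur = getattr(o, a)
            if cur.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {cur.shape} vs {state[k].shape}")
            setattr(o, a, np.array(state[k], dtype=self.dtype))

    def zero_grad(self) -> None:
        for _, (o, a) in self.named_parameters().items():
            getattr(o, "g" + a)[...] = 0.0

    def gradients(self) -> dict[str, np.ndarray]:
        return {k: getattr(o, "g" + a) for k, (o, a) in self.named_parameters().items()}

    def zero_head(self) -> "UNet":
        """Zero the output projection so the network computes S == 0."""
        self.head.W[...] = 0.0
        self.head.b[...] = 0.0
        return self

    # -- forward / backward ----------------------------------------------------

    def _pad_to_grid(self, x: np.ndarray) -> np.ndarray:
        mult = 2 ** self.config.depth
        h, w = x.shape[2], x.shape[3]
        ph, pw = (-h) % mult, (-w) % mult
        self._pad = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="symmetric")
        return x

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        """Predict the residual map; shape (N, 4, H, W) -> (N, 1, H, W).

        Shapes not divisible by ``2**depth`` are symmetric-padded and the
        output cropped back; that path does not support ``backward``.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, {self.config.in_channels}, H, W) input")
        orig_hw = x.shape[2:]
        x = self._pad_to_grid(x)
        if train and (self._pad[0] or self._pad[1]):
            raise ValueError("training requires spatial dims divisible by "
                             f"{2 ** self.config.depth}")
        skips = []
        h = np.ascontiguousarray(x.transpose(1, 0, 2, 3))  # to (C, N, H, W)
        for blk, pool in zip(self.enc, self.pools):
            for u in blk:
                h = u.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for u in self.bottleneck:
            h = u.forward(h)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[0])
            h = np.concatenate([skip, h], axis=0)
            for u in blk:
                h = u.forward(h)
        y = self.head.forward(h)
        y = np.ascontiguousarray(y.transpose(1, 0, 2, 3))  # back to (N, 1, H, W)
        if self._pad[0] or self._pad[1]:
            y = y[:, :, :orig_hw[0], :orig_hw[1]]
        return y

    def backward(self, gy: np.ndarray, *, input_grad: bool = False):
        """Backpropagate through the most recent training forward pass.

        Parameter gradients accumulate in the layers; the gradient with
        respect to the input is only materialized when ``input_grad`` is
        set (training never needs it).
        """
        if self._pad is None:
            raise RuntimeError("backward before forward")
        if self._pad[0] or self._pad[1]:
            raise RuntimeError("backward unsupported through the padding path")
        gy = np.ascontiguousarray(np.asarray(gy, dtype=self.dtype).transpose(1, 0, 2, 3))
        g = self.head.backward(gy)
        gskips = []
        for up, blk, cs in zip(reversed(self.ups), reversed(self.dec),
                               reversed(self._skip_channels)):
            for u in reversed(blk):
                g = u.backward(g)
            gskip, g = g[:cs], g[cs:]
            gskips.append(gskip)
            g = up.backward(g)
        for u in reversed(self.bottleneck):
            g = u.backward(g)
        first_unit = self.enc[0][0]
        for blk, pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(gskips)):
            g = pool.backward(g)
            g = g + gskip
            for u in reversed(blk):
                g = u.backward(g, input_grad=input_grad or u is not first_unit)
                if g is None:
                    return None
        return np.ascontiguousarray(g.transpose(1, 0, 2, 3))


class Adam:
    """Adam optimizer over a UNet's parameter set."""

    def __init__(self, net: UNet, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr = net, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(o, a))
                  for k, (o, a) in net.named_parameters().items()}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self) -> None:
        self.t += 1
        grads = self.net.gradients()
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, (o, a) in self.net.named_parameters().items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mh = self.m[k] / b1t
            vh = self.v[k] / b2t
            getattr(o, a)[...] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# -- checkpoints ----------------------------------------------------------------


def save_checkpoint(path, net: UNet, *, train_config_hash: str = "") -> None:
    """Write parameters + architecture metadata to a single ``.npz`` archive."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "architecture": net.config.to_dict(),
        "train_config_hash": train_config_hash,
    }
    arrays = {"param//" + k: v for k, v in net.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> UNet:
    """Rebuild a UNet from a checkpoint; forward outputs are bit-identical."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')!r}")
        net = UNet(UNetConfig(**meta["architecture"]))
        state = {k[len("param//"):]: data[k] for k in data.files if k.startswith("param//")}
    net.load_state_dict(state)
    return net
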