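"""3D U-Net de-aliasing of complex radial cine images.

The network consumes a single-channel real tensor built by concatenating the
real and imaginary parts of an ``n x n x n_t`` complex cine along the first
spatial axis (``2n x n x n_t``) and returns a tensor of the same shape with
streaking suppressed; the two halves are recombined into a complex cine.

Architecture: encoder ``E_H - E_2H - E_4H`` (the last stage without
maxpool), decoder ``D_2H - D_H``, final 1x1x1 single-channel convolution.
Each ``C_H`` unit is convolution (3x3x3, stride 1, padding 1, bias) ->
batch normalization -> dropout(0.15) -> ReLU; each ``E_H`` is two ``C_H``
units followed by 2x2x2/stride-2 max pooling; each ``D_H`` is a 2x2x2
stride-2 transposed convolution whose output is channel-concatenated with
the matching pre-maxpool encoder output, followed by two ``C_H`` units.

Everything — forward pass, backpropagation, Adam — is implemented on NumPy
arrays (float32, im2col convolutions executed as BLAS matrix products), so
training and inference run on any CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from radcine.synthsim import TrainingPair, norm_constant_of


# ---------------------------------------------------------------------------
# complex <-> plane representation
# ---------------------------------------------------------------------------

def complex_to_plane(cine: np.ndarray) -> np.ndarray:
    """Stack real over imaginary parts along the first axis: (n,n,nt) -> (2n,n,nt)."""
    cine = np.asarray(cine)
    return np.concatenate([cine.real, cine.imag], axis=0).astype(np.float32)


def plane_to_complex(plane: np.ndarray) -> np.ndarray:
    """Inverse of :func:`complex_to_plane`; exact."""
    m = plane.shape[0]
    if m % 2 != 0:
        raise ValueError(f"first extent must be even, got {m}")
    h = m // 2
    return plane[:h].astype(np.float64) + 1j * plane[h:].astype(np.float64)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class UNetConfig:
    """Width and regularization of the fixed-depth U-Net.

    ``base_channels`` (H) sets the width of the first encoder stage; the
    conventional default is 64, but all numerical behavior is
    width-independent and small widths (4-8) train in seconds on a CPU.
    """

    base_channels: int = 64
    dropout_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization schedule: Adam, MSE, step-decayed learning rate."""

    batch_size: int = 16
    iterations: int = 2900
    lr0: float = 0.001
    lr_decay: float = 0.95  # multiplicative, applied every `decay_every` iterations
    decay_every: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.iterations, self.decay_every) < 1:
            raise ValueError("batch_size, iterations, decay_every must be positive")
        if self.lr0 <= 0 or not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("need lr0 > 0 and lr_decay in (0, 1]")


def learning_rate(iteration: int, cfg: TrainConfig | None = None) -> float:
    """Step-decay schedule: ``lr0 * decay ** floor(i / decay_every)``.

    Defaults reproduce the published schedule: 0.001 reduced by 5% every
    100 iterations.
    """
    if cfg is None:
        cfg = TrainConfig()
    return cfg.lr0 * cfg.lr_decay ** (iteration // cfg.decay_every)


# ---------------------------------------------------------------------------
# layers (float32 tensors shaped (N, C, D, H, W))
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal trainable unit: named params/grads plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}  # non-trainable (BN running stats)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col3(x: np.ndarray) -> np.ndarray:
    # x (N,C,D,H,W) -> columns (C*27, N*D*H*W); row order (channel, tap)
    n, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((c * 27, n * d * h * w), dtype=np.float32)
    i = 0
    for ci in range(c):
        for a in range(3):
            for b in range(3):
                for cc in range(3):
                    cols[i] = xp[:, ci, a : a + d, b : b + h, cc : cc + w].ravel()
                    i += 1
    return cols


def _conv3_from_cols(cols: np.ndarray, w_mat: np.ndarray, shape) -> np.ndarray:
    # cols (C*27, N*DHW), w_mat (Cout, C*27); returns (N, Cout, D, H, W)
    n, d, h, w = shape
    y = w_mat @ cols  # (Cout, N*DHW)
    return np.ascontiguousarray(np.moveaxis(y.reshape(-1, n, d, h, w), 0, 1))


class Conv3(_Layer):
    """3x3x3 convolution, stride 1, zero padding 1, with bias.

    Executed as one BLAS matrix product over im2col columns; the columns
    are cached between forward and backward for the weight gradient.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (27 * c_in))
        self.params["W"] = rng.standard_normal((c_out, c_in, 3, 3, 3)).astype(
            np.float32
        ) * np.float32(std)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, training):
        w = self.params["W"]
        self._shape = (x.shape[0],) + x.shape[2:]
        cols = _im2col3(x)
        self._cols = cols if training else None
        y = _conv3_from_cols(cols, w.reshape(w.shape[0], -1), self._shape)
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        w = self.params["W"]
        co = w.shape[0]
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        dy2 = np.moveaxis(dy, 1, 0).reshape(co, -1)  # (Cout, N*DHW)
        self.grads["W"] = (dy2 @ self._cols.T).reshape(w.shape)
        self._cols = None
        # gradient w.r.t. input: same-size convolution with the flipped,
        # channel-transposed kernel
        wb = w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        return _conv3_from_cols(
            _im2col3(dy),
            np.ascontiguousarray(wb).reshape(wb.shape[0], -1),
            self._shape,
        )


class BatchNorm(_Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.state["running_mean"] = np.zeros(channels, dtype=np.float32)
        self.state["running_var"] = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        sh = (1, -1, 1, 1, 1)
        if training:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.state["running_mean"] += self.momentum * (
                mean - self.state["running_mean"]
            )
            self.state["running_var"] += self.momentum * (
                var - self.state["running_var"]
            )
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
            self._xhat, self._inv = xhat, inv
        else:
            inv = 1.0 / np.sqrt(self.state["running_var"] + self.eps)
            xhat = (x - self.state["running_mean"].reshape(sh)) * inv.reshape(sh)
        return self.params["gamma"].reshape(sh) * xhat + self.params["beta"].reshape(sh)

    def backward(self, dy):
        sh = (1, -1, 1, 1, 1)
        xhat, inv = self._xhat, self._inv
        m = dy.size / dy.shape[1]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3, 4))
        dbeta = dy.sum(axis=(0, 2, 3, 4))
        self.grads["gamma"], self.grads["beta"] = dgamma, dbeta
        g = self.params["gamma"] * inv
        dx = g.reshape(sh) * (
            dy - (dbeta / m).reshape(sh) - xhat * (dgamma / m).reshape(sh)
        )
        del self._xhat, self._inv
        return dx.astype(np.float32)


class Dropout(_Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = (
            self.rng.random(x.shape, dtype=np.float32) >= self.rate
        ).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class ReLU(_Layer):
    def forward(self, x, training):
        self._pos = x > 0
        return np.where(self._pos, x, np.float32(0.0))

    def backward(self, dy):
        return np.where(self._pos, dy, np.float32(0.0))


class MaxPool(_Layer):
    """2x2x2 max pooling with stride 2 (extents must be even)."""

    def forward(self, x, training):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"extents must be even for 2x2x2 pooling, got {x.shape}")
        blocks = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8
        )
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dy):
        n, c, d, h, w = self._shape
        out = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        out = out.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        return out


class ConvT2(_Layer):
    """2x2x2 transposed convolution with stride 2 and bias (non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (8 * c_in))
        self.params["W"] = rng.standard_normal((c_in, c_out, 2, 2, 2)).astype(
            np.float32
        ) * np.float32(std)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, training):
        self._x = x
        n, c, d, h, w = x.shape
        t = np.tensordot(x, self.params["W"], axes=([1], [0]))
        # (N,D,H,W,Cout,2,2,2) -> (N,Cout,2D,2H,2W)
        t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
            n, -1, 2 * d, 2 * h, 2 * w
        )
        return t + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        x = self._x
        n, c, d, h, w = x.shape
        co = dy.shape[1]
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        dyb = dy.reshape(n, co, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        self.grads["W"] = np.tensordot(
            x, dyb, axes=([0, 2, 3, 4], [0, 1, 2, 3])
        )
        dx = np.tensordot(dyb, self.params["W"], axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        del self._x
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))


class Conv1(_Layer):
    """1x1x1 convolution with bias, no activation (the output head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(1.0 / c_in)
        self.params["W"] = rng.standard_normal((c_out, c_in)).astype(
            np.float32
        ) * np.float32(std)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, training):
        self._x = x
        y = np.tensordot(self.params["W"], x, axes=([1], [1]))
        y = y.transpose(1, 0, 2, 3, 4)
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        x = self._x
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        self.grads["W"] = np.tensordot(dy, x, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        dx = np.tensordot(self.params["W"].T, dy, axes=([1], [1])).transpose(
            1, 0, 2, 3, 4
        )
        del self._x
        return np.ascontiguousarray(dx)


class _CBlock:
    """C_H unit: conv -> batch-norm -> dropout -> ReLU (in that order)."""

    def __init__(self, c_in, c_out, dropout_rate, init_rng, drop_rng):
        self.layers = [
            Conv3(c_in, c_out, init_rng),
            BatchNorm(c_out),
            Dropout(dropout_rate, drop_rng),
            ReLU(),
        ]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# the U-Net
# ---------------------------------------------------------------------------

class UNet3D:
    """Fixed-depth 3D U-Net: E_H - E_2H - E_4H - D_2H - D_H - 1x1x1 head.

    Input and output are single-channel tensors whose three extents must
    each be divisible by 4 (two 2x pooling stages).
    """

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        h = config.base_channels
        p = config.dropout_rate
        init = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)

        def cb(ci, co):
            return _CBlock(ci, co, p, init, self.drop_rng)

        self.enc1 = [cb(1, h), cb(h, h)]
        self.pool1 = MaxPool()
        self.enc2 = [cb(h, 2 * h), cb(2 * h, 2 * h)]
        self.pool2 = MaxPool()
        self.enc3 = [cb(2 * h, 4 * h), cb(4 * h, 4 * h)]
        self.up2 = ConvT2(4 * h, 2 * h, init)
        self.dec2 = [cb(4 * h, 2 * h), cb(2 * h, 2 * h)]
        self.up1 = ConvT2(2 * h, h, init)
        self.dec1 = [cb(2 * h, h), cb(h, h)]
        self.head = Conv1(h, 1, init)

    # -- plumbing ----------------------------------------------------------
    def _blocks(self):
        for group in (self.enc1, self.enc2, self.enc3, self.dec2, self.dec1):
            for block in group:
                yield from block.layers
        yield self.up2
        yield self.up1
        yield self.head

    def parameters(self):
        """Ordered (layer, name) pairs of all trainable parameters."""
        for i, layer in enumerate(self._blocks()):
            for name in layer.params:
                yield i, layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for _, layer, name in self.parameters())

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, D, H, W), got {x.shape}")
        if any(e % 4 for e in x.shape[2:]):
            raise ValueError(
                f"spatial-temporal extents must be divisible by 4, got {x.shape[2:]}"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)
        for b in self.enc1:
            x = b.forward(x, training)
        s1 = x
        x = self.pool1.forward(x, training)
        for b in self.enc2:
            x = b.forward(x, training)
        s2 = x
        x = self.pool2.forward(x, training)
        for b in self.enc3:
            x = b.forward(x, training)
        x = self.up2.forward(x, training)
        x = np.concatenate([x, s2], axis=1)
        for b in self.dec2:
            x = b.forward(x, training)
        x = self.up1.forward(x, training)
        x = np.concatenate([x, s1], axis=1)
        for b in self.dec1:
            x = b.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dy: np.ndarray) -> None:
        h = self.config.base_channels
        dy = self.head.backward(dy)
        for b in reversed(self.dec1):
            dy = b.backward(dy)
        du1, ds1 = dy[:, :h], dy[:, h:]
        dy = self.up1.backward(du1)
        for b in reversed(self.dec2):
            dy = b.backward(dy)
        du2, ds2 = dy[:, : 2 * h], dy[:, 2 * h :]
        dy = self.up2.backward(du2)
        for b in reversed(self.enc3):
            dy = b.backward(dy)
        dy = self.pool2.backward(dy)
        dy = dy + ds2
        for b in reversed(self.enc2):
            dy = b.backward(dy)
        dy = self.pool1.backward(dy)
        dy = dy + ds1
        for b in reversed(self.enc1):
            dy = b.backward(dy)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet3D:
    """Construct the de-aliasing U-Net with reproducible initialization."""
    return UNet3D(config, seed=seed)


def count_parameters(h: int) -> int:
    """Closed-form trainable parameter count for base width ``h``.

    Per layer: conv 27*Cin*Cout + Cout (+ 2*Cout batch-norm), transposed
    conv 8*Cin*Cout + Cout, head Cin + 1.
    """

    def conv_bn(ci, co):
        return 27 * ci * co + co + 2 * co

    total = conv_bn(1, h) + conv_bn(h, h)  # E_H
    total += conv_bn(h, 2 * h) + conv_bn(2 * h, 2 * h)  # E_2H
    total += conv_bn(2 * h, 4 * h) + conv_bn(4 * h, 4 * h)  # E_4H
    total += 8 * 4 * h * 2 * h + 2 * h  # up 4H -> 2H
    total += conv_bn(4 * h, 2 * h) + conv_bn(2 * h, 2 * h)  # D_2H
    total += 8 * 2 * h * h + h  # up 2H -> H
    total += conv_bn(2 * h, h) + conv_bn(h, h)  # D_H
    total += h + 1  # head
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer over a U-Net's parameters."""

    def __init__(self, net: UNet3D, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, layer, name in self.net.parameters():
            g = layer.grads[name].astype(np.float32)
            key = (i, name)
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / bias1
            vhat = self.v[key] / bias2
            layer.params[name] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )


def train_unet(
    dataset: list[TrainingPair],
    unet_cfg: UNetConfig,
    train_cfg: TrainConfig,
) -> tuple[UNet3D, list[tuple[int, float, float]]]:
    """Train the U-Net on plane-representation MSE with Adam.

    Each iteration assembles a batch from ``batch_size`` distinct sources
    (one pair per source, sampled without replacement) and takes one Adam
    step at the step-decayed learning rate.  Returns the trained network
    and a per-iteration trace of ``(iteration, lr, loss)``.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    if len(dataset) < train_cfg.batch_size:
        raise ValueError(
            f"batch size {train_cfg.batch_size} exceeds the {len(dataset)} "
            "available sources (batches draw distinct sources)"
        )
    inputs = np.stack([complex_to_plane(p.input) for p in dataset])[:, None]
    targets = np.stack([complex_to_plane(p.target) for p in dataset])[:, None]
    net = build_unet(unet_cfg, seed=train_cfg.seed)
    opt = Adam(net)
    batch_rng = np.random.default_rng(train_cfg.seed + 2)
    trace: list[tuple[int, float, float]] = []
    for it in range(train_cfg.iterations):
        idx = batch_rng.choice(len(dataset), size=train_cfg.batch_size, replace=False)
        x, y = inputs[idx], targets[idx]
        pred = net.forward(x, training=True)
        resid = pred - y
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        net.backward((2.0 / resid.size) * resid)
        lr = learning_rate(it, train_cfg)
        opt.step(lr)
        trace.append((it, lr, loss))
    return net, trace


def write_training_log(path: str, trace: list[tuple[int, float, float]]) -> None:
    """Training trace as CSV (iteration, lr, loss)."""
    with open(path, "w") as fh:
        fh.write("iteration,lr,loss\n")
        for it, lr, loss in trace:
            fh.write(f"{it},{lr:.8g},{loss:.8g}\n")


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _pad_to_multiple(cine: np.ndarray, multiple: int = 4):
    pads = []
    for e in cine.shape:
        rem = (-e) % multiple
        pads.append((rem // 2, rem - rem // 2))
    return np.pad(cine, pads), pads


def dealias(input_cine: np.ndarray, net: UNet3D) -> np.ndarray:
    """De-alias a complex cine with a trained network.

    Normalizes by the central-region 95th-percentile rule, pads each extent
    symmetrically to a multiple of 4 if needed, runs the network in
    inference mode (dropout off, batch-norm running statistics), recombines
    the plane output into a complex cine and restores the original scale.
    """
    cine = np.asarray(input_cine)
    if cine.ndim != 3:
        raise ValueError(f"expected (n, n, n_t) complex cine, got {cine.shape}")
    c = norm_constant_of(cine)
    if not c > 0:
        raise ValueError("zero-signal input cannot be normalized")
    padded, pads = _pad_to_multiple(cine / c)
    plane = complex_to_plane(padded)
    out = net.forward(plane[None, None], training=False)[0, 0]
    result = plane_to_complex(out)
    sl = tuple(slice(lo, result.shape[i] - hi) for i, (lo, hi) in enumerate(pads))
    return result[sl] * c


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, net: UNet3D, extra: dict | None = None) -> None:
    """Persist weights, batch-norm statistics and the network config (npz)."""
    arrays = {}
    for i, layer in enumerate(net._blocks()):
        for name, val in layer.params.items():
            arrays[f"p:{i}:{name}"] = val
        for name, val in layer.state.items():
            arrays[f"s:{i}:{name}"] = val
    meta = {
        "base_channels": net.config.base_channels,
        "dropout_rate": net.config.dropout_rate,
        "extra": extra or {},
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[UNet3D, dict]:
    """Rebuild a network from a checkpoint; returns (net, extra-metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        net = UNet3D(
            UNetConfig(
                base_channels=meta["base_channels"],
                dropout_rate=meta["dropout_rate"],
            )
        )
        layers = list(net._blocks())
        for key in data.files:
            if key == "meta":
                continue
            kind, idx, name = key.split(":")
            layer = layers[int(idx)]
            if kind == "p":
                layer.params[name] = data[key]
            else:
                layer.state[name] = data[key]
    return net, meta["extra"]
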