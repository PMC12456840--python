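"""Minimal numpy neural-network layers with explicit backward passes.

Implements exactly what the shim-weight regressor and the non-uniformity
detector need: 2-D convolution (im2col), batch normalization, (leaky) ReLU,
residual basic blocks, global average pooling, a fully connected head, and
an Adam optimizer.  Everything is float32, NCHW layout, and deterministic
given the initialization seed — forward and backward are plain numpy, so
two identical runs are bit-identical.

Layers cache what their backward pass needs during ``forward(..., train=True)``;
``backward`` consumes the upstream gradient and accumulates parameter
gradients into ``Param.g``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Linear",
    "GlobalAvgPool",
    "Sequential",
    "BasicBlock",
    "Adam",
    "state_dict",
    "load_state_dict",
]

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=DTYPE)
        self.g = np.zeros_like(self.v)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, Ho: int, Wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, k, k, Ho, Wo) view-copies per kernel offset."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k, k, Ho, Wo), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[
                :, :, ki : ki + stride * Ho : stride, kj : kj + stride * Wo : stride
            ]
    return cols


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = cin * k * k
        self.W = Param(rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        N, C, H, Wd = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (Wd + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, Ho, Wo)
        flat = cols.reshape(N, C * k * k, Ho * Wo)
        out = np.einsum("of,nfl->nol", self.W.v, flat, optimize=True)
        if self.b is not None:
            out += self.b.v[None, :, None]
        if train:
            self._cache = (flat, x.shape, Ho, Wo)
        return out.reshape(N, self.cout, Ho, Wo)

    def backward(self, dy):
        flat, xshape, Ho, Wo = self._cache
        N, C, H, Wd = xshape
        p, k, s = self.pad, self.k, self.stride
        dyf = dy.reshape(N, self.cout, Ho * Wo)
        self.W.g += np.einsum("nol,nfl->of", dyf, flat, optimize=True)
        if self.b is not None:
            self.b.g += dyf.sum(axis=(0, 2))
        dflat = np.einsum("of,nol->nfl", self.W.v, dyf, optimize=True)
        dcols = dflat.reshape(N, C, k, k, Ho, Wo)
        dxp = np.zeros((N, C, H + 2 * p, Wd + 2 * p), dtype=dy.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += dcols[:, :, ki, kj]
        return dxp[:, :, p : p + H, p : p + Wd] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._calibrating = False

    def params(self):
        return [self.gamma, self.beta]

    def begin_calibration(self):
        self._calibrating = True
        self._cal = [0.0, 0.0, 0.0]  # weight, sum of means, sum of (var + mean^2)

    def end_calibration(self):
        w, sm, sv = self._cal
        if w > 0:
            mean = sm / w
            self.running_mean = np.asarray(mean, dtype=DTYPE)
            self.running_var = np.asarray(sv / w - mean**2, dtype=DTYPE)
        self._calibrating = False

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._calibrating:
                n = x.shape[0] * x.shape[2] * x.shape[3]
                self._cal[0] += n
                self._cal[1] += n * mean
                self._cal[2] += n * (var + mean**2)
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mean).astype(DTYPE)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        N = shape[0] * shape[2] * shape[3]
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.v[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (dxhat - t1 / N - xhat * t2 / N)


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        out = np.where(x > 0, x, self.slope * x)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / cin)
        self.W = Param(rng.uniform(-bound, bound, (cout, cin)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.v.T + self.b.v

    def backward(self, dy):
        self.W.g += dy.T @ self._x
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) mean over the spatial extent."""

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape).copy() / (H * W)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class BasicBlock(Layer):
    """Two 3x3 conv/BN/ReLU layers with a residual skip; stride-2 entry
    blocks project the identity path with a 1x1 convolution."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.proj: Sequential | None = Sequential(
                Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng, bias=False),
                BatchNorm2d(cout),
            )
        else:
            self.proj = None

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x, train=True):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.relu2.forward(h + skip, train)

    def backward(self, dy):
        dy = self.relu2.backward(dy)
        dskip = dy if self.proj is None else self.proj.backward(dy)
        dh = self.bn2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        return dx + dskip


def collect_bn(layer: Layer) -> list[BatchNorm2d]:
    """All batch-norm layers of a model, in forward order."""
    out: list[BatchNorm2d] = []
    if isinstance(layer, BatchNorm2d):
        out.append(layer)
    elif isinstance(layer, Sequential):
        for l in layer.layers:
            out.extend(collect_bn(l))
    elif isinstance(layer, BasicBlock):
        for name in ("bn1", "bn2"):
            out.append(getattr(layer, name))
        if layer.proj is not None:
            out.extend(collect_bn(layer.proj))
    return out


def recalibrate_bn(model: Layer, batches) -> None:
    """Replace batch-norm running statistics with exact population
    statistics computed over the given batches.

    Momentum-averaged running statistics lag the feature distribution while
    it still drifts during training, which makes eval-mode inference (and
    any checkpoint selection based on it) erratic; a calibration pass fixes
    the statistics to those of the data actually seen.
    """
    bns = collect_bn(model)
    if not bns:
        return
    for bn in bns:
        bn.begin_calibration()
    for x in batches:
        model.forward(x, train=True)
    for bn in bns:
        bn.end_calibration()


class Adam:
    """Adam update rule over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            v[...] = self.b2 * v + (1 - self.b2) * p.g * p.g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.v -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _walk(layer: Layer, prefix: str, out: dict) -> None:
    if isinstance(layer, Conv2d):
        out[prefix + "W"] = layer.W
        if layer.b is not None:
            out[prefix + "b"] = layer.b
    elif isinstance(layer, Linear):
        out[prefix + "W"] = layer.W
        out[prefix + "b"] = layer.b
    elif isinstance(layer, BatchNorm2d):
        out[prefix + "gamma"] = layer.gamma
        out[prefix + "beta"] = layer.beta
        out[prefix + "running_mean"] = layer
        out[prefix + "running_var"] = layer
    elif isinstance(layer, Sequential):
        for i, l in enumerate(layer.layers):
            _walk(l, f"{prefix}{i}.", out)
    elif isinstance(layer, BasicBlock):
        for name in ("conv1", "bn1", "conv2", "bn2"):
            _walk(getattr(layer, name), f"{prefix}{name}.", out)
        if layer.proj is not None:
            _walk(layer.proj, f"{prefix}proj.", out)


def state_dict(model: Layer) -> dict[str, np.ndarray]:
    """Flat name → array mapping of all parameters and batch-norm statistics."""
    entries: dict = {}
    _walk(model, "", entries)
    out = {}
    for name, obj in entries.items():
        if isinstance(obj, Param):
            out[name] = obj.v.copy()
        elif name.endswith("running_mean"):
            out[name] = obj.running_mean.copy()
        else:
            out[name] = obj.running_var.copy()
    return out


def load_state_dict(model: Layer, state: dict[str, np.ndarray]) -> None:
    entries: dict = {}
    _walk(model, "", entries)
    if set(entries) != set(state):
        missing = set(entries) ^ set(state)
        raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
    for name, obj in entries.items():
        arr = np.asarray(state[name], dtype=DTYPE)
        if isinstance(obj, Param):
            if obj.v.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            obj.v = arr.copy()
            obj.g = np.zeros_like(obj.v)
        elif name.endswith("running_mean"):
            obj.running_mean = arr.copy()
        else:
            obj.running_var = arr.copy()
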