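"""Minimal numpy neural-network engine with hand-written backpropagation.

Implements exactly the layers the classifier needs — 3D convolution,
batch normalisation, ReLU, max/average pooling, linear layers — plus
softmax cross-entropy loss and SGD with momentum.  Every layer caches
what its backward pass needs during ``forward``; composite modules chain
``bprop`` in reverse order.  Gradient correctness is pinned down by
finite-difference tests rather than by construction, so keep forward and
backward of any layer in sync when editing.

Convolutions use a chunked im2col (sliding-window view + GEMM) so a
full-scale forward pass (116 input channels on a 61x73x61 grid) stays
within a few hundred MB of scratch memory.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

# float32 everywhere: halves memory at full scale, precision is ample for SGD
DTYPE = np.float32

# soft cap (elements) on any single im2col buffer; chunks the GEMM loop
_IM2COL_BUDGET = 30_000_000


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 tuple, got {v!r}")
    return t


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: parameter discovery, train/eval mode, capture hooks.

    Setting ``capture = True`` on any module makes it retain its last
    output (``cap_out``) and the gradient that flowed into it
    (``cap_grad``) — the hook Grad-CAM uses.
    """

    training: bool = True
    capture: bool = False
    cap_out: np.ndarray | None = None
    cap_grad: np.ndarray | None = None

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Parameter):
                    params.append(value)
        return params

    def train(self, mode: bool = True):
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- forward/backward protocol -------------------------------------
    def forward(self, *args):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        out = self.forward(*args)
        if self.capture:
            self.cap_out = out
        return out

    def bprop(self, dout):
        if self.capture:
            self.cap_grad = dout
        return self.backward(dout)

    # -- state (de)serialisation ---------------------------------------
    def _extra_state(self) -> dict[str, np.ndarray]:
        return {}

    def _load_extra_state(self, state: dict[str, np.ndarray]) -> None:
        pass

    def _named_children(self):
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                state[prefix + name] = value.data
        for key, arr in self._extra_state().items():
            state[prefix + key] = arr
        for name, child in self._named_children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        from .errors import CheckpointError

        own = {
            name: value
            for name, value in self.__dict__.items()
            if isinstance(value, Parameter)
        }
        for name, param in own.items():
            key = prefix + name
            if key not in state:
                raise CheckpointError(f"missing parameter {key!r} in checkpoint")
            arr = np.asarray(state[key], dtype=DTYPE)
            if arr.shape != param.data.shape:
                raise CheckpointError(
                    f"shape mismatch for {key!r}: checkpoint {arr.shape}, "
                    f"model {param.data.shape}"
                )
            param.data = arr.copy()
            param.grad = np.zeros_like(param.data)
        extra = self._extra_state()
        if extra:
            loaded = {}
            for key in extra:
                full = prefix + key
                if full not in state:
                    raise CheckpointError(f"missing buffer {full!r} in checkpoint")
                loaded[key] = np.asarray(state[full])
            self._load_extra_state(loaded)
        for name, child in self._named_children():
            child.load_state_dict(state, prefix + name + ".")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv3d(Module):
    """3D cross-correlation over (B, C, X, Y, Z) inputs, He-initialised."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding=0,
                 bias=False, *, rng: np.random.Generator, name: str = "conv3d"):
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.name = name
        fan_in = self.in_channels * int(np.prod(self.kernel))
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(self.out_channels, self.in_channels, *self.kernel))
        )
        self.bias = Parameter(np.zeros(self.out_channels)) if bias else None
        self._xp = None
        self._x_shape = None

    def _out_shape(self, spatial):
        out = []
        for L, k, s, p in zip(spatial, self.kernel, self.stride, self.padding):
            o = (L + 2 * p - k) // s + 1
            if o < 1 or L + 2 * p < k:
                raise ShapeError(
                    f"layer {self.name!r}: spatial dim {L} incompatible with "
                    f"kernel {k}, stride {s}, padding {p}"
                )
            out.append(o)
        return tuple(out)

    def forward(self, x):
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ShapeError(
                f"layer {self.name!r}: expected (B,{self.in_channels},X,Y,Z), "
                f"got {x.shape}"
            )
        B = x.shape[0]
        ox, oy, oz = self._out_shape(x.shape[2:])
        k0, k1, k2 = self.kernel
        s0, s1, s2 = self.stride
        p0, p1, p2 = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)))
        self._xp = xp
        self._x_shape = x.shape
        win = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=(2, 3, 4)
        )[:, :, ::s0, ::s1, ::s2]  # (B, C, ox, oy, oz, k0, k1, k2)
        cols_per_x = self.in_channels * k0 * k1 * k2 * oy * oz
        chunk = max(1, _IM2COL_BUDGET // max(1, cols_per_x))
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = np.empty((B, self.out_channels, ox, oy, oz), dtype=DTYPE)
        for b in range(B):
            for h0 in range(0, ox, chunk):
                seg = win[b, :, h0:h0 + chunk]  # (C, hc, oy, oz, k0,k1,k2)
                hc = seg.shape[1]
                cols = np.ascontiguousarray(
                    seg.transpose(1, 2, 3, 0, 4, 5, 6)
                ).reshape(hc * oy * oz, -1)
                res = cols @ wmat.T  # (hc*oy*oz, O)
                out[b, :, h0:h0 + chunk] = res.reshape(hc, oy, oz, -1).transpose(3, 0, 1, 2)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        return out

    def backward(self, dout):
        x_shape = self._x_shape
        xp = self._xp
        B, C, X, Y, Z = x_shape
        k0, k1, k2 = self.kernel
        s0, s1, s2 = self.stride
        p0, p1, p2 = self.padding
        ox, oy, oz = dout.shape[2:]
        win = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=(2, 3, 4)
        )[:, :, ::s0, ::s1, ::s2]
        self.weight.grad += np.einsum(
            "bcxyzijk,boxyz->ocijk", win, dout, optimize=True
        ).astype(DTYPE)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros_like(xp)
        w = self.weight.data
        for i in range(k0):
            for j in range(k1):
                for l in range(k2):
                    contrib = np.einsum(
                        "boxyz,oc->bcxyz", dout, w[:, :, i, j, l], optimize=True
                    )
                    dxp[:, :,
                        i:i + ox * s0:s0,
                        j:j + oy * s1:s1,
                        l:l + oz * s2:s2] += contrib
        return dxp[:, :, p0:p0 + X, p1:p1 + Y, p2:p2 + Z]


class BatchNorm3d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.channels = int(channels)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.gamma = Parameter(np.ones(self.channels))
        self.beta = Parameter(np.zeros(self.channels))
        self.running_mean = np.zeros(self.channels, dtype=DTYPE)
        self.running_var = np.ones(self.channels, dtype=DTYPE)
        self._cache = None

    def _extra_state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _load_extra_state(self, state):
        self.running_mean = np.asarray(state["running_mean"], dtype=DTYPE).copy()
        self.running_var = np.asarray(state["running_var"], dtype=DTYPE).copy()

    def forward(self, x):
        br = (None, slice(None), None, None, None)
        if self.training:
            axes = (0, 2, 3, 4)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size / self.channels
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            unbiased = var * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(DTYPE)
            istd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[br]) * istd[br]
            self._cache = ("train", xhat, istd)
        else:
            istd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[br]) * istd[br]
            self._cache = ("eval", xhat, istd)
        return (self.gamma.data[br] * xhat + self.beta.data[br]).astype(DTYPE)

    def backward(self, dout):
        mode, xhat, istd = self._cache
        br = (None, slice(None), None, None, None)
        axes = (0, 2, 3, 4)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.data[br]
        if mode == "eval":
            return dxhat * istd[br]
        n = xhat.size / self.channels
        return (istd[br] / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)[br]
            - xhat * (dxhat * xhat).sum(axis=axes)[br]
        )


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(x.dtype)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool3d(Module):
    """Max pooling over (B, C, X, Y, Z); padding is filled with -inf."""

    def __init__(self, kernel, stride=None, padding=0):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride if stride is not None else kernel)
        self.padding = _triple(padding)
        self._cache = None

    def forward(self, x):
        k0, k1, k2 = self.kernel
        s0, s1, s2 = self.stride
        p0, p1, p2 = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=(2, 3, 4)
        )[:, :, ::s0, ::s1, ::s2]
        B, C, ox, oy, oz = win.shape[:5]
        flat = win.reshape(B, C, ox, oy, oz, -1)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, arg, (ox, oy, oz))
        return np.ascontiguousarray(out)

    def backward(self, dout):
        x_shape, xp_shape, arg, (ox, oy, oz) = self._cache
        k0, k1, k2 = self.kernel
        s0, s1, s2 = self.stride
        p0, p1, p2 = self.padding
        B, C = x_shape[:2]
        i = arg // (k1 * k2)
        j = (arg // k2) % k1
        l = arg % k2
        gx = np.arange(ox)[None, None, :, None, None] * s0 + i
        gy = np.arange(oy)[None, None, None, :, None] * s1 + j
        gz = np.arange(oz)[None, None, None, None, :] * s2 + l
        bb = np.arange(B)[:, None, None, None, None]
        cc = np.arange(C)[None, :, None, None, None]
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        np.add.at(dxp,
                  (np.broadcast_to(bb, arg.shape),
                   np.broadcast_to(cc, arg.shape),
                   np.broadcast_to(gx, arg.shape),
                   np.broadcast_to(gy, arg.shape),
                   np.broadcast_to(gz, arg.shape)),
                  dout)
        X, Y, Z = x_shape[2:]
        return dxp[:, :, p0:p0 + X, p1:p1 + Y, p2:p2 + Z]


class GlobalAvgPool3d(Module):
    """Average over the whole spatial extent; output (B, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        B, C, X, Y, Z = self._shape
        scale = 1.0 / (X * Y * Z)
        return np.broadcast_to(
            dout[:, :, None, None, None] * scale, self._shape
        ).astype(dout.dtype).copy()


class Linear(Module):
    def __init__(self, in_features, out_features, *, rng: np.random.Generator,
                 name: str = "linear"):
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        self.name = name
        bound = np.sqrt(2.0 / self.in_features)
        self.weight = Parameter(
            rng.normal(0.0, bound, size=(self.out_features, self.in_features))
        )
        self.bias = Parameter(np.zeros(self.out_features))
        self._x = None

    def forward(self, x):
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ShapeError(
                f"layer {self.name!r}: expected (B,{self.in_features}), got {x.shape}"
            )
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def backward(self, dout):
        for m in reversed(self.mods):
            dout = m.bprop(dout)
        return dout


# ---------------------------------------------------------------------------
# loss and optimiser
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SoftmaxCrossEntropy:
    """Mean softmax cross-entropy over a batch of integer labels."""

    def __init__(self):
        self._probs = None
        self._labels = None

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        probs = softmax(logits.astype(np.float64))
        self._probs = probs
        self._labels = labels
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))

    def backward(self) -> np.ndarray:
        probs = self._probs.copy()
        probs[np.arange(len(self._labels)), self._labels] -= 1.0
        return (probs / len(self._labels)).astype(DTYPE)


class SGD:
    """Minibatch stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
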