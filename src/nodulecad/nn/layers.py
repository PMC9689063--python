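"""Neural-network building blocks on the autodiff engine.

3D convolution is stride-1 only (all convolutions in the detector and
scorer are stride 1; downsampling is done by max-pooling and upsampling
by a kernel-2/stride-2 transposed convolution).  The forward pass of a
convolution is an im2col (``sliding_window_view``) followed by a single
BLAS matmul; the input gradient is computed as a full correlation with
the spatially flipped kernel, which reuses the same machinery and avoids
a scatter.

Modules carry a ``training`` flag.  In eval mode the forward pass runs
outside the tape (inputs and outputs are constant tensors), which keeps
inference memory flat.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, matmul

__all__ = [
    "Module",
    "ModuleList",
    "Conv3d",
    "ConvTranspose3d2x",
    "MaxPool3d",
    "BatchNorm3d",
    "Linear",
    "Dropout",
]


class Module:
    """Base class: parameter registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, (Module, ModuleList)):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [
            (prefix + k, v)
            for k, v in vars(self).items()
            if isinstance(v, np.ndarray) and k.startswith("running_")
        ]
        for name, m in self._modules.items():
            out.extend(m.buffers(prefix + name + "."))
        return out

    def train(self, flag: bool = True):
        object.__setattr__(self, "training", flag)
        for m in self._modules.values():
            m.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class ModuleList:
    def __init__(self, modules=()):
        self._list = list(modules)

    def append(self, m: Module):
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def parameters(self):
        out = []
        for m in self._list:
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = ""):
        out = []
        for i, m in enumerate(self._list):
            out.extend(m.named_parameters(f"{prefix}{i}."))
        return out

    def buffers(self, prefix: str = ""):
        out = []
        for i, m in enumerate(self._list):
            out.extend(m.buffers(f"{prefix}{i}."))
        return out

    def train(self, flag: bool = True):
        for m in self._list:
            m.train(flag)
        return self


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, k: int, pad: int):
    """(N,C,D,H,W) -> (C*k^3, N*Do*Ho*Wo) patch matrix.

    Built as k^3 shifted-slab copies (long contiguous runs) instead of a
    window-view transpose (3-element runs); the GEMM then runs on the
    transposed layout, which is what BLAS handles natively.  Row order
    is c-major then (dz, dy, dx), matching ``weight.reshape(O, -1)``.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    n, c, dp, hp, wp = x.shape
    do, ho, wo = dp - k + 1, hp - k + 1, wp - k + 1
    s = do * ho * wo
    if k == 1:
        cols = np.ascontiguousarray(
            x.transpose(1, 0, 2, 3, 4).reshape(c, n * s))
        return cols, (n, do, ho, wo)
    cols = np.empty((c * k**3, n * s), dtype=x.dtype)
    off = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                slab = x[:, :, dz:dz + do, dy:dy + ho, dx:dx + wo]
                cols[off::k**3, :] = \
                    slab.transpose(1, 0, 2, 3, 4).reshape(c, n * s)
                off += 1
    return cols, (n, do, ho, wo)


class Conv3d(Module):
    """Stride-1 3D convolution with odd kernel and 'same'-style padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, pad: int | None = None, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = (kernel // 2) if pad is None else pad
        fan_in = in_channels * kernel**3
        self.weight = Tensor(
            _he_init(rng, (out_channels, in_channels, kernel, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True) if bias else None

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        k, p, o = self.kernel, self.pad, self.out_channels
        cols, (n, do, ho, wo) = _im2col(x.data, k, p)
        out2 = self.weight.data.reshape(o, -1) @ cols  # (O, N*S)
        if self.bias is not None:
            out2 += self.bias.data[:, None]
        out = out2.reshape(o, n, do, ho, wo).transpose(1, 0, 2, 3, 4)
        if not self.training and not x.requires_grad:
            return Tensor(out)

        parents = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        res = Tensor(out, requires_grad=True, parents=parents)

        def _bwd(g, x=x, self_=self, cols=cols):
            o = self_.out_channels
            g2 = np.ascontiguousarray(
                g.transpose(1, 0, 2, 3, 4).reshape(o, -1))
            self_.weight.accumulate(
                (g2 @ cols.T).reshape(self_.weight.data.shape))
            if self_.bias is not None:
                self_.bias.accumulate(g2.sum(axis=1))
            if x.requires_grad:
                k = self_.kernel
                # full correlation with the flipped kernel recovers dL/dx
                wf = (self_.weight.data[:, :, ::-1, ::-1, ::-1]
                      .transpose(1, 0, 2, 3, 4))
                gcols, (n, d, h, w) = _im2col(g, k, k - 1 - self_.pad)
                gx2 = wf.reshape(self_.in_channels, -1) @ gcols
                x.accumulate(gx2.reshape(self_.in_channels, n, d, h, w)
                             .transpose(1, 0, 2, 3, 4))

        res._backward = _bwd
        return res

    __call__ = forward


class ConvTranspose3d2x(Module):
    """Transposed convolution, kernel 2 stride 2 (exact 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Tensor(
            _he_init(rng, (in_channels, out_channels, 2, 2, 2), in_channels),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        n, c, d, h, w = x.data.shape
        o = self.out_channels
        out = np.tensordot(x.data, self.weight.data, axes=([1], [0]))
        out = out.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, o, 2 * d, 2 * h, 2 * w)
        out += self.bias.data[:, None, None, None]
        if not self.training and not x.requires_grad:
            return Tensor(out)
        res = Tensor(out, requires_grad=True, parents=(x, self.weight, self.bias))

        def _bwd(g, x=x, self_=self, dims=(n, d, h, w)):
            n, d, h, w = dims
            o = self_.out_channels
            gv = g.reshape(n, o, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
            self_.bias.accumulate(g.sum(axis=(0, 2, 3, 4)))
            self_.weight.accumulate(
                np.tensordot(x.data, gv, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            )
            if x.requires_grad:
                gx = np.tensordot(gv, self_.weight.data,
                                  axes=([4, 5, 6, 7], [1, 2, 3, 4]))
                x.accumulate(gx.transpose(0, 4, 1, 2, 3))

        res._backward = _bwd
        return res

    __call__ = forward


class MaxPool3d(Module):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        n, c, d, h, w = x.data.shape
        v = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        v = v.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if not x.requires_grad:
            return Tensor(out)
        res = Tensor(out, requires_grad=True, parents=(x,))

        def _bwd(g, x=x, idx=idx, dims=(n, c, d, h, w)):
            n, c, d, h, w = dims
            gv = np.zeros((n, c, d // 2, h // 2, w // 2, 8), np.float32)
            np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
            gv = gv.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            gx = gv.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
            x.accumulate(gx)

        res._backward = _bwd
        return res

    __call__ = forward


class BatchNorm3d(Module):
    """Batch normalisation over (N, D, H, W) per channel.

    ``eval_stats`` selects the statistics used outside training:
    ``"input"`` (default) normalises each sample with its own per-channel
    spatial statistics (instance statistics) — deterministic, independent
    of batch composition, and consistent with the normalisation the
    network saw during training, which matters in the small-batch regime
    this package trains in; ``"running"`` uses the tracked exponential
    moving averages (textbook behaviour).
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 eval_stats: str = "input"):
        super().__init__()
        if eval_stats not in ("input", "running"):
            raise ValueError("eval_stats must be 'input' or 'running'")
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.eval_stats = eval_stats
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        elif self.eval_stats == "input":
            # per-sample instance statistics, (N, C) broadcast over space
            mu = x.data.mean(axis=(2, 3, 4))[..., None, None, None]
            var = x.data.var(axis=(2, 3, 4))[..., None, None, None]
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mu) * inv
            out = (self.gamma.data[:, None, None, None] * xhat
                   + self.beta.data[:, None, None, None])
            if not x.requires_grad:
                return Tensor(out)
            res = Tensor(out, requires_grad=True,
                         parents=(x, self.gamma, self.beta))

            def _bwd_inst(g, x=x, self_=self, xhat=xhat, inv=inv):
                sp = (2, 3, 4)
                self_.gamma.accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
                self_.beta.accumulate(g.sum(axis=(0, 2, 3, 4)))
                if x.requires_grad:
                    gi = g * self_.gamma.data[:, None, None, None]
                    mean_gi = gi.mean(axis=sp, keepdims=True)
                    mean_gx = (gi * xhat).mean(axis=sp, keepdims=True)
                    x.accumulate((inv * (gi - mean_gi - xhat * mean_gx))
                                 .astype(np.float32))

            res._backward = _bwd_inst
            return res
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[:, None, None, None]) * inv[:, None, None, None]
        out = self.gamma.data[:, None, None, None] * xhat + self.beta.data[:, None, None, None]
        if not self.training and not x.requires_grad:
            return Tensor(out)
        res = Tensor(out, requires_grad=True, parents=(x, self.gamma, self.beta))
        m = x.data.size / self.channels
        batch = self.training

        def _bwd(g, x=x, self_=self, xhat=xhat, inv=inv, m=m, batch=batch):
            axes = (0, 2, 3, 4)
            self_.gamma.accumulate((g * xhat).sum(axis=axes))
            self_.beta.accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gi = g * self_.gamma.data[:, None, None, None]
                if batch:
                    mean_gi = gi.mean(axis=axes)[:, None, None, None]
                    mean_gx = (gi * xhat).mean(axis=axes)[:, None, None, None]
                    gx = inv[:, None, None, None] * (gi - mean_gi - xhat * mean_gx)
                else:
                    gx = gi * inv[:, None, None, None]
                x.accumulate(gx.astype(np.float32))

        res._backward = _bwd
        return res

    __call__ = forward


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            _he_init(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if not self.training and not x.requires_grad:
            return Tensor(x.data @ self.weight.data + self.bias.data)
        return matmul(x, self.weight) + self.bias

    __call__ = forward


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0,1)")
        self.p = p
        self.rng = rng

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p).astype(np.float32)
        mask /= 1.0 - self.p
        return x * Tensor(mask)

    __call__ = forward
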