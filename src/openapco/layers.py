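"""Neural-network layers built on the tape autodiff.

Conventions follow the common deep-learning defaults: feature maps are
``[batch, channels, length]``, convolutions are He-initialised and dense
layers Xavier-initialised, batch normalisation keeps running statistics
with momentum 0.1 and eps 1e-5, dropout uses inverted scaling and is
active only in training mode.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, avg_pool1d, concat, conv1d, softmax

__all__ = [
    "Module",
    "Conv1d",
    "BatchNorm1d",
    "Dense",
    "Dropout",
    "AvgPool1d",
    "GlobalAvgPool1d",
    "ReLU",
    "Sequential",
    "InceptionModule",
    "NonlocalModule",
    "xavier_uniform",
    "he_normal",
]


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


def he_normal(rng: np.random.Generator, shape, fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus buffers, in traversal order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(targets) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(targets, state):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        dilation: int = 1,
        padding: str | int = "same",
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.dilation, self.padding = stride, dilation, padding
        self.weight = Tensor(he_normal(rng, (c_out, c_in, k), c_in * k), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(
            x, self.weight, self.bias, self.stride, self.dilation, self.padding
        )


class BatchNorm1d(Module):
    """Batch normalisation over (batch, length) per channel; also accepts 2-D
    dense activations [batch, features]."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: Tensor) -> Tensor:
        is_3d = x.ndim == 3
        axes = (0, 2) if is_3d else (0,)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var
            )
        else:
            shape = (1, -1, 1) if is_3d else (1, -1)
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xn = (x - mu) / (var + self.eps).sqrt()
        shape = (1, -1, 1) if is_3d else (1, -1)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.weight = Tensor(
            xavier_uniform(rng, (d_in, d_out), d_in, d_out), requires_grad=True
        )
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def reinitialize(self, rng: np.random.Generator) -> None:
        """Xavier re-initialisation (used when the regressor is retrained)."""
        self.weight.data[...] = xavier_uniform(
            rng, (self.d_in, self.d_out), self.d_in, self.d_out
        )
        self.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; the caller supplies the random stream per forward."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class AvgPool1d(Module):
    def __init__(self, k: int, stride: int | None = None, padding: str | int = 0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride or k, padding

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool1d(x, self.k, self.stride, self.padding)


class GlobalAvgPool1d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class InceptionModule(Module):
    """Four parallel convolutional paths concatenated channel-wise.

    Each path ends with ``filters`` channels, so the module output has
    ``4 * filters`` channels and the temporal length is preserved. Path
    specs are lists of ops: ``("pw",)`` pointwise conv, ``("conv", k, d)``
    a dilated conv, ``("pool", p)`` stride-1 same-padded average pooling.
    Every conv is followed by batch norm + ReLU.
    """

    def __init__(
        self,
        c_in: int,
        filters: int,
        path_specs: list[list[tuple]],
        rng: np.random.Generator,
    ):
        super().__init__()
        if len(path_specs) != 4:
            raise ValueError("an inception module has exactly 4 paths")
        self.paths: list[Sequential] = []
        self.n_convs = 0
        self.n_pools = 0
        for spec in path_specs:
            layers: list[Module] = []
            c = c_in
            for op in spec:
                if op[0] == "pw":
                    layers += [Conv1d(c, filters, 1, rng), BatchNorm1d(filters), ReLU()]
                    c = filters
                    self.n_convs += 1
                elif op[0] == "conv":
                    _, k, d = op
                    layers += [
                        Conv1d(c, filters, k, rng, dilation=d, padding="same"),
                        BatchNorm1d(filters),
                        ReLU(),
                    ]
                    c = filters
                    self.n_convs += 1
                elif op[0] == "pool":
                    layers.append(AvgPool1d(op[1], stride=1, padding="same"))
                    self.n_pools += 1
                else:
                    raise ValueError(f"unknown path op {op[0]!r}")
            if c != filters:
                raise ValueError("every inception path must end in a conv")
            self.paths.append(Sequential(*layers))
        self.out_channels = 4 * filters

    def forward(self, x: Tensor) -> Tensor:
        return concat([p(x) for p in self.paths], axis=1)


class NonlocalModule(Module):
    """Residual global-attention block over time positions.

    Embedded-Gaussian form: queries/keys/values are pointwise projections
    to ``c // 2`` channels, attention weights are a softmax over all
    (optionally pooled, rate ``p``) positions, and the aggregated values
    are projected back to ``c`` channels and added to the input. The final
    projection is zero-initialised, so the module starts as the identity
    and learns to depart from it.
    """

    def __init__(self, c: int, rng: np.random.Generator, pool_rate: int = 1):
        super().__init__()
        ci = max(c // 2, 1)
        self.pool_rate = pool_rate
        self.theta = Conv1d(c, ci, 1, rng, bias=False)
        self.phi = Conv1d(c, ci, 1, rng, bias=False)
        self.g = Conv1d(c, ci, 1, rng, bias=False)
        self.w_z = Conv1d(ci, c, 1, rng, bias=False)
        self.w_z.weight.data[...] = 0.0
        self.scale = 1.0 / np.sqrt(ci)

    def forward(self, x: Tensor) -> Tensor:
        q = self.theta(x)  # [N, ci, L]
        k = self.phi(x)
        v = self.g(x)
        if self.pool_rate > 1:
            k = avg_pool1d(k, self.pool_rate)
            v = avg_pool1d(v, self.pool_rate)
        att = softmax(q.transpose(0, 2, 1) @ k * self.scale, axis=-1)  # [N, L, Lp]
        y = att @ v.transpose(0, 2, 1)  # [N, L, ci]
        return x + self.w_z(y.transpose(0, 2, 1))
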