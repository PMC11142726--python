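"""Neural-network building blocks on top of :mod:`grnsage.autograd`.

Modules follow the familiar container pattern: parameters are discovered
recursively, ``train()`` / ``eval()`` toggles batch-normalization behaviour,
and :class:`Adam` owns the optimization state.  Initialization draws from an
explicit ``numpy.random.Generator`` so every run is reproducible from the
run-level seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, maxpool2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (checkpointing)."""
        state: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                state[key] = value.data
            elif isinstance(value, Module):
                state.update(value.named_state(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.named_state(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        state[f"{key}.{i}"] = item.data
            elif isinstance(value, np.ndarray):
                state[key] = value
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in list(self.__dict__.items()):
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                value.data = np.array(state[key], dtype=np.float64)
            elif isinstance(value, Module):
                value.load_state(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        item.data = np.array(state[f"{key}.{i}"], dtype=np.float64)
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.array(state[key]))

    def train(self) -> None:
        self.training = True
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.eval()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.eval()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_glorot(rng, in_features, out_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LazyLinear(Module):
    """Linear layer whose input width is inferred at the first forward pass."""

    def __init__(self, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.out_features = out_features
        self._rng = rng
        self.inner: Linear | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if self.inner is None:
            self.inner = Linear(x.shape[-1], self.out_features, self._rng)
            self.inner.training = self.training
        return self.inner(x)

    def load_state(self, state, prefix: str = "") -> None:  # materialize before loading
        wkey = f"{prefix}inner.weight"
        if self.inner is None and wkey in state:
            self.inner = Linear(state[wkey].shape[0], self.out_features, self._rng)
        super().load_state(state, prefix=prefix)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kh * kw
        fan_out = out_ch * kh * kw
        self.weight = Parameter(_glorot(rng, fan_in, fan_out, (out_ch, in_ch, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel normalization over (batch, height, width).

    Training mode uses batch statistics (biased variance) and updates running
    buffers with momentum 0.1; eval mode applies the frozen running statistics.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(c)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(c)
            )
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class MaxPool2d(Module):
    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.ph, self.pw)


class LSTMCell(Module):
    """Single-layer LSTM consumed step-by-step (used by the LSTM aggregator)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.w_ih = Parameter(_glorot(rng, input_size, 4 * hidden_size, (input_size, 4 * hidden_size)))
        self.w_hh = Parameter(_glorot(rng, hidden_size, 4 * hidden_size, (hidden_size, 4 * hidden_size)))
        self.bias = Parameter(np.zeros(4 * hidden_size))

    def run_sequence(self, xs: Tensor) -> Tensor:
        """Consume a (T, input_size) sequence; return the final hidden state (hidden_size,)."""
        h = Tensor(np.zeros((1, self.hidden_size)))
        c = Tensor(np.zeros((1, self.hidden_size)))
        hs = self.hidden_size
        T = xs.shape[0]
        for t in range(T):
            x_t = xs[t : t + 1]
            gates = x_t @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, 0:hs].sigmoid()
            f = gates[:, hs : 2 * hs].sigmoid()
            g = gates[:, 2 * hs : 3 * hs].tanh()
            o = gates[:, 3 * hs : 4 * hs].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h.reshape(self.hidden_size)


class SGD:
    """Stochastic gradient descent with classical momentum.

    The learning rate is mutated externally per epoch to follow the
    step-decay schedule exactly.
    """

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v


class Adam:
    """Adam optimizer; the learning rate is mutated externally per epoch."""

    def __init__(self, params: list[Parameter], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def stack_rows(rows: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor (autograd-aware)."""
    return concat([r.reshape(1, -1) for r in rows], axis=0)
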