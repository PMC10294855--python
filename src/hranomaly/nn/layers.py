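"""Neural layers built on the autograd engine.

Sequence tensors are shaped ``(batch, time, channels)`` and recurrent layers
consume/produce per-time-step lists of ``(batch, channels)`` tensors. The LSTM
cell follows the standard gated update

    F_t = sigm(W_F x_t + U_F h_{t-1} + b_F)        (forget gate)
    I_t = sigm(W_I x_t + U_I h_{t-1} + b_I)        (input gate)
    C~_t = tanh(W_C x_t + U_C h_{t-1} + b_C)       (candidate cell)
    O_t = sigm(W_O x_t + U_O h_{t-1} + b_O)        (output gate)
    C_t = F_t o C_{t-1} + I_t o C~_t
    h_t = O_t o tanh(C_t)

with o the Hadamard product. Bidirectional layers run a second cell over the
reversed sequence and concatenate per-step outputs.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, pad_time, relu, sigmoid, stack, tanh

__all__ = [
    "Parameter",
    "Dense",
    "LSTMCell",
    "LSTMLayer",
    "BiLSTMLayer",
    "StackedLSTM",
    "Conv1dSame",
    "UpsampleConv1d",
    "Dropout",
    "glorot",
]


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, in_dim, out_dim))
        self.b = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LSTMCell(Module):
    """One LSTM direction; gate weights packed as [I, F, C~, O] blocks."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W = Parameter(glorot(rng, in_dim, 4 * hidden, (in_dim, 4 * hidden)))
        self.U = Parameter(glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias at 1, standard practice
        self.b = Parameter(b)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden
        z = x_t @ self.W + h @ self.U + self.b
        i = sigmoid(z[:, 0:H])
        f = sigmoid(z[:, H : 2 * H])
        g = tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H : 4 * H])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.hidden)), requires_grad=False)
        c = Tensor(np.zeros((batch, self.hidden)), requires_grad=False)
        outs = []
        for x_t in xs:
            h, c = self.step(x_t, h, c)
            outs.append(h)
        return outs


class LSTMLayer(Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.cell = LSTMCell(in_dim, hidden, rng)
        self.out_dim = hidden

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        return self.cell.run(xs)


class BiLSTMLayer(Module):
    """Forward and backward passes with per-step concatenated outputs."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fw = LSTMCell(in_dim, hidden, rng)
        self.bw = LSTMCell(in_dim, hidden, rng)
        self.out_dim = 2 * hidden

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        hf = self.fw.run(xs)
        hb = self.bw.run(xs[::-1])[::-1]
        return [concat([f, b], axis=1) for f, b in zip(hf, hb)]

    def final_state(self, outs: list[Tensor]) -> Tensor:
        """Concatenated last forward state and last backward state."""
        H = self.out_dim // 2
        return concat([outs[-1][:, :H], outs[0][:, H:]], axis=1)


class StackedLSTM(Module):
    """A stack of (Bi)LSTM layers with optional inter-layer dropout."""

    def __init__(
        self,
        in_dim: int,
        layer_sizes: tuple[int, ...],
        rng: np.random.Generator,
        bidirectional: bool = False,
        dropout: float = 0.0,
    ):
        cls = BiLSTMLayer if bidirectional else LSTMLayer
        self.layers: list[Module] = []
        self.dropout = dropout
        dim = in_dim
        for size in layer_sizes:
            layer = cls(dim, size, rng)
            self.layers.append(layer)
            dim = layer.out_dim
        self.out_dim = dim

    def __call__(
        self,
        xs: list[Tensor],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> list[Tensor]:
        for li, layer in enumerate(self.layers):
            xs = layer(xs)
            if training and self.dropout > 0 and li < len(self.layers) - 1:
                xs = [_dropout(x, self.dropout, rng) for x in xs]
        return xs


def _dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask, requires_grad=False)


class Dropout(Module):
    def __init__(self, rate: float):
        self.rate = rate

    def __call__(self, x, training: bool, rng: np.random.Generator | None = None):
        if not training or self.rate <= 0:
            return x
        return _dropout(x, self.rate, rng)


class Conv1dSame(Module):
    """1-D convolution with 'same' padding: output length = ceil(T / stride)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int,
        rng: np.random.Generator,
    ):
        self.k = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size
        self.W = [
            Parameter(glorot(rng, fan_in, out_channels, (in_channels, out_channels)))
            for _ in range(kernel_size)
        ]
        self.b = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        _, T, _ = x.shape
        s = self.stride
        t_out = -(-T // s)  # ceil
        pad_total = max((t_out - 1) * s + self.k - T, 0)
        left = pad_total // 2
        xp = pad_time(x, left, pad_total - left)
        out = None
        for tap in range(self.k):
            sl = xp[:, tap : tap + s * (t_out - 1) + 1 : s, :]
            term = sl @ self.W[tap]
            out = term if out is None else out + term
        return out + self.b


class UpsampleConv1d(Module):
    """Nearest-neighbour x2 upsampling followed by a stride-1 'same' conv.

    Used as the decoding mirror of a stride-2 convolution; avoids the
    zero-interleaving artefacts of a literal transposed convolution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        factor: int = 2,
    ):
        from .autograd import repeat_time

        self.factor = factor
        self._repeat = repeat_time
        self.conv = Conv1dSame(in_channels, out_channels, kernel_size, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(self._repeat(x, self.factor))
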