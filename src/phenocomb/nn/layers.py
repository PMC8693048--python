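"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as :class:`~phenocomb.nn.autodiff.Tensor`
objects; ``parameters()`` flattens them for the optimizers.  Weight
initialization is Glorot-uniform from an explicit ``numpy.random.Generator``
so every model build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, embedding

__all__ = ["Module", "Linear", "Embedding", "LSTMCell", "LSTM", "MLP"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # --- flat (de)serialization for single-file checkpoints -----------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.1, size=(n_vocab, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.W, idx)


class LSTMCell(Module):
    """Standard LSTM cell; gate order i, f, g, o; forget-gate bias +1."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.Wx = Tensor(glorot(rng, n_in, 4 * n_hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_hidden, 4 * n_hidden), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        n = self.n_hidden
        z = x @ self.Wx + h @ self.Wh + self.b
        i = z[:, 0 * n : 1 * n].sigmoid()
        f = z[:, 1 * n : 2 * n].sigmoid()
        g = z[:, 2 * n : 3 * n].tanh()
        o = z[:, 3 * n : 4 * n].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def zeros(self, batch: int) -> tuple[Tensor, Tensor]:
        return Tensor(np.zeros((batch, self.n_hidden))), Tensor(np.zeros((batch, self.n_hidden)))


class LSTM(Module):
    """Multi-layer (optionally bidirectional) LSTM over a padded batch.

    Input: list of per-step Tensors, each (batch, n_in).  Returns the list of
    top-layer outputs per step and the final (h, c) of the top layer.  For the
    bidirectional case the per-step output is the concatenation of the forward
    and backward passes and the "final" state is the pair of last states.
    """

    def __init__(self, n_in: int, n_hidden: int, n_layers: int, rng: np.random.Generator,
                 bidirectional: bool = False):
        self.bidirectional = bidirectional
        self.fwd = [LSTMCell(n_in if i == 0 else n_hidden * (2 if bidirectional else 1),
                             n_hidden, rng) for i in range(n_layers)]
        self.bwd = ([LSTMCell(n_in if i == 0 else n_hidden * 2, n_hidden, rng)
                     for i in range(n_layers)] if bidirectional else [])

    def __call__(self, steps: list[Tensor]) -> tuple[list[Tensor], Tensor]:
        batch = steps[0].shape[0]
        outputs = steps
        last_h: list[Tensor] = []
        n_layers = len(self.fwd)
        for layer in range(n_layers):
            f_cell = self.fwd[layer]
            h, c = f_cell.zeros(batch)
            f_out = []
            for x in outputs:
                h, c = f_cell(x, h, c)
                f_out.append(h)
            if not self.bidirectional:
                outputs = f_out
                if layer == n_layers - 1:
                    last_h = [h]
                continue
            b_cell = self.bwd[layer]
            hb, cb = b_cell.zeros(batch)
            b_out = []
            for x in reversed(outputs):
                hb, cb = b_cell(x, hb, cb)
                b_out.append(hb)
            b_out.reverse()
            outputs = [concat([f, b], axis=1) for f, b in zip(f_out, b_out)]
            if layer == n_layers - 1:
                last_h = [h, hb]
        final = last_h[0] if len(last_h) == 1 else concat(last_h, axis=1)
        return outputs, final


class MLP(Module):
    """Feed-forward stack with ReLU between layers, linear output."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x
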