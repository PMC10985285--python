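"""Attention-augmented ConvNeXt-style network, in numpy with manual backprop.

Architecture
------------
An input batch of ILAs (N, 20, 9, 21) flows through

1. an *attention block*: one single-filter 1-D convolution per amino-acid
   row h, run along the core-position axis of the row's 9 x 21 slice; the
   conv output is mean-reduced, shifted by a bias initialized from
   amino-acid frequencies (min-max scaled), and squashed by a logistic to
   a score a_h in (0, 1); row h of the input is then scaled by a_h;
2. an *interaction stem*: the contact channel is multiplied elementwise
   with each of the 20 peptide channels and the 20 product channels are
   appended, exposing the pairwise contact x peptide interactions the
   encoding interlocks; a pointwise projection to the first stage width
   plus layer normalization follows;
3. ConvNeXt-style stages: depthwise convolution (same padding, kernels
   clipped to the 20 x 9 spatial extent), layer normalization over
   channels, a pointwise 4x expansion with GELU, a pointwise contraction,
   and a residual connection;
4. global average pooling and a 1-unit head; the interaction stem's
   product channels, pooled over core positions only (leaving a 20 x 20
   MHC-type x peptide-type interaction profile), are appended to the
   pooled backbone features — a residual readout of the raw pairwise
   interaction signal. The presentation (AP) head is read through a
   logistic; the affinity (BA) head reads the same bounded (0, 1) output
   as a log50k regression value.

Everything is dense numpy; batches are channels-last throughout. The model
is deliberately desk-scale: two stages of widths 16/32 by default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from ..alphabet import N_AMINO_ACIDS, N_CORE, VECTOR_DIM

#: network-wide floating dtype; single precision is plenty for these
#: bounded inputs and roughly halves memory traffic
DTYPE = np.float32


# ---------------------------------------------------------------------------
# configs

@dataclass
class ModelConfig:
    """Hyperparameters of the attention + ConvNeXt model."""

    head: str = "ap"  # "ap" (presentation, BCE) or "ba" (affinity, MSE)
    stage_depths: tuple[int, ...] = (1, 1)
    stage_widths: tuple[int, ...] = (16, 32)
    dw_kernel: tuple[int, int] = (3, 7)  # (type axis, core-position axis)
    attention_kernel_width: int = 3
    interaction_stem: bool = True
    dropout: float = 0.0
    learning_rate: float = 2e-3
    lr_decay_epochs: int = 8  # halve the step size every this many epochs
    batch_size: int = 64
    epochs: int = 24
    patience: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head not in ("ap", "ba"):
            raise ValueError(f"head must be 'ap' or 'ba', got {self.head!r}")
        if len(self.stage_depths) != len(self.stage_widths):
            raise ValueError("stage_depths and stage_widths must align")
        if any(d < 1 for d in self.stage_depths) or any(w < 1 for w in self.stage_widths):
            raise ValueError("stage depths and widths must be positive")
        if not 1 <= self.attention_kernel_width <= N_CORE:
            raise ValueError(f"attention kernel width must be in 1..{N_CORE}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("learning_rate", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def init_attention_weights(freqs: np.ndarray) -> np.ndarray:
    """Min-max scale 20 amino-acid frequencies to attention init weights.

    The most frequent amino acid gets weight 1, the least frequent 0; if
    all frequencies are equal every weight is 1 (degenerate fallback).
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (N_AMINO_ACIDS,):
        raise ValueError(f"expected {N_AMINO_ACIDS} frequencies, got shape {f.shape}")
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError(f"frequencies must sum to 1, got {f.sum()}")
    lo, hi = f.min(), f.max()
    if np.isclose(hi, lo):
        return np.ones(N_AMINO_ACIDS)
    return (f - lo) / (hi - lo)


def peptide_frequencies(peptides: Sequence[str]) -> np.ndarray:
    """Empirical amino-acid frequencies of a peptide set (uniform if empty)."""
    from ..alphabet import AA_INDEX

    counts = np.zeros(N_AMINO_ACIDS)
    for pep in peptides:
        for ch in pep:
            counts[AA_INDEX[ch]] += 1
    if counts.sum() == 0:
        return np.full(N_AMINO_ACIDS, 1.0 / N_AMINO_ACIDS)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# activations

_GELU_C = np.float32(np.sqrt(2.0 / np.pi))
_GELU_A = np.float32(0.044715)


def _gelu(x: np.ndarray) -> np.ndarray:
    # tanh approximation of x * Phi(x)
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + _GELU_A * x * x * x)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    x2 = x * x
    t = np.tanh(_GELU_C * (x + _GELU_A * x * x2))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (1.0 + 3.0 * _GELU_A * x2)


# ---------------------------------------------------------------------------
# layers

class Layer:
    """A parameterized layer with cached forward state and explicit grads."""

    #: per-layer learning-rate multiplier picked up by the optimizer
    lr_scale: float = 1.0

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Pointwise(Layer):
    """1x1 cross-channel linear mix: y = x @ W + b on channels-last input."""

    def __init__(self, name: str, cin: int, cout: int, rng: np.random.Generator):
        super().__init__(name)
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)).astype(DTYPE),
            "b": np.zeros(cout, dtype=DTYPE),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.grads = {"W": x2.T @ g2, "b": g2.sum(axis=0)}
        return g @ self.params["W"].T


class DepthwiseConvSame(Layer):
    """Per-channel KxL convolution with zero same-padding."""

    def __init__(self, name: str, channels: int, kernel: tuple[int, int], rng: np.random.Generator):
        super().__init__(name)
        K, L = kernel
        self.kernel = (K, L)
        self.params = {
            "V": rng.normal(0.0, np.sqrt(2.0 / (K * L)), (channels, K, L)).astype(DTYPE),
            "b": np.zeros(channels, dtype=DTYPE),
        }

    def forward(self, x, train=False):
        K, L = self.kernel
        ph, pw = K // 2, L // 2
        # pad asymmetrically for even kernels
        self._pads = ((ph, K - 1 - ph), (pw, L - 1 - pw))
        xp = np.pad(x, ((0, 0), self._pads[0], self._pads[1], (0, 0)))
        self._xp = xp
        N, H, W, C = x.shape
        V = self.params["V"]
        out = np.zeros_like(x)
        for k in range(K):
            for l in range(L):
                out += xp[:, k:k + H, l:l + W, :] * V[:, k, l]
        self._shape = (N, H, W, C)
        return out + self.params["b"]

    def backward(self, g):
        K, L = self.kernel
        N, H, W, C = self._shape
        V = self.params["V"]
        win = sliding_window_view(self._xp, (K, L), axis=(1, 2))  # (N,H,W,C,K,L)
        gV = np.einsum("nijckl,nijc->ckl", win, g, optimize=True)
        # input gradient = same-padded convolution of g with the flipped
        # kernel and swapped pads
        (pt, pb), (pl, pr) = self._pads
        gp = np.pad(g, ((0, 0), (pb, pt), (pr, pl), (0, 0)))
        dx = np.zeros_like(g)
        for k in range(K):
            for l in range(L):
                dx += gp[:, k:k + H, l:l + W, :] * V[:, K - 1 - k, L - 1 - l]
        self.grads = {"V": gV, "b": g.sum(axis=(0, 1, 2))}
        return dx


class LayerNorm(Layer):
    """Normalization over the channel axis at every spatial location."""

    def __init__(self, name: str, channels: int, eps: float = 1e-6):
        super().__init__(name)
        self.eps = eps
        self.params = {"gamma": np.ones(channels, dtype=DTYPE),
                       "beta": np.zeros(channels, dtype=DTYPE)}

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        xhat = self._xhat
        axes = tuple(range(g.ndim - 1))
        self.grads = {"gamma": (g * xhat).sum(axis=axes), "beta": g.sum(axis=axes)}
        dxhat = g * self.params["gamma"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) * self._inv


class Gelu(Layer):
    def __init__(self, name: str):
        super().__init__(name)

    def forward(self, x, train=False):
        self._x = x
        self._t = np.tanh(_GELU_C * (x + _GELU_A * x * x * x))
        return 0.5 * x * (1.0 + self._t)

    def backward(self, g):
        x, t = self._x, self._t
        inner = _GELU_C * (1.0 + 3.0 * _GELU_A * x * x)
        return g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * inner)


class Relu(Layer):
    def __init__(self, name: str):
        super().__init__(name)

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return g * self._mask


class AttentionBlock(Layer):
    """Per-row 1-D convolution attention with frequency-initialized biases.

    Row h of an (N, H, W, C) input yields a score
    a_h = logistic(mean_t Conv1D_h(X[h]) + bias_h); with zero-initialized
    filter weights a_h = logistic(init_weight_h). The output is the input
    with row h scaled by a_h. The block trains with a raised learning
    rate: its 20 per-row biases receive weak, heavily shared gradients
    compared with the convolutional stack downstream.
    """

    lr_scale = 8.0

    def __init__(self, name: str, height: int, width: int, channels: int,
                 kernel_width: int, init_weights: np.ndarray):
        super().__init__(name)
        if kernel_width > width:
            raise ValueError(f"attention kernel width {kernel_width} exceeds input width {width}")
        init = np.asarray(init_weights, dtype=float)
        if init.shape != (height,):
            raise ValueError(f"need {height} init weights, got shape {init.shape}")
        self.kernel_width = kernel_width
        self.params = {
            "U": np.zeros((height, kernel_width, channels), dtype=DTYPE),
            "bias": init.astype(DTYPE),
        }

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Attention scores a_h for a batch, shape (N, H), entries in (0, 1)."""
        if x.ndim == 3:
            x = x[None]
        Wk = self.kernel_width
        win = sliding_window_view(x, Wk, axis=2)  # (N, H, T, C, Wk)
        y = np.einsum("nhtcw,hwc->nht", win, self.params["U"], optimize=True)
        m = y.mean(axis=2) + self.params["bias"]
        return expit(m)

    def forward(self, x, train=False):
        Wk = self.kernel_width
        self._x = x
        self._win = sliding_window_view(x, Wk, axis=2)
        y = np.einsum("nhtcw,hwc->nht", self._win, self.params["U"], optimize=True)
        self._T = y.shape[2]
        m = y.mean(axis=2) + self.params["bias"]
        self._a = expit(m)
        return x * self._a[:, :, None, None]

    def backward(self, g):
        x, a = self._x, self._a
        da = np.einsum("nhwc,nhwc->nh", g, x, optimize=True)
        dm = da * a * (1.0 - a)
        self.grads = {"bias": dm.sum(axis=0)}
        dy = np.repeat(dm[:, :, None] / self._T, self._T, axis=2)  # (N, H, T)
        self.grads["U"] = np.einsum("nht,nhtcw->hwc", dy, self._win, optimize=True)
        dx = g * a[:, :, None, None]
        U = self.params["U"]
        N, H, W, C = x.shape
        for w in range(self.kernel_width):
            dx[:, :, w:w + self._T, :] += dy[:, :, :, None] * U[None, :, w, :][:, :, None, :]
        return dx


class InteractionStem(Layer):
    """Append contact x peptide product channels to the input.

    Channel 0 carries the allele's contact map, channels 1..C-1 the
    peptide; their elementwise products are the explicit pairwise
    interaction features of the degenerate coding.
    """

    def __init__(self, name: str):
        super().__init__(name)

    def forward(self, x, train=False):
        self._x = x
        return np.concatenate([x, x[..., :1] * x[..., 1:]], axis=-1)

    def backward(self, g):
        x = self._x
        C = x.shape[-1]
        g1, g2 = g[..., :C], g[..., C:]
        dx = g1.copy()
        dx[..., 0] += np.einsum("nhwc,nhwc->nhw", g2, x[..., 1:], optimize=True)
        dx[..., 1:] += g2 * x[..., :1]
        return dx


class ConvNeXtBlock(Layer):
    """depthwise conv -> layernorm -> pointwise 4x + GELU -> pointwise -> residual"""

    def __init__(self, name: str, channels: int, kernel: tuple[int, int], rng):
        super().__init__(name)
        self.dw = DepthwiseConvSame(f"{name}.dw", channels, kernel, rng)
        self.ln = LayerNorm(f"{name}.ln", channels)
        self.pw1 = Pointwise(f"{name}.pw1", channels, 4 * channels, rng)
        self.act = Gelu(f"{name}.act")
        self.pw2 = Pointwise(f"{name}.pw2", 4 * channels, channels, rng)
        self.sublayers = [self.dw, self.ln, self.pw1, self.act, self.pw2]

    def forward(self, x, train=False):
        h = x
        for layer in self.sublayers:
            h = layer.forward(h, train=train)
        return x + h

    def backward(self, g):
        h = g
        for layer in reversed(self.sublayers):
            h = layer.backward(h)
        return g + h


class GlobalAvgPool(Layer):
    def __init__(self, name: str):
        super().__init__(name)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        N, H, W, C = self._shape
        return np.broadcast_to(g[:, None, None, :], self._shape) / (H * W)


class Dense(Layer):
    def __init__(self, name: str, cin: int, cout: int, rng):
        super().__init__(name)
        self.params = {"W": rng.normal(0.0, np.sqrt(1.0 / cin), (cin, cout)).astype(DTYPE),
                       "b": np.zeros(cout, dtype=DTYPE)}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads = {"W": self._x.T @ g, "b": g.sum(axis=0)}
        return g @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, name: str, rate: float, rng: np.random.Generator):
        super().__init__(name)
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = self.rng.random(x.shape) >= self.rate
        return x * self._mask / (1.0 - self.rate)

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask / (1.0 - self.rate)


# ---------------------------------------------------------------------------
# networks

def _iter_layers(layers):
    for layer in layers:
        if isinstance(layer, ConvNeXtBlock):
            yield from layer.sublayers
        else:
            yield layer


class ConvNeXtMHCNet:
    """The full attention + ConvNeXt model over (N, 20, 9, 21) ILA batches."""

    input_shape = (N_AMINO_ACIDS, N_CORE, VECTOR_DIM)

    def __init__(self, config: ModelConfig, attention_init: np.ndarray | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H, W, C = self.input_shape
        if attention_init is None:
            attention_init = np.ones(H)
        self.attention = AttentionBlock(
            "attn", H, W, C, config.attention_kernel_width, attention_init
        )
        self.layers: list[Layer] = [self.attention]
        prev = C
        if config.interaction_stem:
            self.layers.append(InteractionStem("interact"))
            prev = 2 * C - 1
        kh = min(config.dw_kernel[0], H)
        kw = min(config.dw_kernel[1], W)
        for s, (depth, width) in enumerate(zip(config.stage_depths, config.stage_widths)):
            self.layers.append(Pointwise(f"s{s}.in", prev, width, rng))
            self.layers.append(LayerNorm(f"s{s}.ln", width))
            for d in range(depth):
                self.layers.append(ConvNeXtBlock(f"s{s}.b{d}", width, (kh, kw), rng))
            prev = width
        self.pool = GlobalAvgPool("pool")
        self.dropout = Dropout("drop", config.dropout, rng)
        self._n_skip = H * (C - 1) if config.interaction_stem else 0
        self.head = Dense("head", prev + self._n_skip, 1, rng)
        self.layers += [self.pool, self.dropout, self.head]
        self._stem_index = next(
            (i for i, l in enumerate(self.layers) if isinstance(l, InteractionStem)), None
        )

    # -- plumbing -----------------------------------------------------------

    def parameter_layers(self):
        return [l for l in _iter_layers(self.layers) if l.params]

    def count_params(self) -> int:
        return int(sum(p.size for l in self.parameter_layers() for p in l.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{l.name}/{k}": v.copy() for l in self.parameter_layers() for k, v in l.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.parameter_layers():
            for k in layer.params:
                key = f"{layer.name}/{k}"
                if key not in state:
                    raise KeyError(f"missing parameter {key}")
                if state[key].shape != layer.params[k].shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {state[key].shape} vs {layer.params[k].shape}"
                    )
                layer.params[k] = state[key].copy()

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.state_dict()):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.state_dict()[key]).tobytes())
        return h.hexdigest()[:16]

    # -- compute ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        skip = None
        for i, layer in enumerate(self.layers):
            if layer is self.head and skip is not None:
                h = np.concatenate([h, skip], axis=-1)
            h = layer.forward(h, train=train)
            if self._stem_index is not None and i == self._stem_index:
                # residual readout: the product channels pooled over core
                # positions (a per-row interaction profile) go to the head
                self._skip_shape = h.shape
                skip = h[..., self.input_shape[2]:].mean(axis=2).reshape(len(h), -1)
        return h[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        g = dlogit[:, None]
        g_skip = None
        for i in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[i]
            g = layer.backward(g)
            if layer is self.head and self._stem_index is not None:
                C_main = g.shape[-1] - self._n_skip
                g, g_skip = g[..., :C_main], g[..., C_main:]
            if self._stem_index is not None and i == self._stem_index + 1:
                # reinject the skip gradient at the interaction stem output
                N, H, W, _ = self._skip_shape
                add = np.zeros(self._skip_shape, dtype=g.dtype)
                add[..., self.input_shape[2]:] = \
                    g_skip.reshape(N, H, -1)[:, :, None, :] / W
                g = g + add

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Head output in (0, 1): AP probability or BA log50k target."""
        x = np.asarray(x, dtype=DTYPE)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(expit(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(outs) if outs else np.zeros(0)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        meta = {"config": asdict(self.config), "provenance": provenance or {},
                "state_hash": self.state_hash(), "n_params": self.count_params()}
        meta["config"]["stage_depths"] = list(self.config.stage_depths)
        meta["config"]["stage_widths"] = list(self.config.stage_widths)
        meta["config"]["dw_kernel"] = list(self.config.dw_kernel)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ConvNeXtMHCNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        c = meta["config"]
        config = ModelConfig(
            head=c["head"], stage_depths=tuple(c["stage_depths"]),
            stage_widths=tuple(c["stage_widths"]), dw_kernel=tuple(c["dw_kernel"]),
            attention_kernel_width=c["attention_kernel_width"],
            interaction_stem=c.get("interaction_stem", True), dropout=c["dropout"],
            learning_rate=c["learning_rate"],
            lr_decay_epochs=c.get("lr_decay_epochs", 8), batch_size=c["batch_size"],
            epochs=c["epochs"], patience=c["patience"], seed=c["seed"],
        )
        net = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net


class SimpleCNN:
    """Two plain convolution layers + pooling + dense head.

    The fixed reference architecture used for head-to-head encoding
    ablations: every encoding is judged by the identical network, so
    accuracy differences are attributable to the encoding alone. Accepts
    any (N, H, W, C) input with H, W >= 3. Inputs with the ILA's 21
    channels get the same interaction stem and row-resolved product
    readout as the full model (both computable only when an encoding
    carries a contact channel, and applied identically to every such
    encoding under comparison).
    """

    def __init__(self, input_shape: tuple[int, int, int], seed: int = 0,
                 widths: tuple[int, int] = (8, 16),
                 interaction_stem: bool | None = None):
        H, W, C = input_shape
        if H < 3 or W < 3:
            raise ValueError(f"input spatial extent {H}x{W} too small for 3x3 convolutions")
        if interaction_stem is None:
            interaction_stem = C == VECTOR_DIM
        self.input_shape = input_shape
        rng = np.random.default_rng(seed)
        c1, c2 = widths
        self.stem = InteractionStem("stem") if interaction_stem else None
        cin = 2 * C - 1 if interaction_stem else C
        self._n_skip = H * (C - 1) if interaction_stem else 0
        self.conv1 = Conv2DValid("conv1", cin, c1, (3, 3), rng)
        self.conv2 = Conv2DValid("conv2", c1, c2, (3, 3), rng)
        self.head = Dense("head", c2 + self._n_skip, 1, rng)
        self.layers: list[Layer] = [
            self.conv1, Relu("r1"), self.conv2, Relu("r2"), GlobalAvgPool("pool"),
            self.head,
        ]

    def parameter_layers(self):
        return [l for l in self.layers if l.params]

    def count_params(self) -> int:
        return int(sum(p.size for l in self.parameter_layers() for p in l.params.values()))

    def forward(self, x, train=False):
        skip = None
        h = x
        if self.stem is not None:
            h = self.stem.forward(h)
            self._skip_shape = h.shape
            skip = h[..., self.input_shape[2]:].mean(axis=2).reshape(len(h), -1)
        for layer in self.layers:
            if layer is self.head and skip is not None:
                h = np.concatenate([h, skip], axis=-1)
            h = layer.forward(h, train=train)
        return h[:, 0]

    def backward(self, dlogit):
        g = dlogit[:, None]
        g_skip = None
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if layer is self.head and self.stem is not None:
                g, g_skip = g[..., :-self._n_skip], g[..., -self._n_skip:]
        if self.stem is not None:
            N, H, W, _ = self._skip_shape
            add = np.zeros(self._skip_shape, dtype=g.dtype)
            add[..., self.input_shape[2]:] = g_skip.reshape(N, H, -1)[:, :, None, :] / W
            g = self.stem.backward(g + add)
        return g

    def predict(self, x, batch_size: int = 512):
        x = np.asarray(x, dtype=DTYPE)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(expit(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(outs) if outs else np.zeros(0)


class Conv2DValid(Layer):
    """Standard (cross-channel) KxL convolution, valid padding."""

    def __init__(self, name: str, cin: int, cout: int, kernel: tuple[int, int], rng):
        super().__init__(name)
        K, L = kernel
        self.kernel = kernel
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / (cin * K * L)), (K, L, cin, cout)).astype(DTYPE),
            "b": np.zeros(cout, dtype=DTYPE),
        }

    def forward(self, x, train=False):
        K, L = self.kernel
        self._x = x
        self._win = sliding_window_view(x, (K, L), axis=(1, 2))  # (N, Ho, Wo, C, K, L)
        return np.einsum("nijckl,klcd->nijd", self._win, self.params["W"], optimize=True) \
            + self.params["b"]

    def backward(self, g):
        K, L = self.kernel
        self.grads = {
            "W": np.einsum("nijckl,nijd->klcd", self._win, g, optimize=True),
            "b": g.sum(axis=(0, 1, 2)),
        }
        N, Ho, Wo, _ = g.shape
        dx = np.zeros_like(self._x)
        W = self.params["W"]
        for k in range(K):
            for l in range(L):
                dx[:, k:k + Ho, l:l + Wo, :] += g @ W[k, l].T
        return dx


# ---------------------------------------------------------------------------
# optimization

class Adam:
    """Adaptive-moment gradient descent over a network's parameter layers."""

    def __init__(self, net, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {f"{l.name}/{k}": np.zeros_like(v)
                  for l in net.parameter_layers() for k, v in l.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self) -> None:
        self.t += 1
        for layer in self.net.parameter_layers():
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                key = f"{layer.name}/{k}"
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / (1 - self.b1 ** self.t)
                vhat = self.v[key] / (1 - self.b2 ** self.t)
                p -= self.lr * layer.lr_scale * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training

class DivergenceError(RuntimeError):
    pass


def _loss_and_grad(logits: np.ndarray, y: np.ndarray, kind: str):
    n = len(y)
    if kind == "bce":
        # numerically stable softplus
        loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
        dlogit = (expit(logits) - y) / n
    elif kind == "mse":
        p = expit(logits)
        loss = float(np.mean((p - y) ** 2))
        dlogit = 2.0 * (p - y) * p * (1.0 - p) / n
    else:
        raise ValueError(f"unknown loss {kind!r}")
    return loss, dlogit


def evaluate_loss(net, x, y, kind: str, batch_size: int = 512) -> float:
    x = np.asarray(x, dtype=DTYPE)
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size], train=False)
        loss, _ = _loss_and_grad(logits, y[i:i + batch_size], kind)
        total += loss * len(logits)
        n += len(logits)
    return total / max(n, 1)


def fit_network(
    net,
    x: np.ndarray,
    y: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    loss: str = "bce",
    epochs: int | None = None,
    batch_size: int | None = None,
    learning_rate: float | None = None,
    patience: int | None = None,
    lr_decay_epochs: int | None = None,
    seed: int = 0,
) -> dict:
    """Minibatch Adam training with early stopping on validation loss.

    Returns a history dict with per-epoch train/val losses. Fully
    deterministic for a fixed seed and initial state. Raises
    :class:`DivergenceError` if the loss turns non-finite.
    """
    cfg = getattr(net, "config", None)
    epochs = epochs if epochs is not None else (cfg.epochs if cfg else 10)
    batch_size = batch_size if batch_size is not None else (cfg.batch_size if cfg else 64)
    learning_rate = learning_rate if learning_rate is not None else (cfg.learning_rate if cfg else 1e-3)
    patience = patience if patience is not None else (cfg.patience if cfg else 0)
    if lr_decay_epochs is None:
        lr_decay_epochs = getattr(cfg, "lr_decay_epochs", 0) if cfg else 0

    x = np.asarray(x, dtype=DTYPE)
    y = np.asarray(y, dtype=DTYPE)
    if x_val is not None:
        x_val = np.asarray(x_val, dtype=DTYPE)
        y_val = np.asarray(y_val, dtype=DTYPE)
    rng = np.random.default_rng(seed)
    opt = Adam(net, lr=learning_rate)
    history: dict = {"train_loss": [], "val_loss": [], "seed": seed, "loss": loss}
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    for epoch in range(epochs):
        if lr_decay_epochs and epoch > 0 and epoch % lr_decay_epochs == 0:
            opt.lr *= 0.5
        order = rng.permutation(len(x))
        running, seen = 0.0, 0
        for i in range(0, len(x), batch_size):
            idx = order[i:i + batch_size]
            logits = net.forward(x[idx], train=True)
            batch_loss, dlogit = _loss_and_grad(logits, y[idx], loss)
            if not np.isfinite(batch_loss):
                raise DivergenceError(
                    f"loss became non-finite at epoch {epoch}, batch {i // batch_size}"
                )
            net.backward(dlogit)
            opt.step()
            running += batch_loss * len(idx)
            seen += len(idx)
        history["train_loss"].append(running / seen)
        if x_val is not None and len(x_val):
            vloss = evaluate_loss(net, x_val, y_val, loss)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = net.state_dict()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if patience and bad_epochs >= patience:
                    break
    if best_state is not None:
        net.load_state_dict(best_state)
    return history


def transfer_weights(source: ConvNeXtMHCNet, target_head: str) -> ConvNeXtMHCNet:
    """Copy a trained backbone into a fresh model with a new head.

    All non-head parameters are copied; the head is reinitialized. The
    returned model's provenance (recorded on save) carries the source
    state hash via the ``transfer_source`` attribute.
    """
    if target_head not in ("ap", "ba"):
        raise ValueError("target_head must be 'ap' or 'ba'")
    cfg = ModelConfig(**{**asdict(source.config), "head": target_head})
    cfg.stage_depths = tuple(cfg.stage_depths)
    cfg.stage_widths = tuple(cfg.stage_widths)
    cfg.dw_kernel = tuple(cfg.dw_kernel)
    target = ConvNeXtMHCNet(cfg, attention_init=source.attention.params["bias"].copy())
    state = source.state_dict()
    head_keys = {k for k in state if k.startswith("head/")}
    for k in head_keys:
        state[k] = target.state_dict()[k]
    target.load_state_dict(state)
    target.transfer_source = source.state_hash()
    return target
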