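"""Minimal dense/sparse feed-forward layers with explicit gradients.

A deliberately small numpy engine: each layer caches what its backward
pass needs, gradients are written by hand and verified against finite
differences in the test suite. This keeps the dependency surface to
numpy/scipy while supporting masked (knowledge-sparsified) linear maps
whose off-mask weights do not exist at all — so their gradients are
structurally zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Parameter",
    "Layer",
    "Dense",
    "MaskedDense",
    "LayerNorm",
    "Tanh",
    "SliceColumns",
    "GeneScorer",
    "SequentialNet",
    "count_parameters",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward caches, backward consumes the cache once."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _accumulate(self, param: Parameter, grad: np.ndarray) -> None:
        # frozen parameters keep an identically-zero gradient
        if param.trainable:
            param.grad += grad


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Dense(Layer):
    """Affine map ``y = x @ W + b`` (bias optional)."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        bias: bool = True,
        name: str = "dense",
    ):
        self.n_in, self.n_out = n_in, n_out
        self.W = Parameter(_fan_in_uniform(rng, (n_in, n_out), n_in), f"{name}.W")
        self.b = (
            Parameter(_fan_in_uniform(rng, (n_out,), n_in), f"{name}.b")
            if bias
            else None
        )
        self._x: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        self._accumulate(self.W, x.T @ grad_out)
        if self.b is not None:
            self._accumulate(self.b, grad_out.sum(axis=0))
        return grad_out @ self.W.value.T


class MaskedDense(Layer):
    """Sparse linear map whose only weights sit on mask edges.

    The weight vector holds exactly one scalar per nonzero of the binary
    ``mask`` (shape ``n_in x n_out``); positions outside the mask do not
    exist, so their gradients are structurally zero. A single shared
    scalar offset is added to every output when ``shared_bias`` is on.
    """

    def __init__(
        self,
        mask: np.ndarray,
        rng: np.random.Generator,
        shared_bias: bool = True,
        name: str = "masked",
    ):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.n_in, self.n_out = mask.shape
        csr = sp.csr_matrix(mask.astype(np.float64))
        coo = csr.tocoo()
        self.rows = coo.row.copy()
        self.cols = coo.col.copy()
        self._csr = csr
        fan_in = np.maximum(mask.sum(axis=0), 1)  # per-output fan-in
        bound = 1.0 / np.sqrt(fan_in[self.cols])
        init = rng.uniform(-1.0, 1.0, size=len(self.cols)) * bound
        self.w = Parameter(init, f"{name}.w")
        self.b = Parameter(np.zeros(()), f"{name}.b") if shared_bias else None
        self._x: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return len(self.cols)

    def params(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def _matrix(self) -> sp.csr_matrix:
        self._csr.data = self.w.value
        return self._csr

    def dense_weight(self) -> np.ndarray:
        """Materialised ``n_in x n_out`` weight matrix (zeros off-mask)."""
        return self._matrix().toarray()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = self._matrix().T.dot(x.T).T
        if self.b is not None:
            y = y + self.b.value
        return np.asarray(y)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        gw = (x[:, self.rows] * grad_out[:, self.cols]).sum(axis=0)
        self._accumulate(self.w, gw)
        if self.b is not None:
            self._accumulate(self.b, np.asarray(grad_out.sum()))
        return np.asarray(self._matrix().dot(grad_out.T).T)


class LayerNorm(Layer):
    """Per-row normalisation with affine gain and offset (2H params)."""

    def __init__(self, n: int, name: str = "ln", eps: float = 1e-5):
        self.n = n
        self.eps = eps
        self.gain = Parameter(np.ones(n), f"{name}.gain")
        self.offset = Parameter(np.zeros(n), f"{name}.offset")
        self._cache: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.gain, self.offset]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return self.gain.value * xhat + self.offset.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._accumulate(self.gain, (grad_out * xhat).sum(axis=0))
        self._accumulate(self.offset, grad_out.sum(axis=0))
        dxhat = grad_out * self.gain.value
        n = self.n
        return (
            inv
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
            )
        )


class Tanh(Layer):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * (1.0 - self._y**2)


class SliceColumns(Layer):
    """Keep the first ``n`` columns; backward zero-pads the rest."""

    def __init__(self, n: int):
        self.n = n
        self._width: int | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._width = x.shape[-1]
        return x[..., : self.n]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grad = np.zeros(grad_out.shape[:-1] + (self._width,))
        grad[..., : self.n] = grad_out
        return grad


class GeneScorer(Layer):
    """Shared two-layer compressor: each gene's 17-vector -> one scalar.

    The same weights are applied to every gene, so permuting the gene
    axis commutes with the forward pass. Input ``(N, G, n_types)``,
    output ``(N, G)``.
    """

    def __init__(self, n_types: int, hidden: int, rng: np.random.Generator):
        self.n_types = n_types
        self.hidden = hidden
        self.fc1 = Dense(n_types, hidden, rng, name="gene.fc1")
        self.act = Tanh()
        self.fc2 = Dense(hidden, 1, rng, name="gene.fc2")
        self._shape: tuple | None = None

    def params(self) -> list[Parameter]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, g, t = x.shape
        if t != self.n_types:
            raise ValueError(f"expected {self.n_types} types, got {t}")
        self._shape = (n, g)
        flat = x.reshape(n * g, t)
        out = self.fc2.forward(self.act.forward(self.fc1.forward(flat)))
        return out.reshape(n, g)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, g = self._shape
        grad = grad_out.reshape(n * g, 1)
        grad = self.fc1.backward(self.act.backward(self.fc2.backward(grad)))
        return grad.reshape(n, g, self.n_types)


class SequentialNet:
    """An ordered stack of layers with an explicit body/head boundary.

    ``latent_index`` marks how many leading layers form the feature
    extractor ("body"); the remaining layers are the task head. The body
    output is the latent representation reused by transfer learning.
    """

    def __init__(
        self,
        layers: Sequence[Layer],
        latent_index: int | None = None,
        latent_dim: int | None = None,
        input_kind: str = "tensor",
    ):
        self.layers = list(layers)
        self.latent_index = len(self.layers) if latent_index is None else latent_index
        self.latent_dim = latent_dim
        self.input_kind = input_kind

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def latent(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers[: self.latent_index]:
            x = layer.forward(x)
        return x

    def body_params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers[: self.latent_index]:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- flat state for checkpoints -------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"{i}:{p.name}": p.value for i, p in enumerate(self.params())}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            key = f"{i}:{p.name}"
            if key not in state:
                raise KeyError(f"checkpoint is missing parameter {key}")
            if state[key].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.value = np.asarray(state[key], dtype=np.float64).copy()
            p.grad = np.zeros_like(p.value)


def count_parameters(component) -> int:
    """Exact count of trainable scalars in a layer or network.

    Masked layers contribute only their on-mask weights (plus the shared
    offset), so knowledge-sparsified trunks are counted at their true
    size.
    """
    return int(sum(p.size for p in component.params() if p.trainable))
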