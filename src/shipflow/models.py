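"""Gravity-informed flow models.

Two architectures score the candidate destination regions of a source port;
the scores are turned into flow allocations by a softmax scaled by the total
outflow (see :mod:`shipflow.evaluate`):

* **Transformer gravity** -- a linear embedding into a 64-dimensional space
  followed by a stack of transformer encoder blocks (2-head self-attention,
  residual + layer norm, position-wise feed-forward, dropout 0.1) and a
  scalar output head. No positional encoding is used: the destination
  regions of a sample form an unordered set, and the model is
  permutation-equivariant over them.
* **Deep gravity** -- the MLP baseline: ``k`` hidden layers with leaky-ReLU
  activations, the first k/3 of width 256 and the remaining 2k/3 of width
  128, and a scalar output.

Both operate on one sample at a time (an N x 10 feature matrix, N <= 17);
samples of varying N cannot be batched, matching batch size 1 training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, softmax

LAYERNORM_EPS = 1e-5


@dataclass(frozen=True)
class TransformerGravitySpec:
    input_dim: int = 10
    embed_dim: int = 64
    heads: int = 2
    encoder_layers: int = 3
    ffn_dim: int = 256
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        if self.encoder_layers < 1:
            raise ValueError("need at least one encoder layer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads


@dataclass(frozen=True)
class DeepGravitySpec:
    input_dim: int = 10
    total_hidden_layers: int = 15
    wide_dim: int = 256
    narrow_dim: int = 128
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.total_hidden_layers % 3 != 0 or self.total_hidden_layers < 3:
            raise ValueError("total_hidden_layers must be a positive multiple of 3")

    @property
    def widths(self) -> list[int]:
        """Hidden widths: k/3 wide layers then 2k/3 narrow layers (1:2 ratio)."""
        k = self.total_hidden_layers
        return [self.wide_dim] * (k // 3) + [self.narrow_dim] * (2 * k // 3)


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def _check_input(X: np.ndarray, input_dim: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != input_dim:
        raise ValueError(f"expected an (N, {input_dim}) feature matrix, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the feature matrix")
    return X


class _ModelBase:
    """Shared parameter bookkeeping for the NumPy models."""

    params: dict[str, Tensor]

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = state[k].copy()

    def _dropout(self, x: Tensor, p: float, mode: str, rng: np.random.Generator | None) -> Tensor:
        if mode != "train" or p <= 0.0:
            return x
        if rng is None:
            raise ValueError("train-mode forward needs an rng for dropout")
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)


class TransformerGravity(_ModelBase):
    """Transformer-encoder scoring model over destination-region feature rows."""

    def __init__(self, spec: TransformerGravitySpec = TransformerGravitySpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, f = spec.embed_dim, spec.ffn_dim
        p: dict[str, Tensor] = {
            "embed.W": Tensor(_glorot(rng, d, spec.input_dim)),
            "embed.b": Tensor(np.zeros(d)),
        }
        for layer in range(spec.encoder_layers):
            pre = f"enc{layer}."
            p[pre + "Wqkv"] = Tensor(_glorot(rng, 3 * d, d))
            p[pre + "bqkv"] = Tensor(np.zeros(3 * d))
            p[pre + "Wo"] = Tensor(_glorot(rng, d, d))
            p[pre + "bo"] = Tensor(np.zeros(d))
            p[pre + "ln1.a"] = Tensor(np.ones(d))
            p[pre + "ln1.b"] = Tensor(np.zeros(d))
            p[pre + "W1"] = Tensor(_glorot(rng, f, d))
            p[pre + "b1"] = Tensor(np.zeros(f))
            p[pre + "W2"] = Tensor(_glorot(rng, d, f))
            p[pre + "b2"] = Tensor(np.zeros(d))
            p[pre + "ln2.a"] = Tensor(np.ones(d))
            p[pre + "ln2.b"] = Tensor(np.zeros(d))
        p["out.W"] = Tensor(_glorot(rng, 1, d))
        p["out.b"] = Tensor(np.zeros(1))
        self.params = p

    def _layernorm(self, x: Tensor, a: Tensor, b: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + LAYERNORM_EPS).sqrt() * a + b

    def _attention(self, z: Tensor, layer: int) -> Tensor:
        spec, p = self.spec, self.params
        d, dk = spec.embed_dim, spec.head_dim
        pre = f"enc{layer}."
        qkv = z @ p[pre + "Wqkv"].T + p[pre + "bqkv"]
        heads = []
        for h in range(spec.heads):
            q = qkv[:, h * dk:(h + 1) * dk]
            k = qkv[:, d + h * dk:d + (h + 1) * dk]
            v = qkv[:, 2 * d + h * dk:2 * d + (h + 1) * dk]
            att = softmax(q @ k.T * (1.0 / np.sqrt(dk)), axis=-1)
            heads.append(att @ v)
        cat = heads[0] if len(heads) == 1 else concat(heads, axis=-1)
        return cat @ p[pre + "Wo"].T + p[pre + "bo"]

    def forward(self, X, mode: str = "eval", rng: np.random.Generator | None = None) -> Tensor:
        """Score the N destination rows of one sample; returns a length-N tensor."""
        spec, p = self.spec, self.params
        Xv = _check_input(X, spec.input_dim)
        z = Tensor(Xv) @ p["embed.W"].T + p["embed.b"]
        for layer in range(spec.encoder_layers):
            pre = f"enc{layer}."
            attn = self._dropout(self._attention(z, layer), spec.dropout, mode, rng)
            z2 = self._layernorm(z + attn, p[pre + "ln1.a"], p[pre + "ln1.b"])
            h = self._dropout((z2 @ p[pre + "W1"].T + p[pre + "b1"]).relu(),
                              spec.dropout, mode, rng)
            h = self._dropout(h @ p[pre + "W2"].T + p[pre + "b2"], spec.dropout, mode, rng)
            z = self._layernorm(h + z2, p[pre + "ln2.a"], p[pre + "ln2.b"])
        return (z @ p["out.W"].T + p["out.b"]).reshape(-1)


class DeepGravity(_ModelBase):
    """Feed-forward baseline scoring each destination row independently."""

    def __init__(self, spec: DeepGravitySpec = DeepGravitySpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        fan_in = spec.input_dim
        for i, width in enumerate(spec.widths):
            p[f"h{i}.W"] = Tensor(_glorot(rng, width, fan_in))
            p[f"h{i}.b"] = Tensor(np.zeros(width))
            fan_in = width
        p["out.W"] = Tensor(_glorot(rng, 1, fan_in))
        p["out.b"] = Tensor(np.zeros(1))
        self.params = p

    def forward(self, X, mode: str = "eval", rng: np.random.Generator | None = None) -> Tensor:
        spec, p = self.spec, self.params
        Xv = _check_input(X, spec.input_dim)
        z = Tensor(Xv)
        for i in range(len(spec.widths)):
            z = (z @ p[f"h{i}.W"].T + p[f"h{i}.b"]).leaky_relu(spec.negative_slope)
        return (z @ p["out.W"].T + p["out.b"]).reshape(-1)


def build_model(spec, seed: int = 0) -> _ModelBase:
    """Instantiate the model matching a spec."""
    if isinstance(spec, TransformerGravitySpec):
        return TransformerGravity(spec, seed)
    if isinstance(spec, DeepGravitySpec):
        return DeepGravity(spec, seed)
    raise TypeError(f"unknown model spec {type(spec).__name__}")


def count_params(spec) -> int:
    """Exact number of trainable scalars (weights, biases, layer-norm affines)."""
    return build_model(spec, seed=0).n_params()
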