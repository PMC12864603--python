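"""Parameter containers, layers and the Adam optimizer used by both encoders.

Parameters live in a flat, ordered ``dict[str, Tensor]`` so that counting,
checkpointing and optimization never depend on object topology.  All random
initialization draws from a caller-supplied :class:`numpy.random.Generator`,
which is how the fixed-seed bit-reproducibility contract is met.
"""

from __future__ import annotations

import hashlib
from typing import Dict, Iterable

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

ParamDict = Dict[str, Tensor]


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-component seed: adding components never reshuffles streams."""
    digest = hashlib.sha256(f"{int(seed)}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rng_for(seed: int, tag: str) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(derive_seed(seed, tag)))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def uniform_init(rng: np.random.Generator, shape, scale: float | None = None,
                 dtype=np.float64) -> Tensor:
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        scale = 1.0 / np.sqrt(max(fan_in, 1))
    data = rng.uniform(-scale, scale, size=shape).astype(dtype)
    return Tensor(data, requires_grad=True)


def zeros_init(shape, dtype=np.float64) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def constant_init(shape, value: float, dtype=np.float64) -> Tensor:
    return Tensor(np.full(shape, value, dtype=dtype), requires_grad=True)


def add_linear(params: ParamDict, name: str, rng: np.random.Generator,
               n_in: int, n_out: int, bias: bool = True, dtype=np.float64) -> None:
    params[f"{name}.W"] = uniform_init(rng, (n_in, n_out), dtype=dtype)
    if bias:
        params[f"{name}.b"] = zeros_init((n_out,), dtype=dtype)


def linear(params: ParamDict, name: str, x: Tensor) -> Tensor:
    out = ad.matmul(x, params[f"{name}.W"])
    b = params.get(f"{name}.b")
    if b is not None:
        out = ad.add(out, b)
    return out


def add_layer_norm(params: ParamDict, name: str, dim: int, dtype=np.float64) -> None:
    params[f"{name}.gamma"] = constant_init((dim,), 1.0, dtype=dtype)
    params[f"{name}.beta"] = zeros_init((dim,), dtype=dtype)


def layer_norm(params: ParamDict, name: str, x: Tensor, eps: float = 1e-5) -> Tensor:
    mu = ad.mean_(x, axis=-1, keepdims=True)
    centered = ad.add(x, ad.mul(mu, -1.0))
    var = ad.mean_(ad.mul(centered, centered), axis=-1, keepdims=True)
    inv = ad.power(ad.add(var, eps), -0.5)
    normed = ad.mul(centered, inv)
    return ad.add(ad.mul(normed, params[f"{name}.gamma"]), params[f"{name}.beta"])


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
    return ad.mul(x, mask)


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

def count_params(params: ParamDict, prefix: str = "") -> int:
    return int(sum(t.data.size for name, t in params.items()
                   if name.startswith(prefix)))


def clone_params(params: ParamDict) -> ParamDict:
    return {k: Tensor(v.data.copy(), requires_grad=v.requires_grad)
            for k, v in params.items()}


def zero_grads(params: ParamDict) -> None:
    for t in params.values():
        t.grad = None


def global_grad_norm(params: ParamDict) -> float:
    total = 0.0
    for t in params.values():
        if t.grad is not None:
            total += float(np.sum(t.grad.astype(np.float64) ** 2))
    return float(np.sqrt(total))


class Adam:
    """Adam with decoupled weight decay (AdamW-style) and global-norm clipping."""

    def __init__(self, params: ParamDict, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self._m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.clip_norm is not None:
            norm = global_grad_norm(self.params)
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            m = self._m[k] = self.beta1 * self._m[k] + (1.0 - self.beta1) * g
            v = self._v[k] = self.beta2 * self._v[k] + (1.0 - self.beta2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update


def iter_minibatches(n: int, batch_size: int,
                     rng: np.random.Generator) -> Iterable[np.ndarray]:
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
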