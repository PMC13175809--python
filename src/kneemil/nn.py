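"""Neural-network layers and the AdamW optimizer on top of ``autodiff``.

Layers follow the usual conventions: ``Linear`` stores its weight as
(in_features, out_features); initialization is Kaiming-uniform for
ReLU paths and Glorot-uniform elsewhere, drawn from an explicit
``numpy.random.Generator`` so every model build is seedable.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d, relu, tanh


class Module:
    """Minimal container: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        bound = float(np.sqrt(6.0 / (in_features + out_features)))
        self.weight = Tensor(_uniform(rng, (in_features, out_features), bound),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        bound = float(np.sqrt(6.0 / fan_in))  # Kaiming-uniform for ReLU blocks
        self.weight = Tensor(_uniform(rng, (out_ch, in_ch, kernel, kernel), bound),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over token sequences (N, T, E)."""

    def __init__(self, embed_dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if embed_dim % heads:
            raise ValueError(f"embed_dim {embed_dim} not divisible by "
                             f"heads {heads}")
        self.heads = heads
        self.head_dim = embed_dim // heads
        self.q_proj = Linear(embed_dim, embed_dim, rng)
        self.k_proj = Linear(embed_dim, embed_dim, rng)
        self.v_proj = Linear(embed_dim, embed_dim, rng)
        self.out_proj = Linear(embed_dim, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import softmax
        n, t, e = x.shape
        h, d = self.heads, self.head_dim

        def split(z: Tensor) -> Tensor:
            return z.reshape(n, t, h, d).transpose(0, 2, 1, 3)  # (N,h,T,d)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, e)
        return self.out_proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MHA(LN(x)); x + FF(LN(x)), FF width 2E, ReLU."""

    def __init__(self, embed_dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(embed_dim)
        self.attn = MultiHeadSelfAttention(embed_dim, heads, rng)
        self.ln2 = LayerNorm(embed_dim)
        self.ff1 = Linear(embed_dim, 2 * embed_dim, rng)
        self.ff2 = Linear(2 * embed_dim, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(relu(self.ff1(self.ln2(x))))

    def zero_residual_(self) -> None:
        """Zero the residual-branch outputs so the block is the identity map."""
        self.attn.out_proj.weight.data[:] = 0.0
        self.attn.out_proj.bias.data[:] = 0.0
        self.ff2.weight.data[:] = 0.0
        self.ff2.bias.data[:] = 0.0


class AdamW:
    """Decoupled-weight-decay Adam (betas 0.9/0.999, eps 1e-8 by default)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
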