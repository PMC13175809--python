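"""Slice encoder, slice-aggregation strategies and the three-view classifier.

The exam-level model treats each study as three ordered bags of slices
(sagittal, coronal, axial).  A shared per-slice encoder maps every
R x R slice to a D-dimensional embedding.  Within each view the slice
sequence is summarized by one of four aggregators:

* ``multiscale_attention`` — the full aggregator: sliding-window mean
  pooling along the slice axis at several odd kernel sizes (truncated
  windows at the stack edges), a scale-specific linear projection
  D -> E, learned scale and positional embeddings, pre-norm multi-head
  self-attention layers over the concatenated token sets, and a learned
  query that softmax-reads the tokens into one E-vector per view;
* ``mean`` / ``max`` — coordinate-wise pooling over slices followed by
  a D -> E projection (standard non-learned aggregation baselines);
* ``attention_mil`` — gated attention-based multiple-instance pooling
  (tanh/sigmoid gates, softmax slice weights) followed by projection.

The three view embeddings are fused by concatenation and a two-layer
MLP with ReLU and dropout, producing three logits whose sigmoids are the
exam probabilities for (abnormal, ACL tear, meniscus tear).  No post-hoc
temperature scaling is applied, so the sigmoid outputs are the reported
calibrated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError, ContractError
from .nn import Conv2d, Linear, Module, TransformerBlock

N_LABELS = 3
AGGREGATORS = ("multiscale_attention", "mean", "max", "attention_mil")
FUSIONS = ("learned", "average")


@dataclass(frozen=True)
class ModelConfig:
    encoder_dim: int = 2048          # D; reference-scale value
    embed_dim: int = 256             # E
    heads: int = 4
    attn_layers: int = 2
    pool_kernels: tuple[int, ...] = (1, 3, 5)
    mlp_hidden: int = 512
    dropout: float = 0.2
    positional_encoding: bool = True
    aggregator: str = "multiscale_attention"
    fusion: str = "learned"
    encoder_channels: tuple[int, ...] = (16, 32, 64)
    mil_hidden: int = 64

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} must be divisible by heads "
                f"{self.heads}")
        for k in self.pool_kernels:
            if k < 1 or k % 2 == 0:
                raise ConfigurationError(
                    f"pool_kernels must be odd positive integers, got {k}")
        if self.aggregator not in AGGREGATORS:
            raise ConfigurationError(
                f"unknown aggregator {self.aggregator!r}; valid: {AGGREGATORS}")
        if self.fusion not in FUSIONS:
            raise ConfigurationError(
                f"unknown fusion {self.fusion!r}; valid: {FUSIONS}")

    @staticmethod
    def tiny(**overrides) -> "ModelConfig":
        """Desk-scale configuration used throughout the test suite."""
        base = dict(encoder_dim=32, embed_dim=32, heads=4, attn_layers=1,
                    pool_kernels=(1, 3, 5), mlp_hidden=64, dropout=0.2,
                    encoder_channels=(8, 16, 24), mil_hidden=16)
        base.update(overrides)
        return ModelConfig(**base)


@dataclass
class SliceEmbeddingSequence:
    view: str
    embeddings: np.ndarray           # (S, D)


@dataclass
class ViewEmbedding:
    view: str
    vector: np.ndarray               # (E,)
    weights: np.ndarray | None = None  # readout weights over tokens/slices


@dataclass
class ExamPrediction:
    """Calibrated probabilities and logits for (abnormal, acl, meniscus)."""
    probabilities: np.ndarray
    logits: np.ndarray

    def __post_init__(self):
        assert np.allclose(self.probabilities,
                           1.0 / (1.0 + np.exp(-self.logits)), atol=1e-7)


# -- encoders ----------------------------------------------------------------

class ConvSliceEncoder(Module):
    """Strided convolutional slice encoder: 1 -> c1 -> c2 -> c3 -> D
    channels (3x3 kernels, stride 2, ReLU) with global average pooling."""

    def __init__(self, encoder_dim: int, rng: np.random.Generator,
                 channels: tuple[int, ...] = (16, 32, 64)):
        super().__init__()
        plan = (1, *channels, encoder_dim)
        self.blocks = [Conv2d(plan[i], plan[i + 1], 3, rng, stride=2,
                              padding=1) for i in range(len(plan) - 1)]
        self.out_dim = encoder_dim

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, 1, R, R) -> (N, D)
        for block in self.blocks:
            x = ad.relu(block(x))
        return x.mean(axis=(2, 3))


class MeanPixelEncoder(Module):
    """Analytic test double: mean pixel intensity copied D-fold."""

    def __init__(self, encoder_dim: int):
        super().__init__()
        self.out_dim = encoder_dim

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=(1, 2, 3))
        return m.reshape(-1, 1) @ Tensor(np.ones((1, self.out_dim),
                                                 dtype=np.float32))


def encode_slices(view_stack: np.ndarray, encoder: Module,
                  view: str = "") -> SliceEmbeddingSequence:
    """Encode an (S, R, R) stack slice-by-slice into an (S, D) sequence."""
    if view_stack.ndim != 3:
        raise ContractError(f"expected rank-3 view stack, got rank "
                            f"{view_stack.ndim}")
    x = Tensor(view_stack[:, None, :, :].astype(np.float32))
    emb = encoder(x)
    if emb.data.ndim != 2 or emb.data.shape[0] != view_stack.shape[0]:
        raise ContractError(
            f"encoder contract violated: expected ({view_stack.shape[0]}, D), "
            f"got {emb.data.shape}")
    return SliceEmbeddingSequence(view=view, embeddings=emb.data)


# -- multi-scale attention aggregator ---------------------------------------

def moving_average_matrix(S: int, kernel: int) -> np.ndarray:
    """Row-stochastic (S, S) matrix for stride-1 mean pooling with window
    ``kernel``, averaging over the valid entries at truncated boundaries."""
    if kernel < 1 or kernel % 2 == 0:
        raise ConfigurationError(f"kernel must be odd positive, got {kernel}")
    half = kernel // 2
    mat = np.zeros((S, S), dtype=np.float32)
    for i in range(S):
        lo, hi = max(0, i - half), min(S, i + half + 1)
        mat[i, lo:hi] = 1.0 / (hi - lo)
    return mat


class MultiScaleAttentionAggregator(Module):
    """Multi-scale temporal pooling + self-attention + learned-query readout."""

    def __init__(self, config: ModelConfig, S: int, rng: np.random.Generator):
        super().__init__()
        D, E = config.encoder_dim, config.embed_dim
        self.config = config
        self.S = S
        self.pool_mats = [Tensor(moving_average_matrix(S, k))
                          for k in config.pool_kernels]
        self.scale_projs = [Linear(D, E, rng) for _ in config.pool_kernels]
        self.scale_emb = Tensor(
            (0.02 * rng.standard_normal((len(config.pool_kernels), E))
             ).astype(np.float32), requires_grad=True)
        self.pos_emb = Tensor((0.02 * rng.standard_normal((S, E))
                               ).astype(np.float32), requires_grad=True) \
            if config.positional_encoding else None
        self.blocks = [TransformerBlock(E, config.heads, rng)
                       for _ in range(config.attn_layers)]
        self.readout_query = Tensor(
            (0.02 * rng.standard_normal(E)).astype(np.float32),
            requires_grad=True)

    def multiscale_tokens(self, seq: Tensor) -> Tensor:
        """(N, S, D) slice embeddings -> (N, n_kernels*S, E) tokens."""
        token_sets = []
        for i, (mat, proj) in enumerate(zip(self.pool_mats, self.scale_projs)):
            pooled = mat @ seq                   # truncated-window averaging
            tokens = proj(pooled) + self.scale_emb[i]
            if self.pos_emb is not None:
                tokens = tokens + self.pos_emb
            token_sets.append(tokens)
        return ad.concatenate(token_sets, axis=1)

    def attend(self, tokens: Tensor) -> tuple[Tensor, Tensor]:
        """Transform tokens and read them out with the learned query.
        Returns (summary (N, E), readout weights (N, T))."""
        x = tokens
        for block in self.blocks:
            x = block(x)
        scores = (x @ self.readout_query) * \
            (1.0 / np.sqrt(self.config.embed_dim))
        weights = ad.softmax(scores, axis=-1)        # (N, T)
        n, t, e = x.shape
        summary = (weights.reshape(n, 1, t) @ x).reshape(n, e)
        return summary, weights

    def forward(self, seq: Tensor) -> tuple[Tensor, Tensor]:
        return self.attend(self.multiscale_tokens(seq))

    def zero_attention_(self) -> None:
        """Neutralize every learned aggregation component: attention blocks
        become identities, scale/positional embeddings and the readout
        query are zeroed.  With pool_kernels=(1,) the aggregator then
        equals mean pooling through scale projection 0."""
        for block in self.blocks:
            block.zero_residual_()
        self.scale_emb.data[:] = 0.0
        if self.pos_emb is not None:
            self.pos_emb.data[:] = 0.0
        self.readout_query.data[:] = 0.0


# -- baseline aggregators ----------------------------------------------------

class MeanPoolAggregator(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(config.encoder_dim, config.embed_dim, rng)

    def forward(self, seq: Tensor) -> tuple[Tensor, Tensor]:
        n, s, _ = seq.shape
        uniform = Tensor(np.full((n, s), 1.0 / s, dtype=np.float32))
        return self.proj(seq.mean(axis=1)), uniform


class MaxPoolAggregator(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(config.encoder_dim, config.embed_dim, rng)

    def forward(self, seq: Tensor) -> tuple[Tensor, Tensor]:
        n, s, _ = seq.shape
        uniform = Tensor(np.full((n, s), 1.0 / s, dtype=np.float32))
        return self.proj(seq.max(axis=1)), uniform


class AttentionMILAggregator(Module):
    """Gated attention-MIL pooling: a_i ∝ exp(w^T (tanh(V h_i) ⊙ σ(U h_i)))."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        D, L = config.encoder_dim, config.mil_hidden
        self.V = Linear(D, L, rng)
        self.U = Linear(D, L, rng)
        self.w = Linear(L, 1, rng)
        self.proj = Linear(D, config.embed_dim, rng)

    def forward(self, seq: Tensor) -> tuple[Tensor, Tensor]:
        n, s, _ = seq.shape
        gated = ad.tanh(self.V(seq)) * ad.sigmoid(self.U(seq))
        scores = self.w(gated).reshape(n, s)
        weights = ad.softmax(scores, axis=-1)
        summary = (weights.reshape(n, 1, s) @ seq).reshape(n, -1)
        return self.proj(summary), weights


def build_aggregator(config: ModelConfig, S: int,
                     rng: np.random.Generator) -> Module:
    if config.aggregator == "multiscale_attention":
        return MultiScaleAttentionAggregator(config, S, rng)
    if config.aggregator == "mean":
        return MeanPoolAggregator(config, rng)
    if config.aggregator == "max":
        return MaxPoolAggregator(config, rng)
    return AttentionMILAggregator(config, rng)


# -- fusion and the full model ----------------------------------------------

class FusionClassifier(Module):
    """Concat(3E) -> Linear(hidden) -> ReLU -> Dropout -> Linear(3) logits.
    ``fusion='average'`` replaces concatenation by the view-embedding mean
    (the 'view averaging' ablation), keeping the same MLP head shape."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        in_dim = 3 * config.embed_dim if config.fusion == "learned" \
            else config.embed_dim
        self.fc1 = Linear(in_dim, config.mlp_hidden, rng)
        self.fc2 = Linear(config.mlp_hidden, N_LABELS, rng)
        self._rng = np.random.default_rng(int(rng.integers(2 ** 31)))

    def forward(self, view_embeddings: list[Tensor]) -> Tensor:
        if len(view_embeddings) != 3:
            raise ContractError(
                f"expected 3 view embeddings in (sagittal, coronal, axial) "
                f"order, got {len(view_embeddings)}")
        if self.config.fusion == "learned":
            fused = ad.concatenate(view_embeddings, axis=-1)
        else:
            fused = (view_embeddings[0] + view_embeddings[1]
                     + view_embeddings[2]) * (1.0 / 3.0)
        h = ad.relu(self.fc1(fused))
        h = ad.dropout(h, self.config.dropout, self._rng, self.training)
        return self.fc2(h)


def fuse_and_classify(view_embeddings: list[ViewEmbedding],
                      head: FusionClassifier) -> ExamPrediction:
    """Fuse three view embeddings (fixed sagittal/coronal/axial order)."""
    tensors = [Tensor(v.vector.reshape(1, -1).astype(np.float32))
               for v in view_embeddings]
    logits = head(tensors).data.reshape(-1)
    return ExamPrediction(probabilities=1.0 / (1.0 + np.exp(-logits)),
                          logits=logits)


class ExamClassifier(Module):
    """End-to-end exam model: shared slice encoder, shared per-view
    aggregator, and the fusion head."""

    def __init__(self, config: ModelConfig, S: int, seed: int = 0,
                 encoder: Module | None = None):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.S = S
        self.encoder = encoder if encoder is not None else ConvSliceEncoder(
            config.encoder_dim, rng, config.encoder_channels)
        self.aggregator = build_aggregator(config, S, rng)
        self.head = FusionClassifier(config, rng)

    def forward(self, x: np.ndarray) -> dict:
        """x: (B, 3, S, R, R) -> dict with 'logits' (B,3) Tensor,
        'probabilities' ndarray, 'view_weights' (B, 3, T) ndarray."""
        if x.ndim != 5 or x.shape[1] != 3:
            raise ContractError(f"expected (B, 3, S, R, R), got {x.shape}")
        b, _, s, r, _ = x.shape
        dtype = np.float64 if x.dtype == np.float64 else np.float32
        flat = Tensor(np.ascontiguousarray(
            x.reshape(b * 3 * s, 1, r, r), dtype=dtype))
        emb = self.encoder(flat).reshape(b * 3, s, -1)
        summary, weights = self.aggregator(emb)
        e = summary.shape[-1]
        per_view = summary.reshape(b, 3, e)
        logits = self.head([per_view[:, v, :] for v in range(3)])
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        return {"logits": logits, "probabilities": probs,
                "view_weights": weights.data.reshape(b, 3, -1)}

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Deterministic evaluation-mode probabilities, batched."""
        was_training = self.training
        self.eval()
        try:
            chunks = [self.forward(x[i:i + batch_size])["probabilities"]
                      for i in range(0, x.shape[0], batch_size)]
        finally:
            if was_training:
                self.train()
        return np.concatenate(chunks, axis=0)


# -- losses ------------------------------------------------------------------

_EPS = 1e-7


def bce_loss(probabilities, labels) -> Tensor:
    """Mean binary cross-entropy over labels and batch; probabilities are
    clamped to [1e-7, 1 - 1e-7]."""
    p = probabilities if isinstance(probabilities, Tensor) \
        else Tensor(np.asarray(probabilities, dtype=np.float64))
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ContractError(f"shape mismatch: predictions {p.shape} vs "
                            f"labels {y.shape}")
    p = ad.clip(p, _EPS, 1.0 - _EPS)
    ll = Tensor(y) * ad.log(p) + Tensor(1.0 - y) * ad.log(1.0 - p)
    return -ll.mean()


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable BCE on logits (identical function of the data)."""
    y = Tensor(np.asarray(labels, dtype=np.float32))
    z = logits
    abs_z = ad.relu(z) + ad.relu(-z)
    return (ad.relu(z) - z * y + ad.log(ad.exp(-abs_z) + 1.0)).mean()
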