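"""Multimodal framework extensions — not part of the benchmarked model.

These units formalize the general multimodal formulation around the
visual-only exam classifier: cross-modal fusion of visual, temporal and
auxiliary feature vectors, adaptive modality weighting, a feature
alignment regularizer, attention reweighting with a recurrent context
state, a focal-style risk loss, and hierarchical output combination.
No public benchmark provides the temporal/biomechanical or auxiliary
streams these operate on, so every unit here is a composable,
individually tested building block that the benchmarked visual-only
configuration deliberately leaves switched off (see
:func:`benchmark_extension_flags`).

The temporal and auxiliary encoders are interface contracts only
(vector in, vector out); only the visual branch is ever instantiated
with data in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, InputError

MODALITIES = ("visual", "temporal", "auxiliary")


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - np.max(x))
    return e / e.sum()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ModalityFeatures:
    """Per-modality feature vectors in a shared latent space, with an
    availability mask for missing streams."""
    visual: np.ndarray | None = None
    temporal: np.ndarray | None = None
    auxiliary: np.ndarray | None = None

    def available(self) -> dict[str, np.ndarray]:
        out = {}
        dim = None
        for name in MODALITIES:
            vec = getattr(self, name)
            if vec is None:
                continue
            vec = np.asarray(vec, dtype=np.float64)
            if not np.isfinite(vec).all():
                raise InputError(f"{name} features contain non-finite values")
            if dim is not None and vec.shape != dim:
                raise ContractError("available modality vectors must share "
                                    "one dimension")
            dim = vec.shape
            out[name] = vec
        if not out:
            raise InputError("no modality available")
        return out


def adaptive_weighted_fusion(features: ModalityFeatures,
                             weight_logits: np.ndarray
                             ) -> tuple[np.ndarray, dict[str, float]]:
    """Convex combination of the available modalities with weights
    softmaxed over the availability mask (weights sum to 1)."""
    avail = features.available()
    logits = np.asarray(weight_logits, dtype=np.float64)
    if logits.shape != (len(MODALITIES),):
        raise ContractError(f"expected {len(MODALITIES)} weight logits")
    names = [m for m in MODALITIES if m in avail]
    idx = [MODALITIES.index(m) for m in names]
    w = _softmax(logits[idx])
    fused = sum(wi * avail[m] for wi, m in zip(w, names))
    return fused, dict(zip(names, map(float, w)))


@dataclass
class CrossModalParams:
    """Two-stage fusion parameters: W_alpha (2, 2d), b_alpha (2),
    W_psi (d, 2d), b_psi (d)."""
    W_alpha: np.ndarray
    b_alpha: np.ndarray
    W_psi: np.ndarray
    b_psi: np.ndarray

    @staticmethod
    def zeros(d: int) -> "CrossModalParams":
        return CrossModalParams(np.zeros((2, 2 * d)), np.zeros(2),
                                np.zeros((d, 2 * d)), np.zeros(d))

    @staticmethod
    def random(d: int, rng: np.random.Generator,
               scale: float = 0.1) -> "CrossModalParams":
        return CrossModalParams(scale * rng.standard_normal((2, 2 * d)),
                                scale * rng.standard_normal(2),
                                scale * rng.standard_normal((d, 2 * d)),
                                scale * rng.standard_normal(d))


def cross_modal_fuse(f_v: np.ndarray, f_t: np.ndarray, f_a: np.ndarray,
                     params: CrossModalParams) -> np.ndarray:
    """Pairwise visual-temporal attention then auxiliary integration:
    alpha = softmax(W_a [F_v; F_t] + b_a); F_vt = a1 F_v + a2 F_t;
    F_joint = tanh(W_psi [F_vt; F_a] + b_psi), entries in (-1, 1)."""
    f_v, f_t, f_a = (np.asarray(x, dtype=np.float64) for x in (f_v, f_t, f_a))
    if not f_v.shape == f_t.shape == f_a.shape:
        raise ContractError("modality features must share one dimension")
    alpha = _softmax(params.W_alpha @ np.concatenate([f_v, f_t])
                     + params.b_alpha)
    f_vt = alpha[0] * f_v + alpha[1] * f_t
    return np.tanh(params.W_psi @ np.concatenate([f_vt, f_a]) + params.b_psi)


def alignment_loss(features: ModalityFeatures) -> float:
    """Sum over ordered modality pairs i != j of
    ||Norm(F_i) - Norm(F_j)||^2 with unit-l2 Norm; zero iff all
    normalized features coincide."""
    avail = features.available()
    if len(avail) < 2:
        raise InputError("alignment needs at least two modalities")
    normed = {}
    for name, vec in avail.items():
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            raise InputError(f"{name} feature vector is zero; cannot "
                             "normalize")
        normed[name] = vec / norm
    total = 0.0
    for i in normed:
        for j in normed:
            if i != j:
                total += float(np.sum((normed[i] - normed[j]) ** 2))
    return total


def attention_reweight(f_joint: np.ndarray, W_a: np.ndarray,
                       b_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Feature-dimension attention: alpha = softmax(W_a F + b_a) over the
    d coordinates (sums to 1); F_attn = alpha ⊙ F."""
    f_joint = np.asarray(f_joint, dtype=np.float64)
    alpha = _softmax(np.asarray(W_a) @ f_joint + np.asarray(b_a))
    return alpha * f_joint, alpha


def risk_score(f_attn: np.ndarray, hidden: np.ndarray, W_s: np.ndarray,
               b_s: float, activation: str = "tanh") -> float:
    """Latent score s = phi(W_s [F_attn; H] + b_s) with bounded phi
    (tanh by default, sigmoid switchable); P_injury = logistic(s)."""
    z = float(np.asarray(W_s) @ np.concatenate([np.asarray(f_attn),
                                                np.asarray(hidden)]) + b_s)
    s = np.tanh(z) if activation == "tanh" else _sigmoid(z)
    return float(_sigmoid(s))


_EPS = 1e-7


def focal_risk_loss(p: float, y: int, gamma: float) -> float:
    """Focal-style risk loss with asymmetric modulators, as specified:
    -(1-P)^g * y * log P  -  P^g * (1-y) * log(1-P).  gamma = 0 recovers
    binary cross-entropy."""
    if gamma < 0:
        raise ContractError("gamma must be >= 0")
    p = float(np.clip(p, _EPS, 1.0 - _EPS))
    return float(-(1.0 - p) ** gamma * y * np.log(p)
                 - p ** gamma * (1 - y) * np.log(1.0 - p))


@dataclass
class RecurrentParams:
    W_h: np.ndarray
    W_x: np.ndarray
    b_h: np.ndarray
    W_o: np.ndarray
    b_o: float


def recurrent_step(h_prev: np.ndarray, x_t: np.ndarray,
                   params: RecurrentParams) -> tuple[np.ndarray, float]:
    """H_t = tanh(W_h H_{t-1} + W_x X_t + b_h); y_t = logistic(W_o H_t + b_o)."""
    h = np.tanh(np.asarray(params.W_h) @ np.asarray(h_prev)
                + np.asarray(params.W_x) @ np.asarray(x_t)
                + np.asarray(params.b_h))
    y = float(_sigmoid(float(np.asarray(params.W_o) @ h + params.b_o)))
    return h, y


def hierarchical_combine(o_irpm: np.ndarray, o_pom: np.ndarray,
                         alpha: float, beta: float) -> np.ndarray:
    """Learnable-balance combination alpha * O_irpm + beta * O_pom."""
    o_irpm = np.asarray(o_irpm, dtype=np.float64)
    o_pom = np.asarray(o_pom, dtype=np.float64)
    if o_irpm.shape != o_pom.shape:
        raise ContractError(f"shape mismatch: {o_irpm.shape} vs {o_pom.shape}")
    return alpha * o_irpm + beta * o_pom


def benchmark_extension_flags() -> dict[str, bool]:
    """Which extension objectives the benchmarked visual-only configuration
    activates.  All are off: the benchmark model trains with per-label
    binary cross-entropy only."""
    return {
        "focal_risk_loss": False,
        "alignment_loss": False,
        "constraint_penalty": False,
        "adaptive_weighted_fusion": False,
        "cross_modal_fusion": False,
        "recurrent_context": False,
        "hierarchical_combination": False,
    }
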