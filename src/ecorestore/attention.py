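"""Scaled dot-product self-attention aggregation over time steps.

Single-head attention on the BiGRU state sequence H (T x 2H):

    Q = H W_Q,  K = H W_K,  V = H W_V
    A = rowsoftmax(Q K^T / sqrt(d_k))          (T x T, rows sum to 1)
    context = mean over rows of A V            (d_k,)
    y-hat = w . context + b                    (standardized target scale)

The attention-score stage defines a full T x T matrix while the fusion stage
is a single weighted sum over steps; the two are reconciled by averaging the
T per-row contexts, and the per-step importance alpha_t reported for the
"critical moments" analysis is the column mean of A (a probability vector
over steps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionParams",
    "project_qkv",
    "attention_weights",
    "attend",
    "predict_head",
    "step_importance",
]


@dataclass
class AttentionParams:
    """Q/K/V projections ((2H) x d_k) plus the affine regression head."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    head_w: np.ndarray
    head_b: float

    def __post_init__(self) -> None:
        dk = self.W_Q.shape[1]
        if dk < 1:
            raise ValueError("d_k must be at least 1")
        if self.W_K.shape != self.W_Q.shape or self.W_V.shape != self.W_Q.shape:
            raise ValueError("W_Q, W_K, W_V must share one shape")
        if self.head_w.shape != (dk,):
            raise ValueError("head width must equal d_k")
        for name in ("W_Q", "W_K", "W_V", "head_w"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def d_k(self) -> int:
        return self.W_Q.shape[1]

    @classmethod
    def init(cls, in_dim: int, d_k: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(in_dim)
        return cls(
            W_Q=rng.uniform(-s, s, (in_dim, d_k)),
            W_K=rng.uniform(-s, s, (in_dim, d_k)),
            W_V=rng.uniform(-s, s, (in_dim, d_k)),
            head_w=rng.uniform(-1.0 / np.sqrt(d_k), 1.0 / np.sqrt(d_k), d_k),
            head_b=0.0,
        )


def project_qkv(H: np.ndarray, p: AttentionParams):
    """Plain matrix products (no bias): Q = H W_Q, K = H W_K, V = H W_V."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[1] != p.W_Q.shape[0]:
        raise ValueError(
            f"H has shape {H.shape}, expected (T, {p.W_Q.shape[0]})"
        )
    return H @ p.W_Q, H @ p.W_K, H @ p.W_V


def rowsoftmax(S: np.ndarray) -> np.ndarray:
    """Numerically stable row-wise softmax."""
    S = S - S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=-1, keepdims=True)


def attention_weights(Q: np.ndarray, K: np.ndarray, d_k: int) -> np.ndarray:
    """A = rowsoftmax(Q K^T / sqrt(d_k)); every row sums to 1."""
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K widths differ")
    S = Q @ K.T / np.sqrt(d_k)
    if not np.isfinite(S).all():
        raise ValueError("non-finite attention scores")
    return rowsoftmax(S)


def attend(A: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Fused context vector: per-row contexts A V, averaged over rows."""
    A = np.asarray(A, dtype=float)
    V = np.asarray(V, dtype=float)
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("attention rows must sum to 1")
    return (A @ V).mean(axis=0)


def step_importance(A: np.ndarray) -> np.ndarray:
    """Per-step importance alpha_t = column means of A (sums to 1)."""
    return np.asarray(A, dtype=float).mean(axis=0)


def predict_head(context: np.ndarray, p: AttentionParams) -> float:
    """Affine regression head on the fused context (standardized scale)."""
    return float(p.head_w @ np.asarray(context, dtype=float) + p.head_b)
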