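"""Gated recurrent unit cell, bidirectional composition, and stacked layers.

The cell computes, with sigma the logistic function and (.) elementwise:

    z_t = sigma(W_z x_t + U_z h_{t-1} + b_z)        (update gate)
    r_t = sigma(W_r x_t + U_r h_{t-1} + b_r)        (reset gate)
    h~_t = tanh(W_h x_t + U_h (r_t . h_{t-1}) + b_h)
    h_t = (1 - z_t) . h_{t-1} + z_t . h~_t

A bidirectional layer runs one pass left-to-right and one on the reversed
sequence, concatenating states forward-half-first; two such layers are
stacked with inverted dropout on the inter-layer activations (training mode
only, so inference needs no rescaling and is deterministic).

Everything here is plain NumPy.  These functions are the reference,
sequence-at-a-time formulation; the batched training-time forward/backward
lives in :mod:`ecorestore.network` and is tested against this one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRUCellParams",
    "BiGRUParams",
    "sigmoid",
    "gru_cell",
    "gru_forward",
    "bigru_layer",
    "bigru_stack",
]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GRUCellParams:
    """All weights of one GRU direction (hidden x input / hidden x hidden)."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        H, I = self.W_z.shape
        expect = {
            "W_r": (H, I), "W_h": (H, I),
            "U_z": (H, H), "U_r": (H, H), "U_h": (H, H),
            "b_z": (H,), "b_r": (H,), "b_h": (H,),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def hidden_dim(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_z.shape[1]

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        """Uniform(-1/sqrt(hidden), 1/sqrt(hidden)) initialization."""
        s = 1.0 / np.sqrt(hidden_dim)

        def u(*shape):
            return rng.uniform(-s, s, size=shape)

        return cls(
            W_z=u(hidden_dim, input_dim), W_r=u(hidden_dim, input_dim),
            W_h=u(hidden_dim, input_dim),
            U_z=u(hidden_dim, hidden_dim), U_r=u(hidden_dim, hidden_dim),
            U_h=u(hidden_dim, hidden_dim),
            b_z=np.zeros(hidden_dim), b_r=np.zeros(hidden_dim),
            b_h=np.zeros(hidden_dim),
        )


@dataclass
class BiGRUParams:
    """Stack of bidirectional layers: [(forward cell, backward cell), ...]."""

    layers: list[tuple[GRUCellParams, GRUCellParams]]
    dropout_rate: float = 0.3
    hidden_dim: int = 64

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        for li, (fwd, bwd) in enumerate(self.layers):
            if fwd.hidden_dim != self.hidden_dim or bwd.hidden_dim != self.hidden_dim:
                raise ValueError(f"layer {li}: hidden dim mismatch")
            if fwd.input_dim != bwd.input_dim:
                raise ValueError(f"layer {li}: fwd/bwd input dims differ")
            if li > 0 and fwd.input_dim != 2 * self.hidden_dim:
                raise ValueError(f"layer {li}: input dim must be 2*hidden")

    @classmethod
    def init(
        cls,
        input_dim: int,
        hidden_dim: int = 64,
        n_layers: int = 2,
        dropout_rate: float = 0.3,
        rng: np.random.Generator | None = None,
    ) -> "BiGRUParams":
        rng = rng or np.random.default_rng(0)
        layers = []
        dim = input_dim
        for _ in range(n_layers):
            layers.append(
                (GRUCellParams.init(dim, hidden_dim, rng),
                 GRUCellParams.init(dim, hidden_dim, rng))
            )
            dim = 2 * hidden_dim
        return cls(layers=layers, dropout_rate=dropout_rate, hidden_dim=hidden_dim)


def gru_cell(x_t: np.ndarray, h_prev: np.ndarray, p: GRUCellParams) -> np.ndarray:
    """One GRU step; ``x_t`` is (input,), ``h_prev`` is (hidden,)."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x_t.shape != (p.input_dim,) or h_prev.shape != (p.hidden_dim,):
        raise ValueError(
            f"shape mismatch: x_t {x_t.shape} vs input {p.input_dim}, "
            f"h_prev {h_prev.shape} vs hidden {p.hidden_dim}"
        )
    z = sigmoid(p.W_z @ x_t + p.U_z @ h_prev + p.b_z)
    r = sigmoid(p.W_r @ x_t + p.U_r @ h_prev + p.b_r)
    h_tilde = np.tanh(p.W_h @ x_t + p.U_h @ (r * h_prev) + p.b_h)
    return (1.0 - z) * h_prev + z * h_tilde


def gru_forward(seq: np.ndarray, p: GRUCellParams, h_0: np.ndarray | None = None):
    """Run the cell left-to-right from h_0 = 0; returns all T hidden states."""
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError("seq must be a non-empty (T, input) matrix")
    h = np.zeros(p.hidden_dim) if h_0 is None else np.asarray(h_0, dtype=float)
    states = np.empty((seq.shape[0], p.hidden_dim))
    for t in range(seq.shape[0]):
        h = gru_cell(seq[t], h, p)
        states[t] = h
    return states


def bigru_layer(
    seq: np.ndarray, fwd: GRUCellParams, bwd: GRUCellParams
) -> np.ndarray:
    """Bidirectional layer: H_t = [forward state ; backward state], (T, 2H).

    Backward states come from running the cell over the time-reversed
    sequence and re-reversing the result.
    """
    f = gru_forward(seq, fwd)
    b = gru_forward(np.asarray(seq, dtype=float)[::-1], bwd)[::-1]
    return np.concatenate([f, b], axis=1)


def bigru_stack(
    seq: np.ndarray,
    params: BiGRUParams,
    training_mode: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Stacked bidirectional layers with inter-layer inverted dropout.

    Dropout fires only in training mode; inference is deterministic and uses
    the activations unscaled (inverted dropout divides by the keep
    probability at training time).
    """
    rng = np.random.default_rng(seed)
    h = np.asarray(seq, dtype=float)
    for li, (fwd, bwd) in enumerate(params.layers):
        if li > 0 and training_mode and params.dropout_rate > 0.0:
            keep = 1.0 - params.dropout_rate
            mask = rng.random(h.shape) < keep
            h = h * mask / keep
        h = bigru_layer(h, fwd, bwd)
    return h
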