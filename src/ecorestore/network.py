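"""Batched forward/backward pass and Adam training for the sequence model.

:mod:`ecorestore.bigru` and :mod:`ecorestore.attention` define the model
mathematics one sequence at a time; this module implements the same
computation over mini-batches with a hand-written backward pass
(backpropagation through time), so the stack trains on plain NumPy.  The
batched forward is tested for exact agreement with the sequence-at-a-time
formulation, and the backward pass against finite differences.

Three architectures are expressible, covering the ablation variants:

* ``HybridNet(bidirectional=True, use_attention=True)`` — the full model:
  features -> 2-layer BiGRU -> self-attention -> affine head;
* ``use_attention=False`` — mean-pool over time instead of attention;
* ``bidirectional=False`` — unidirectional GRU stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .attention import AttentionParams
from .bigru import BiGRUParams, GRUCellParams

__all__ = ["HybridNet", "Adam", "TrainSettings", "FitHistory", "train_network"]

_GATE_NAMES = ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "b_z", "b_r", "b_h")


# ---------------------------------------------------------------------------
# one GRU direction, batched
# ---------------------------------------------------------------------------

def _gru_direction_forward(X: np.ndarray, p: GRUCellParams):
    """X is (B, T, I); returns states (B, T, H) and the backprop cache."""
    B, T, _ = X.shape
    H = p.hidden_dim
    # input contributions for every step at once
    az_x = X @ p.W_z.T + p.b_z
    ar_x = X @ p.W_r.T + p.b_r
    ah_x = X @ p.W_h.T + p.b_h
    h = np.zeros((B, H))
    states = np.empty((B, T, H))
    zs = np.empty((B, T, H))
    rs = np.empty((B, T, H))
    hts = np.empty((B, T, H))
    prevs = np.empty((B, T, H))
    for t in range(T):
        prevs[:, t] = h
        z = expit(az_x[:, t] + h @ p.U_z.T)
        r = expit(ar_x[:, t] + h @ p.U_r.T)
        ht = np.tanh(ah_x[:, t] + (r * h) @ p.U_h.T)
        h = (1.0 - z) * h + z * ht
        states[:, t] = h
        zs[:, t] = z
        rs[:, t] = r
        hts[:, t] = ht
    cache = {"X": X, "z": zs, "r": rs, "ht": hts, "prev": prevs}
    return states, cache


def _gru_direction_backward(dstates: np.ndarray, cache: dict, p: GRUCellParams):
    """Backprop through time; returns (dX, grads dict keyed like the params)."""
    X = cache["X"]
    B, T, _ = X.shape
    g = {n: np.zeros_like(getattr(p, n)) for n in _GATE_NAMES}
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, p.hidden_dim))
    for t in range(T - 1, -1, -1):
        dh = dstates[:, t] + dh_next
        z, r, ht, prev = (
            cache["z"][:, t], cache["r"][:, t], cache["ht"][:, t], cache["prev"][:, t]
        )
        dz = dh * (ht - prev)
        dht = dh * z
        dprev = dh * (1.0 - z)

        dah = dht * (1.0 - ht * ht)
        g["W_h"] += dah.T @ X[:, t]
        g["U_h"] += dah.T @ (r * prev)
        g["b_h"] += dah.sum(axis=0)
        drh = dah @ p.U_h
        dr = drh * prev
        dprev += drh * r

        dar = dr * r * (1.0 - r)
        g["W_r"] += dar.T @ X[:, t]
        g["U_r"] += dar.T @ prev
        g["b_r"] += dar.sum(axis=0)
        dprev += dar @ p.U_r

        daz = dz * z * (1.0 - z)
        g["W_z"] += daz.T @ X[:, t]
        g["U_z"] += daz.T @ prev
        g["b_z"] += daz.sum(axis=0)
        dprev += daz @ p.U_z

        dX[:, t] = daz @ p.W_z + dar @ p.W_r + dah @ p.W_h
        dh_next = dprev
    return dX, g


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

@dataclass
class HybridNet:
    """Trainable sequence regressor on standardized targets.

    Holds the layer-level parameter containers (:class:`BiGRUParams`,
    :class:`AttentionParams`) and implements batched forward/backward over
    them.  ``head`` width adapts to the pooling mode: d_k under attention,
    the recurrent output width under mean pooling.
    """

    recurrent: BiGRUParams
    attention: AttentionParams | None
    head_w: np.ndarray
    head_b: np.ndarray  # shape (1,) so Adam can address it uniformly
    bidirectional: bool = True

    @property
    def use_attention(self) -> bool:
        return self.attention is not None

    @classmethod
    def create(
        cls,
        input_dim: int,
        hidden_dim: int = 64,
        n_layers: int = 2,
        dropout_rate: float = 0.3,
        d_k: int = 64,
        bidirectional: bool = True,
        use_attention: bool = True,
        seed: int = 0,
    ) -> "HybridNet":
        rng = np.random.default_rng(seed)
        width = 2 * hidden_dim if bidirectional else hidden_dim
        layers = []
        dim = input_dim
        for _ in range(n_layers):
            fwd = GRUCellParams.init(dim, hidden_dim, rng)
            bwd = GRUCellParams.init(dim, hidden_dim, rng) if bidirectional else fwd
            layers.append((fwd, bwd))
            dim = width
        recurrent = BiGRUParams(
            layers=layers, dropout_rate=dropout_rate, hidden_dim=hidden_dim
        ) if bidirectional else _UniParams(layers, dropout_rate, hidden_dim)
        att = None
        head_in = width
        if use_attention:
            att = AttentionParams.init(width, d_k=d_k, rng=rng)
            head_in = d_k
        s = 1.0 / np.sqrt(head_in)
        return cls(
            recurrent=recurrent,
            attention=att,
            head_w=rng.uniform(-s, s, head_in),
            head_b=np.zeros(1),
            bidirectional=bidirectional,
        )

    # -- parameter plumbing --------------------------------------------------

    def parameters(self):
        """Yield (name, array) for every trainable tensor, in a fixed order."""
        for li, (fwd, bwd) in enumerate(self.recurrent.layers):
            for n in _GATE_NAMES:
                yield f"l{li}.f.{n}", getattr(fwd, n)
            if self.bidirectional:
                for n in _GATE_NAMES:
                    yield f"l{li}.b.{n}", getattr(bwd, n)
        if self.attention is not None:
            yield "att.W_Q", self.attention.W_Q
            yield "att.W_K", self.attention.W_K
            yield "att.W_V", self.attention.W_V
        yield "head.w", self.head_w
        yield "head.b", self.head_b

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters():
            v[...] = state[k]

    # -- forward / backward ---------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        want_cache: bool = False,
    ):
        """X is (B, T, input_dim); returns predictions (B,) [and cache]."""
        h = np.asarray(X, dtype=float)
        caches = []
        dropout_rate = self.recurrent.dropout_rate
        for li, (fwd, bwd) in enumerate(self.recurrent.layers):
            mask = None
            if li > 0 and training and dropout_rate > 0.0:
                keep = 1.0 - dropout_rate
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
            sf, cf = _gru_direction_forward(h, fwd)
            if self.bidirectional:
                sb_rev, cb = _gru_direction_forward(h[:, ::-1], bwd)
                out = np.concatenate([sf, sb_rev[:, ::-1]], axis=2)
            else:
                cb = None
                out = sf
            caches.append({"mask": mask, "cf": cf, "cb": cb})
            h = out

        if self.attention is not None:
            p = self.attention
            Q = h @ p.W_Q
            K = h @ p.W_K
            V = h @ p.W_V
            S = np.einsum("btd,bsd->bts", Q, K) / np.sqrt(p.d_k)
            S = S - S.max(axis=2, keepdims=True)
            E = np.exp(S)
            A = E / E.sum(axis=2, keepdims=True)
            C = np.einsum("bts,bsd->btd", A, V)
            c = C.mean(axis=1)
            pool_cache = {"H": h, "Q": Q, "K": K, "V": V, "A": A}
        else:
            c = h.mean(axis=1)
            pool_cache = {"H": h}

        yhat = c @ self.head_w + self.head_b[0]
        if not want_cache:
            return yhat
        return yhat, {"layers": caches, "pool": pool_cache, "c": c}

    def attention_matrix(self, X: np.ndarray) -> np.ndarray:
        """Row-stochastic A (B, T, T) at inference; attention variants only."""
        if self.attention is None:
            raise ValueError("model has no attention layer")
        _, cache = self.forward(X, want_cache=True)
        return cache["pool"]["A"]

    def backward(self, dyhat: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of the scalar loss wrt every parameter; dyhat is (B,)."""
        grads: dict[str, np.ndarray] = {}
        c = cache["c"]
        pool = cache["pool"]
        grads["head.w"] = dyhat @ c
        grads["head.b"] = np.array([dyhat.sum()])
        dc = np.outer(dyhat, self.head_w)

        if self.attention is not None:
            p = self.attention
            H, Q, K, V, A = pool["H"], pool["Q"], pool["K"], pool["V"], pool["A"]
            T = H.shape[1]
            dC = np.repeat(dc[:, None, :] / T, T, axis=1)
            dA = np.einsum("btd,bsd->bts", dC, V)
            dV = np.einsum("bts,btd->bsd", A, dC)
            dS = A * (dA - (dA * A).sum(axis=2, keepdims=True))
            dS /= np.sqrt(p.d_k)
            dQ = np.einsum("bts,bsd->btd", dS, K)
            dK = np.einsum("bts,btd->bsd", dS, Q)
            grads["att.W_Q"] = np.einsum("bti,btd->id", H, dQ)
            grads["att.W_K"] = np.einsum("bti,btd->id", H, dK)
            grads["att.W_V"] = np.einsum("bti,btd->id", H, dV)
            dH = dQ @ p.W_Q.T + dK @ p.W_K.T + dV @ p.W_V.T
        else:
            H = pool["H"]
            T = H.shape[1]
            dH = np.repeat(dc[:, None, :] / T, T, axis=1)

        for li in range(len(self.recurrent.layers) - 1, -1, -1):
            fwd, bwd = self.recurrent.layers[li]
            lc = cache["layers"][li]
            if self.bidirectional:
                Hh = fwd.hidden_dim
                dXf, gf = _gru_direction_backward(dH[..., :Hh], lc["cf"], fwd)
                dXb_rev, gb = _gru_direction_backward(
                    dH[..., Hh:][:, ::-1], lc["cb"], bwd
                )
                dX = dXf + dXb_rev[:, ::-1]
                for n in _GATE_NAMES:
                    grads[f"l{li}.f.{n}"] = gf[n]
                    grads[f"l{li}.b.{n}"] = gb[n]
            else:
                dX, gf = _gru_direction_backward(dH, lc["cf"], fwd)
                for n in _GATE_NAMES:
                    grads[f"l{li}.f.{n}"] = gf[n]
            if lc["mask"] is not None:
                dX = dX * lc["mask"]
            dH = dX
        return grads

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic inference over (N, T, input_dim), batched."""
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for s in range(0, X.shape[0], batch_size):
            out[s : s + batch_size] = self.forward(X[s : s + batch_size])
        return out


class _UniParams:
    """Container mirroring BiGRUParams for the unidirectional ablation."""

    def __init__(self, layers, dropout_rate, hidden_dim):
        self.layers = layers
        self.dropout_rate = dropout_rate
        self.hidden_dim = hidden_dim


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, net: HybridNet, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, param in net.parameters():
            g = grads[name]
            m = self.m.setdefault(name, np.zeros_like(param))
            v = self.v.setdefault(name, np.zeros_like(param))
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainSettings:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    min_delta: float = 1e-6
    seed: int = 0


@dataclass
class FitHistory:
    """Per-epoch training trace with the early-stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metrics: list[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def train_network(
    net: HybridNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    settings: TrainSettings,
    val_metric_fn=None,
) -> FitHistory:
    """Minimize MSE on standardized targets with Adam and early stopping.

    Stops when validation loss has not improved by more than ``min_delta``
    for ``patience`` consecutive epochs, then restores the best-epoch
    parameters.  Deterministic for a fixed ``settings.seed``.
    """
    rng = np.random.default_rng(settings.seed)
    opt = Adam(lr=settings.learning_rate)
    hist = FitHistory()
    n = len(y_train)
    best_val = np.inf
    best_state = net.get_state()
    bad_epochs = 0
    for epoch in range(1, settings.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, settings.batch_size):
            idx = order[s : s + settings.batch_size]
            yhat, cache = net.forward(
                X_train[idx], training=True, rng=rng, want_cache=True
            )
            err = yhat - y_train[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (non-finite loss)"
                )
            grads = net.backward(2.0 * err / len(idx), cache)
            opt.step(net, grads)
            losses.append(loss)
        val_pred = net.predict(X_val)
        vloss = float(np.mean((val_pred - y_val) ** 2))
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(vloss)
        if val_metric_fn is not None:
            hist.val_metrics.append(val_metric_fn(val_pred))
        if vloss < best_val - settings.min_delta:
            best_val = vloss
            hist.best_epoch = epoch
            best_state = net.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
        hist.stopped_epoch = epoch
        if bad_epochs >= settings.patience:
            break
    net.set_state(best_state)
    return hist
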