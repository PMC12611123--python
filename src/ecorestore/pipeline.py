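"""End-to-end assembly: chronological splitting, rolling-origin CV, metric
suite, training of the full model and its ablation variants.

The evaluation protocol is strictly chronological: windows are sorted by
their end month, the last 10% form the test set and the preceding 20% the
validation set, and every statistic a fitted model depends on
(standardization, Cubist rules, climatology) is computed from the training
block only.  Metrics follow the study protocol: RMSE, MAPE, R-squared, and
"prediction accuracy" = the percentage of samples whose relative error is
within +/-10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cubist import CubistModel, fit_cubist_layer
from .network import FitHistory, HybridNet, TrainSettings, train_network
from .preprocess import Standardizer, WindowDataset

__all__ = [
    "TrainConfig",
    "Metrics",
    "VARIANTS",
    "chrono_split",
    "ts_cv_folds",
    "evaluate",
    "accuracy_by_group",
    "compare_models",
    "train_model",
    "FittedVariant",
]

VARIANTS = ("full", "cubist_only", "bigru_only", "cubist_gru")

_REL_EPS = 1e-8  # floor on |y| in relative-error metrics
_ACCURACY_TOL = 0.10


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (study defaults)."""

    T: int = 30
    D: int = 6
    cubist_dim: int = 16
    cubist_min_leaf: int = 20
    cubist_max_rules: int = 14
    hidden: int = 64
    layers: int = 2
    dropout: float = 0.3
    d_k: int = 64
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    min_delta: float = 1e-6
    split: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience >= self.max_epochs and self.max_epochs > 1:
            warnings.warn("patience >= max_epochs: early stopping cannot fire",
                          stacklevel=2)


@dataclass
class Metrics:
    """RMSE / MAPE / R^2 / +/-10% accuracy for one prediction set."""

    rmse: float
    mape: float
    r2: float
    accuracy: float
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mape": self.mape, "r2": self.r2,
                "accuracy": self.accuracy, "n": self.n}


def evaluate(preds: np.ndarray, truth: np.ndarray) -> Metrics:
    """Metric suite on the original (unstandardized) target scale.

    mape and accuracy use relative errors |yhat - y| / max(|y|, 1e-8);
    accuracy is the percentage of samples within the +/-10% band.  R^2 is
    NaN (with a warning) when the truth is constant.
    """
    preds = np.asarray(preds, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if preds.shape != truth.shape or preds.size == 0:
        raise ValueError("preds and truth must be equal-length, non-empty")
    err = preds - truth
    rmse = float(np.sqrt(np.mean(err**2)))
    rel = np.abs(err) / np.maximum(np.abs(truth), _REL_EPS)
    mape = float(100.0 * np.mean(rel))
    accuracy = float(100.0 * np.mean(rel <= _ACCURACY_TOL))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant truth: R^2 undefined (NaN)", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = float(1.0 - np.sum(err**2) / ss_tot)
    return Metrics(rmse=rmse, mape=mape, r2=r2, accuracy=accuracy, n=len(truth))


def accuracy_by_group(
    preds: np.ndarray, truth: np.ndarray, groups: np.ndarray
) -> dict[str, Metrics | None]:
    """:func:`evaluate` restricted to each group label (None when empty)."""
    preds = np.asarray(preds, dtype=float)
    truth = np.asarray(truth, dtype=float)
    groups = np.asarray(groups)
    out: dict[str, Metrics | None] = {}
    for g in ("low", "mid", "high"):
        sel = groups == g
        if not sel.any():
            out[g] = None
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[g] = evaluate(preds[sel], truth[sel])
    for g in np.unique(groups):  # any non-band labels a caller passed
        if g not in out:
            out[str(g)] = evaluate(preds[groups == g], truth[groups == g])
    return out


def compare_models(
    errors_a: np.ndarray, errors_b: np.ndarray, signed: bool = False
) -> tuple[float, float]:
    """Paired t-test on the two models' per-sample prediction errors.

    By default compares absolute errors d_i = |e_a,i| - |e_b,i|; pass
    ``signed=True`` to compare the signed errors instead.  Returns
    (t statistic, two-sided p).  All-zero differences give (0, 1); zero
    spread with a nonzero mean gives (inf-signed t, p = 0) with a warning.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matching error vectors with at least 3 samples")
    if not signed:
        a, b = np.abs(a), np.abs(b)
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return 0.0, 1.0
        warnings.warn("zero-variance differences: p degenerate", stacklevel=2)
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def chrono_split(
    ds: WindowDataset, fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Chronological train/val/test split on window end times.

    test = last round(f_test * N) windows, val = previous round(f_val * N),
    train = remainder (reproduces 2252/643/322 at N = 3217 with the default
    fractions).  The dataset must already be sorted by window_end (ties by
    site then start), which :func:`~ecorestore.preprocess.make_windows`
    guarantees.
    """
    n = len(ds)
    if n < 10:
        raise ValueError("need at least 10 windows to split")
    if np.any(np.diff(ds.window_end) < 0):
        raise ValueError("dataset not sorted by window_end")
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split produces an empty block")
    idx = np.arange(n)
    return (
        ds.subset(idx[:n_train]),
        ds.subset(idx[n_train : n_train + n_val]),
        ds.subset(idx[n_train + n_val :]),
    )


def ts_cv_folds(train: WindowDataset, k: int = 5):
    """Expanding-window (rolling-origin) folds on the training block.

    Fold i (1-based) fits on the first i*B windows and evaluates on the next
    B, where B = floor(N / (k+1)); evaluation blocks are disjoint and always
    strictly later than their fit block.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    n = len(train)
    if np.any(np.diff(train.window_end) < 0):
        raise ValueError("training block not chronologically sorted")
    block = n // (k + 1)
    if block < 1:
        raise ValueError("too few windows for the requested k")
    folds = []
    for i in range(1, k + 1):
        fit_idx = np.arange(0, i * block)
        eval_idx = np.arange(i * block, (i + 1) * block)
        folds.append((train.subset(fit_idx), train.subset(eval_idx)))
    return folds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FittedVariant:
    """One fitted architecture variant plus everything inference needs.

    ``step_supervision`` records how the Cubist layer was supervised:
    ``"growth"`` (per-step one-month log-FVC growth; the standalone Cubist
    prediction is then the integrated exp(sum)-1 over the window) or
    ``"broadcast"`` (window target at every step; standalone prediction is
    the final-step rule output).
    """

    variant: str
    cfg: TrainConfig
    cubist: CubistModel | None
    net: HybridNet | None
    standardizer: Standardizer
    history: FitHistory | None = None
    step_supervision: str = "broadcast"

    def predict_windows(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict on raw-scale covariate windows (N, T, D); raw-scale output."""
        Xs = (np.asarray(X_raw, dtype=float) - self.standardizer.mean) / (
            self.standardizer.std
        )
        return self._predict_standardized_X(Xs)

    def _predict_standardized_X(self, Xs: np.ndarray) -> np.ndarray:
        if self.variant == "cubist_only":
            N, T, d = Xs.shape
            step_preds = self.cubist.predict_rows(Xs.reshape(N * T, d))
            if self.step_supervision == "growth":
                # integrate predicted one-month log-growth over the window
                return np.expm1(step_preds.reshape(N, T)[:, :-1].sum(axis=1))
            return step_preds.reshape(N, T)[:, -1]  # final-step prediction
        feats = self.cubist.featurize_windows(Xs) if self.cubist is not None else Xs
        y_std = self.net.predict(feats)
        return self.standardizer.inverse_transform_y(y_std)


def _network_inputs(variant: str, cubist: CubistModel | None, Xs: np.ndarray):
    if variant == "bigru_only":
        return Xs
    return cubist.featurize_windows(Xs)


def _step_growth_targets(ds: WindowDataset) -> np.ndarray:
    """One-month log-FVC growth per window step, (N, T); last step repeats.

    Computed on the raw (unstandardized) FVC trajectory inside each window,
    so it uses training data only when ``ds`` is the training block.
    """
    fvc = ds.X[:, :, ds.variables.index("fvc")]
    g = np.diff(np.log(np.maximum(fvc, 1e-3)), axis=1)
    return np.concatenate([g, g[:, -1:]], axis=1)


def train_model(
    train: WindowDataset,
    val: WindowDataset,
    cfg: TrainConfig,
    variant: str = "full",
    standardizer: Standardizer | None = None,
) -> FittedVariant:
    """Fit one architecture variant on the (chronological) train block.

    Variants: ``full`` = Cubist features -> 2-layer BiGRU -> attention ->
    head; ``cubist_only`` = the rule model alone; ``bigru_only`` = raw
    covariates -> BiGRU -> mean-pool -> head; ``cubist_gru`` = Cubist
    features -> unidirectional GRU -> mean-pool -> head.  For the
    restoration-rate task the network trains on the standardized log1p
    target and the Cubist layer is supervised on per-step log-FVC growth;
    the survival task keeps the identity transform and broadcast
    supervision.  All leakage-sensitive statistics come from ``train`` only.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if train.standardized or val.standardized:
        raise ValueError("pass raw-scale windows; standardization happens here")
    restoration = train.task == "restoration_rate"
    supervision = "growth" if restoration else "broadcast"
    std = standardizer or Standardizer.fit(
        train, y_transform="log1p" if restoration else "identity"
    )
    Xs_train = (train.X - std.mean) / std.std
    Xs_val = (val.X - std.mean) / std.std
    y_train_std = std.transform_y(train.y)
    y_val_std = std.transform_y(val.y)

    cubist = None
    if variant != "bigru_only":
        cubist = fit_cubist_layer(
            Xs_train,
            train.y,
            min_leaf=cfg.cubist_min_leaf,
            max_rules=cfg.cubist_max_rules,
            feature_dim=cfg.cubist_dim,
            step_targets=(
                _step_growth_targets(train) if supervision == "growth" else None
            ),
        )
    if variant == "cubist_only":
        return FittedVariant(variant, cfg, cubist, None, std, None,
                             step_supervision=supervision)

    F_train = _network_inputs(variant, cubist, Xs_train)
    F_val = _network_inputs(variant, cubist, Xs_val)
    net = HybridNet.create(
        input_dim=F_train.shape[2],
        hidden_dim=cfg.hidden,
        n_layers=cfg.layers,
        dropout_rate=cfg.dropout,
        d_k=cfg.d_k,
        bidirectional=(variant != "cubist_gru"),
        use_attention=(variant == "full"),
        seed=cfg.seed,
    )

    def val_metric_fn(val_pred_std):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = evaluate(std.inverse_transform_y(val_pred_std), val.y)
        return m.as_dict()

    history = train_network(
        net,
        F_train,
        y_train_std,
        F_val,
        y_val_std,
        TrainSettings(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            min_delta=cfg.min_delta,
            seed=cfg.seed,
        ),
        val_metric_fn=val_metric_fn,
    )
    return FittedVariant(variant, cfg, cubist, net, std, history,
                         step_supervision=supervision)
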