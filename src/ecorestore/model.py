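"""Model / Results objects tying the whole stack together.

:class:`CubistBiGRUSA` is constructed from data (a window dataset, a site
panel, or a long-format DataFrame), carries the training configuration and
the chronological splits, and :meth:`~CubistBiGRUSA.fit` returns a
:class:`CubistBiGRUSAResults` holding the fitted layers, training history,
split metrics, attention weights and attribution hooks, with a
``summary()`` table.

Typical use::

    from ecorestore import CubistBiGRUSA, ScenarioConfig, TrainConfig

    model = CubistBiGRUSA.from_scenario(ScenarioConfig(seed=42),
                                        TrainConfig(seed=42, max_epochs=30))
    res = model.fit()            # the full Cubist-BiGRU-SA variant
    print(res.summary())
    res.metrics("test").accuracy # +/-10% prediction accuracy, percent
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attrib
from .cubist import CubistModel
from .network import HybridNet
from .pipeline import (
    FittedVariant,
    Metrics,
    TrainConfig,
    accuracy_by_group,
    chrono_split,
    evaluate,
    train_model,
)
from .preprocess import (
    Standardizer,
    WindowDataset,
    make_windows,
    monthly_climatology,
    preprocess_panel,
    seasonal_adjust,
)
from .simulate import ScenarioConfig, SiteSeries, generate_panel

__all__ = ["CubistBiGRUSA", "CubistBiGRUSAResults", "BENCHMARK_SAMPLES"]

#: Window count of the default benchmark (104 sites x 31 windows, trimmed).
BENCHMARK_SAMPLES = 3217


class CubistBiGRUSA:
    """Hybrid rule-tree / bidirectional-recurrent / self-attention regressor.

    Parameters
    ----------
    windows : WindowDataset
        Raw-scale covariate windows with targets, chronologically sorted.
    config : TrainConfig
        Hyperparameters; defaults follow the study protocol (T=30, D=6,
        m=16, hidden 64, 2 layers, dropout 0.3, Adam lr 0.001, batch 32).
    climatology : DataFrame, optional
        Training-period calendar-month climatology already applied to the
        panel the windows came from (kept for inference-time reuse).
    """

    def __init__(
        self,
        windows: WindowDataset,
        config: TrainConfig | None = None,
        climatology: pd.DataFrame | None = None,
    ):
        self.config = config or TrainConfig()
        self.windows = windows
        self.climatology = climatology
        self.train, self.val, self.test = chrono_split(windows, self.config.split)

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_panel(
        cls,
        panel: list[SiteSeries],
        config: TrainConfig | None = None,
        task: str = "restoration_rate",
        seasonal: bool = False,
        max_samples: int | None = None,
    ) -> "CubistBiGRUSA":
        """Clean a site panel, window it, and build the model.

        Runs gap filling and outlier screening, then windowing.  With
        ``seasonal=True`` the meteorological variables are additionally
        anomaly-adjusted against a climatology computed strictly from the
        months covered by the training block; the default keeps the raw
        seasonal cycle, which the temporal layers rely on to locate a window
        within the year.
        """
        config = config or TrainConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            clean = preprocess_panel(panel)
        climatology = None
        if seasonal:
            # find the training-block boundary on unadjusted windows, then
            # adjust with a climatology restricted to months before it
            probe = make_windows(clean, T=config.T, task=task, max_samples=max_samples)
            n = len(probe)
            n_cut = n - int(round(config.split[1] * n)) - int(round(config.split[2] * n))
            cutoff = int(probe.window_end[n_cut - 1])
            climatology = monthly_climatology(clean, max_month_index=cutoff)
            clean = [seasonal_adjust(s, climatology) for s in clean]
        windows = make_windows(clean, T=config.T, task=task, max_samples=max_samples)
        return cls(windows, config, climatology)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: TrainConfig | None = None,
        task: str = "restoration_rate",
        **kwargs,
    ) -> "CubistBiGRUSA":
        """Build from a long-format panel DataFrame (see :mod:`ecorestore.io`)."""
        from .io import panel_from_dataframe

        return cls.from_panel(panel_from_dataframe(df), config, task=task, **kwargs)

    @classmethod
    def from_scenario(
        cls,
        scenario: ScenarioConfig | None = None,
        config: TrainConfig | None = None,
        task: str = "restoration_rate",
    ) -> "CubistBiGRUSA":
        """Default synthetic benchmark: 104 sites x 60 months -> 3217 windows."""
        scenario = scenario or ScenarioConfig()
        config = config or TrainConfig()
        panel = generate_panel(scenario)
        max_samples = BENCHMARK_SAMPLES if (
            scenario.n_sites == 104 and scenario.months == 60 and config.T == 30
        ) else None
        model = cls.from_panel(panel, config, task=task, max_samples=max_samples)
        model.panel = panel
        return model

    # -- fitting ---------------------------------------------------------------

    def fit(self, variant: str = "full") -> "CubistBiGRUSAResults":
        """Train one architecture variant and evaluate it on all splits."""
        fitted = train_model(self.train, self.val, self.config, variant=variant)
        return CubistBiGRUSAResults(self, fitted)


class CubistBiGRUSAResults:
    """Fitted-model container: estimates, history, metrics, attribution."""

    def __init__(self, model: CubistBiGRUSA, fitted: FittedVariant):
        self.model = model
        self.fitted = fitted
        self.variant = fitted.variant
        self.history = fitted.history
        self._metrics: dict[str, Metrics] = {}
        self._preds: dict[str, np.ndarray] = {}

    # -- prediction ------------------------------------------------------------

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict targets for raw-scale covariate windows (N, T, D)."""
        return self.fitted.predict_windows(X_raw)

    def _split(self, split: str) -> WindowDataset:
        try:
            return {"train": self.model.train, "val": self.model.val,
                    "test": self.model.test}[split]
        except KeyError:
            raise ValueError(f"unknown split {split!r}") from None

    def predictions(self, split: str = "test") -> np.ndarray:
        if split not in self._preds:
            self._preds[split] = self.predict(self._split(split).X)
        return self._preds[split]

    # -- evaluation --------------------------------------------------------------

    def metrics(self, split: str = "test") -> Metrics:
        if split not in self._metrics:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._metrics[split] = evaluate(
                    self.predictions(split), self._split(split).y
                )
        return self._metrics[split]

    def accuracy_by_group(self, split: str = "test") -> dict[str, Metrics | None]:
        ds = self._split(split)
        return accuracy_by_group(self.predictions(split), ds.y, ds.altitude_band)

    def errors(self, split: str = "test") -> np.ndarray:
        return self.predictions(split) - self._split(split).y

    # -- interpretation ----------------------------------------------------------

    def attention_profile(self, split: str = "test") -> np.ndarray:
        """Mean per-step importance alpha_t over a split's windows, (T,)."""
        if self.fitted.net is None or not self.fitted.net.use_attention:
            raise ValueError("variant has no attention layer")
        ds = self._split(split)
        std = self.fitted.standardizer
        Xs = (ds.X - std.mean) / std.std
        feats = (
            self.fitted.cubist.featurize_windows(Xs)
            if self.fitted.cubist is not None
            else Xs
        )
        profs = []
        for s in range(0, len(ds), 256):
            A = self.fitted.net.attention_matrix(feats[s : s + 256])
            profs.append(A.mean(axis=1))  # column means per window
        return np.concatenate(profs).mean(axis=0)

    def export_attention(self, path, split: str = "test") -> pd.DataFrame:
        """Per-prediction step weights alpha_t as CSV (window, step, weight)."""
        if self.fitted.net is None or not self.fitted.net.use_attention:
            raise ValueError("variant has no attention layer")
        ds = self._split(split)
        std = self.fitted.standardizer
        Xs = (ds.X - std.mean) / std.std
        feats = (
            self.fitted.cubist.featurize_windows(Xs)
            if self.fitted.cubist is not None
            else Xs
        )
        rows = []
        for s in range(0, len(ds), 256):
            A = self.fitted.net.attention_matrix(feats[s : s + 256])
            alpha = A.mean(axis=1)  # column means: importance per step
            for i in range(alpha.shape[0]):
                for t in range(alpha.shape[1]):
                    rows.append((s + i, t + 1, alpha[i, t]))
        df = pd.DataFrame(rows, columns=["window", "step", "weight"])
        if path is not None:
            df.to_csv(path, index=False)
        return df

    def shapley(
        self,
        n_windows: int = 50,
        background_size: int = 50,
        n_perm: int = 200,
        seed: int = 0,
    ) -> attrib.ShapleyResult:
        """Sampling Shapley attribution of test-split predictions.

        Background windows come from the training split; explained windows
        are an evenly-spaced subsample of the test split.  Values are on the
        raw target scale.
        """
        rng = np.random.default_rng(seed)
        bg_idx = rng.choice(
            len(self.model.train), size=min(background_size, len(self.model.train)),
            replace=False,
        )
        test = self.model.test
        take = np.linspace(0, len(test) - 1, min(n_windows, len(test))).astype(int)
        return attrib.shapley_for_windows(
            self.fitted,
            test.X[take],
            self.model.train.X[bg_idx],
            n_perm=n_perm,
            seed=seed,
            variables=list(test.variables),
        )

    def importance(self, **kwargs) -> pd.DataFrame:
        """Global mean-|phi| ranking of the input variables."""
        res = self.shapley(**kwargs)
        return attrib.global_importance(res.phi, res.variables)

    # -- reporting ----------------------------------------------------------------

    def summary(self) -> str:
        cfg = self.fitted.cfg
        lines = [
            "Cubist-BiGRU-SA regression results",
            "=" * 58,
            f"variant:        {self.variant}",
            f"task:           {self.model.windows.task}",
            f"windows:        {len(self.model.windows)} "
            f"(train {len(self.model.train)} / val {len(self.model.val)} / "
            f"test {len(self.model.test)})",
            f"window length:  T={cfg.T}, D={cfg.D} variables",
        ]
        if self.fitted.cubist is not None:
            lines.append(
                f"cubist:         {len(self.fitted.cubist.rules)} rules, "
                f"m={self.fitted.cubist.feature_dim} features"
            )
        if self.history is not None:
            lines.append(
                f"training:       stopped at epoch {self.history.stopped_epoch}, "
                f"best epoch {self.history.best_epoch}"
            )
        lines.append("-" * 58)
        lines.append(f"{'split':<8}{'rmse':>10}{'mape%':>10}{'r2':>10}{'acc%':>10}{'n':>8}")
        for split in ("train", "val", "test"):
            m = self.metrics(split)
            lines.append(
                f"{split:<8}{m.rmse:>10.4f}{m.mape:>10.2f}{m.r2:>10.4f}"
                f"{m.accuracy:>10.1f}{m.n:>8d}"
            )
        lines.append("-" * 58)
        lines.append("test accuracy by altitude band (+/-10% relative error):")
        for band, m in self.accuracy_by_group("test").items():
            if band in ("low", "mid", "high"):
                txt = "empty" if m is None else f"{m.accuracy:5.1f}%  (n={m.n})"
                lines.append(f"  {band:<6}{txt}")
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------------

    def plot_history(self, ax=None):
        """Training/validation loss curves per epoch."""
        import matplotlib.pyplot as plt

        if self.history is None:
            raise ValueError("variant has no training history")
        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.history.train_loss) + 1)
        ax.plot(epochs, self.history.train_loss, label="train loss")
        ax.plot(epochs, self.history.val_loss, label="validation loss")
        ax.axvline(self.history.best_epoch, ls="--", c="grey", label="best epoch")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (standardized target)")
        ax.legend()
        return ax

    def plot_attention(self, split: str = "test", ax=None):
        """Mean attention importance per window step."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        alpha = self.attention_profile(split)
        ax.bar(np.arange(1, len(alpha) + 1), alpha)
        ax.set_xlabel("window step (month)")
        ax.set_ylabel(r"mean importance $\alpha_t$")
        return ax

    # -- persistence -----------------------------------------------------------------

    def save(self, out_dir) -> None:
        """Write the model bundle (Cubist JSON, weights, stats, config)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "ecorestore-bundle",
            "version": 1,
            "variant": self.variant,
            "config": asdict(self.fitted.cfg),
            "standardizer": self.fitted.standardizer.to_dict(),
            "task": self.model.windows.task,
            "step_supervision": self.fitted.step_supervision,
        }
        (out / "bundle.json").write_text(json.dumps(meta, indent=1))
        if self.fitted.cubist is not None:
            self.fitted.cubist.to_json(out / "cubist.json")
        if self.fitted.net is not None:
            np.savez(out / "network.npz", **dict(self.fitted.net.parameters()))

    @staticmethod
    def load_fitted(out_dir) -> FittedVariant:
        """Reload a saved bundle as a :class:`FittedVariant` for inference."""
        out = Path(out_dir)
        meta = json.loads((out / "bundle.json").read_text())
        if meta.get("format") != "ecorestore-bundle":
            raise ValueError("not an ecorestore model bundle")
        cfg = TrainConfig(**{**meta["config"],
                             "split": tuple(meta["config"]["split"])})
        std = Standardizer.from_dict(meta["standardizer"])
        cubist = None
        if (out / "cubist.json").exists():
            cubist = CubistModel.from_json(out / "cubist.json")
        net = None
        if (out / "network.npz").exists():
            variant = meta["variant"]
            input_dim = cfg.cubist_dim if variant != "bigru_only" else cfg.D
            net = HybridNet.create(
                input_dim=input_dim,
                hidden_dim=cfg.hidden,
                n_layers=cfg.layers,
                dropout_rate=cfg.dropout,
                d_k=cfg.d_k,
                bidirectional=(variant != "cubist_gru"),
                use_attention=(variant == "full"),
                seed=cfg.seed,
            )
            with np.load(out / "network.npz") as arrs:
                net.set_state({k: arrs[k] for k in arrs.files})
        return FittedVariant(
            meta["variant"], cfg, cubist, net, std, None,
            step_supervision=meta.get("step_supervision", "broadcast"),
        )
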