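"""Cubist/M5-style rule-based regression tree used as a feature extractor.

A greedy binary tree is grown on per-step rows by maximizing the classic
standard-deviation reduction (SDR) criterion

    SDR = sd(parent) - sum_children (n_child / n_parent) * sd(child),

with candidate thresholds at midpoints of consecutive sorted unique feature
values.  Each leaf's root-to-leaf path becomes one rule with an ordinary
least-squares linear model fitted on the leaf's rows (ridge fallback
lambda = 1e-6 when rank-deficient); the rules partition the feature space, so
every point matches exactly one rule.  A global OLS model over all rows backs
up numeric edge cases at prediction time.

For the hybrid model the tree is exposed as a fixed-width feature map: the
``m``-vector F = [indicator of the top (m-2) rules by coverage, local-rule
prediction, global prediction], the last two z-scored by training-target
statistics.  With the default 14-rule cap this yields the 16-dimensional
structured feature block consumed by the sequence model.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Rule", "CubistModel", "fit_tree", "fit_cubist_layer"]

_SDR_MIN_IMPROVEMENT = 1e-9
_RIDGE_LAMBDA = 1e-6


@dataclass
class Rule:
    """One region of the partition: path conditions + local linear model.

    ``conditions`` maps feature index -> (lower, upper]; a point x matches when
    lower < x[k] <= upper for every constrained feature k (thresholds are
    left-inclusive: "<= threshold" routes left).
    """

    conditions: dict[int, tuple[float, float]]
    coefficients: np.ndarray  # [beta_0, beta_1..beta_d]
    coverage: int
    region_id: int

    def matches(self, x: np.ndarray) -> bool:
        return all(lo < x[k] <= hi for k, (lo, hi) in self.conditions.items())

    def matches_rows(self, X: np.ndarray) -> np.ndarray:
        ok = np.ones(X.shape[0], dtype=bool)
        for k, (lo, hi) in self.conditions.items():
            ok &= (X[:, k] > lo) & (X[:, k] <= hi)
        return ok

    def predict(self, x: np.ndarray) -> float:
        return float(self.coefficients[0] + x @ self.coefficients[1:])


@dataclass
class CubistModel:
    """Fitted rule list + global linear model + feature-map layout."""

    rules: list[Rule]
    global_model: np.ndarray
    feature_dim: int
    n_features: int
    target_mean: float
    target_std: float
    split_stats: list[dict] = field(default_factory=list)
    # rule indices (into self.rules) occupying the indicator slots, by coverage
    _indicator_rules: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature_dim < 3:
            raise ValueError("feature_dim must be at least 3")
        if not self._indicator_rules:
            order = sorted(
                range(len(self.rules)),
                key=lambda i: (-self.rules[i].coverage, self.rules[i].region_id),
            )
            self._indicator_rules = order[: self.feature_dim - 2]

    # -- prediction ---------------------------------------------------------

    def _match_index(self, x: np.ndarray) -> int | None:
        for i, r in enumerate(self.rules):
            if r.matches(x):
                return i
        return None

    def predict(self, x: np.ndarray) -> float:
        """Local-model prediction of the unique matching rule (Cubist y-hat)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_features,):
            raise ValueError(
                f"expected feature vector of length {self.n_features}, got {x.shape}"
            )
        i = self._match_index(x)
        if i is None:  # numeric edge: fall back to the global model
            return float(self.global_model[0] + x @ self.global_model[1:])
        return self.rules[i].predict(x)

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`predict` over the rows of an (N, d) matrix."""
        X = np.asarray(X, dtype=float)
        out = X @ self.global_model[1:] + self.global_model[0]
        assigned = np.zeros(X.shape[0], dtype=bool)
        for r in self.rules:
            sel = r.matches_rows(X) & ~assigned
            if sel.any():
                out[sel] = X[sel] @ r.coefficients[1:] + r.coefficients[0]
                assigned[sel] = True
        return out

    # -- structured features -------------------------------------------------

    def rule_features(self, x: np.ndarray) -> np.ndarray:
        """m-vector F: top-coverage rule indicators + standardized predictions."""
        x = np.asarray(x, dtype=float)
        F = np.zeros(self.feature_dim)
        i = self._match_index(x)
        if i is not None and i in self._indicator_rules:
            F[self._indicator_rules.index(i)] = 1.0
        local = (
            self.rules[i].predict(x)
            if i is not None
            else float(self.global_model[0] + x @ self.global_model[1:])
        )
        glob = float(self.global_model[0] + x @ self.global_model[1:])
        F[-2] = (local - self.target_mean) / self.target_std
        F[-1] = (glob - self.target_mean) / self.target_std
        return F

    def featurize_rows(self, X: np.ndarray) -> np.ndarray:
        """Vectorized rule_features over (N, d) rows -> (N, m)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        F = np.zeros((n, self.feature_dim))
        glob = X @ self.global_model[1:] + self.global_model[0]
        local = glob.copy()
        assigned = np.zeros(n, dtype=bool)
        for i, r in enumerate(self.rules):
            sel = r.matches_rows(X) & ~assigned
            if not sel.any():
                continue
            local[sel] = X[sel] @ r.coefficients[1:] + r.coefficients[0]
            if i in self._indicator_rules:
                F[sel, self._indicator_rules.index(i)] = 1.0
            assigned[sel] = True
        F[:, -2] = (local - self.target_mean) / self.target_std
        F[:, -1] = (glob - self.target_mean) / self.target_std
        return F

    def featurize_windows(self, X: np.ndarray) -> np.ndarray:
        """Apply the feature map at every (window, step): (N, T, d) -> (N, T, m)."""
        X = np.asarray(X, dtype=float)
        N, T, d = X.shape
        return self.featurize_rows(X.reshape(N * T, d)).reshape(N, T, self.feature_dim)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "ecorestore-cubist",
            "version": 1,
            "n_features": self.n_features,
            "feature_dim": self.feature_dim,
            "target_mean": self.target_mean,
            "target_std": self.target_std,
            "global_model": self.global_model.tolist(),
            "indicator_rules": list(self._indicator_rules),
            "split_stats": self.split_stats,
            "rules": [
                {
                    "region_id": r.region_id,
                    "coverage": r.coverage,
                    "conditions": {
                        str(k): [lo, hi] for k, (lo, hi) in r.conditions.items()
                    },
                    "coefficients": r.coefficients.tolist(),
                }
                for r in self.rules
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CubistModel":
        if d.get("format") != "ecorestore-cubist":
            raise ValueError("not a cubist model document")
        rules = [
            Rule(
                conditions={
                    int(k): (float(v[0]), float(v[1]))
                    for k, v in rd["conditions"].items()
                },
                coefficients=np.asarray(rd["coefficients"], dtype=float),
                coverage=int(rd["coverage"]),
                region_id=int(rd["region_id"]),
            )
            for rd in d["rules"]
        ]
        return cls(
            rules=rules,
            global_model=np.asarray(d["global_model"], dtype=float),
            feature_dim=int(d["feature_dim"]),
            n_features=int(d["n_features"]),
            target_mean=float(d["target_mean"]),
            target_std=float(d["target_std"]),
            split_stats=list(d.get("split_stats", [])),
            _indicator_rules=list(d["indicator_rules"]),
        )

    @classmethod
    def from_json(cls, path) -> "CubistModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# induction
# ---------------------------------------------------------------------------

def _sd(y_sum: float, y_sq: float, n: int) -> float:
    var = y_sq / n - (y_sum / n) ** 2
    return float(np.sqrt(max(var, 0.0)))


def best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (feature, threshold, SDR) over midpoint candidates, or None.

    Children must each hold at least ``min_leaf`` rows.  Ties are broken by
    lower feature index, then smaller threshold, making induction independent
    of row order.
    """
    n = len(y)
    parent_sd = float(y.std())
    best = None  # (sdr, feature, threshold)
    for k in range(X.shape[1]):
        order = np.argsort(X[:, k], kind="stable")
        xs = X[order, k]
        ys = y[order]
        cum_y = np.cumsum(ys)
        cum_y2 = np.cumsum(ys * ys)
        total_y, total_y2 = cum_y[-1], cum_y2[-1]
        # candidate split after position i (1-based count i+1 on the left)
        diffs = np.nonzero(xs[1:] > xs[:-1])[0]  # boundaries between uniques
        for i in diffs:
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            sd_l = _sd(cum_y[i], cum_y2[i], n_left)
            sd_r = _sd(total_y - cum_y[i], total_y2 - cum_y2[i], n_right)
            sdr = parent_sd - (n_left * sd_l + n_right * sd_r) / n
            thr = 0.5 * (xs[i] + xs[i + 1])
            cand = (sdr, k, thr)
            if best is None or sdr > best[0] + 1e-15:
                best = cand
    if best is None or best[0] < _SDR_MIN_IMPROVEMENT:
        return None
    return best


def _leaf_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS [intercept, betas]; ridge (lambda 1e-6) when rank-deficient."""
    n, d = X.shape
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < d + 1:
        reg = _RIDGE_LAMBDA * np.eye(d + 1)
        reg[0, 0] = 0.0  # never penalize the intercept
        return np.linalg.solve(A.T @ A + reg, A.T @ y)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int = 20,
    max_rules: int = 14,
    feature_dim: int = 16,
) -> CubistModel:
    """Grow the SDR tree and turn its leaves into a rule list.

    Growth is greedy best-first: the splittable leaf with the largest SDR is
    expanded until no leaf improves by more than 1e-9, every leaf is smaller
    than ``2 * min_leaf``, or the leaf count reaches ``max_rules``.  Constant
    targets (or N < 2 * min_leaf) yield the degenerate single-rule model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (N, d) with matching y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values not supported; preprocess first")
    n, d = X.shape

    global_model = (
        np.concatenate([[float(y.mean())], np.zeros(d)])
        if y.std() == 0.0
        else _leaf_ols(X, y)
    )
    target_std = float(y.std()) or 1.0

    # best-first growth; heap keyed by -SDR with an insertion counter tie-break
    no_bounds = {k: (-np.inf, np.inf) for k in range(d)}
    leaves: dict[int, tuple[np.ndarray, dict]] = {}  # id -> (row idx, bounds)
    heap: list = []
    counter = 0
    split_stats: list[dict] = []

    def consider(leaf_id, rows, bounds):
        nonlocal counter
        leaves[leaf_id] = (rows, bounds)
        if len(rows) >= 2 * min_leaf and y[rows].std() > 0.0:
            found = best_split(X[rows], y[rows], min_leaf)
            if found is not None:
                sdr, k, thr = found
                heapq.heappush(heap, (-sdr, counter, leaf_id, k, thr))
                counter += 1

    consider(0, np.arange(n), {k: (-np.inf, np.inf) for k in range(d)})
    next_id = 1
    while heap and len(leaves) < max_rules:
        neg_sdr, _, leaf_id, k, thr = heapq.heappop(heap)
        if leaf_id not in leaves:
            continue
        rows, bounds = leaves.pop(leaf_id)
        split_stats.append(
            {"node_size": int(len(rows)), "feature": int(k),
             "threshold": float(thr), "sdr": float(-neg_sdr)}
        )
        left = rows[X[rows, k] <= thr]
        right = rows[X[rows, k] > thr]
        lo, hi = bounds[k]
        lb = dict(bounds)
        lb[k] = (lo, thr)
        rb = dict(bounds)
        rb[k] = (thr, hi)
        consider(next_id, left, lb)
        consider(next_id + 1, right, rb)
        next_id += 2

    rules = []
    for j, leaf_id in enumerate(sorted(leaves)):
        rows, bounds = leaves[leaf_id]
        conds = {k: b for k, b in bounds.items() if b != (-np.inf, np.inf)}
        coef = (
            np.concatenate([[float(y[rows].mean())], np.zeros(d)])
            if y[rows].std() == 0.0
            else _leaf_ols(X[rows], y[rows])
        )
        rules.append(Rule(conditions=conds, coefficients=coef,
                          coverage=int(len(rows)), region_id=j))

    return CubistModel(
        rules=rules,
        global_model=global_model,
        feature_dim=feature_dim,
        n_features=d,
        target_mean=float(y.mean()),
        target_std=target_std,
        split_stats=split_stats,
    )


def fit_cubist_layer(
    X_windows: np.ndarray,
    y_windows: np.ndarray,
    min_leaf: int = 20,
    max_rules: int = 14,
    feature_dim: int = 16,
    step_targets: np.ndarray | None = None,
) -> CubistModel:
    """Fit the tree on flattened per-step rows of the *training* windows.

    With ``step_targets=None`` the per-step supervision target is the
    window-level target broadcast to every step of its window.  Passing an
    (N, T) array supervises each step on its own quantity instead — the
    restoration pipeline uses the one-month log-FVC growth, which the
    sequence layers then integrate over the window.
    """
    X_windows = np.asarray(X_windows, dtype=float)
    y_windows = np.asarray(y_windows, dtype=float)
    N, T, d = X_windows.shape
    rows = X_windows.reshape(N * T, d)
    if step_targets is None:
        targets = np.repeat(y_windows, T)
    else:
        step_targets = np.asarray(step_targets, dtype=float)
        if step_targets.shape != (N, T):
            raise ValueError("step_targets must be (N, T)")
        targets = step_targets.reshape(N * T)
    return fit_tree(rows, targets, min_leaf=min_leaf, max_rules=max_rules,
                    feature_dim=feature_dim)
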