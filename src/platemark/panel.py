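"""Leave-one-out panel evaluation and subset search.

Every candidate-protein subset ("panel") is scored by pooled leave-one-out
probabilities from an L2-penalized, class-weight-balanced logistic
regression.  Per fold, features are autoscaled with training-fold
statistics only; the held-out probability is recorded; the n pooled
probabilities give the confusion matrix (threshold 0.5 by default) and
the ROC / PR areas.  The search is fully deterministic — there is no
random state anywhere in folding or fitting.

The logistic fit minimizes

    sum_i s_i * logloss_i + (lam/2) * ||w||^2      (intercept unpenalized)

with balanced per-sample weights s_i = n / (2 * n_class(i)) and lam = 1,
solved by Newton iterations (batched across folds for speed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _m

_NEWTON_TOL = 1e-10
_NEWTON_MAX_ITER = 100
_DEFAULT_LAMBDA = 1.0


def loo_folds(sample_ids) -> list[tuple[list, object]]:
    """One (train_ids, test_id) pair per sample."""
    ids = list(sample_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    if len(ids) < 3:
        raise ValueError("need >=3 samples for leave-one-out")
    return [(ids[:i] + ids[i + 1:], ids[i]) for i in range(len(ids))]


def _balanced_weights(y: np.ndarray) -> np.ndarray:
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single-class training set")
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


def _newton_batch(Z: np.ndarray, y: np.ndarray, s: np.ndarray, lam: float) -> np.ndarray:
    """Batched Newton solver. Z: (F, n, d) with leading 1s column;
    y, s: (F, n). Returns beta: (F, d)."""
    f, n, d = Z.shape
    beta = np.zeros((f, d))
    pen = np.zeros(d)
    pen[1:] = lam  # intercept unpenalized
    eye = np.eye(d) * pen
    for _ in range(_NEWTON_MAX_ITER):
        eta = np.clip(np.einsum("fnd,fd->fn", Z, beta), -35.0, 35.0)
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = np.einsum("fnd,fn->fd", Z, s * (prob - y)) + pen * beta
        w = s * prob * (1.0 - prob)
        hess = np.einsum("fnd,fn,fne->fde", Z, w, Z) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        beta -= step
        if np.abs(step).max() < _NEWTON_TOL:
            break
    return beta


def fit_balanced_logistic(
    X, y, lam: float = _DEFAULT_LAMBDA
) -> tuple[np.ndarray, float]:
    """Single balanced L2-logistic fit; returns (weights, intercept).

    Features are used as passed (callers handle scaling).
    """
    x = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    s = _balanced_weights(yv)
    z = np.hstack([np.ones((len(yv), 1)), x])
    beta = _newton_batch(z[None], yv[None], s[None], lam)[0]
    return beta[1:], float(beta[0])


@dataclass
class _FoldPrep:
    """Per-fold autoscaled training tensors over the full candidate block."""

    sample_ids: list
    y: np.ndarray  # (n,)
    x_train: np.ndarray  # (n_folds, n-1, k_all) scaled with train stats
    x_test: np.ndarray  # (n_folds, k_all) held-out rows, train-scaled
    y_train: np.ndarray  # (n_folds, n-1)
    weights: np.ndarray  # (n_folds, n-1) balanced class weights


def _prepare_folds(X: pd.DataFrame, y: np.ndarray) -> _FoldPrep:
    x = X.to_numpy(dtype=float)
    n, k = x.shape
    folds = loo_folds(list(X.index))
    x_train = np.empty((n, n - 1, k))
    x_test = np.empty((n, k))
    y_train = np.empty((n, n - 1))
    weights = np.empty((n, n - 1))
    for f in range(n):
        tr = np.r_[0:f, f + 1:n]
        xt = x[tr]
        mu = xt.mean(axis=0)
        sd = xt.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x_train[f] = (xt - mu) / sd
        x_test[f] = (x[f] - mu) / sd
        y_train[f] = y[tr]
        weights[f] = _balanced_weights(y[tr])
    return _FoldPrep(list(X.index), y, x_train, x_test, y_train, weights)


def _loo_probabilities(prep: _FoldPrep, cols: np.ndarray, lam: float) -> np.ndarray:
    """Pooled held-out probabilities for the panel given by ``cols``."""
    n = len(prep.y)
    xt = prep.x_train[:, :, cols]
    z = np.concatenate([np.ones((n, n - 1, 1)), xt], axis=2)
    beta = _newton_batch(z, prep.y_train, prep.weights, lam)
    test = np.concatenate([np.ones((n, 1)), prep.x_test[:, cols]], axis=1)
    eta = np.clip(np.einsum("fd,fd->f", test, beta), -35.0, 35.0)
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class PanelEvaluation:
    panel: tuple[str, ...]
    probabilities: pd.Series  # pooled held-out probability per sample
    confusion: _m.ConfusionMatrix
    metrics: _m.MetricSet
    roc_points: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    pr_points: tuple[np.ndarray, np.ndarray]  # (recall, precision)
    degenerate: bool = False  # constant pooled probabilities


def _evaluate_probs(
    panel: tuple[str, ...], probs: np.ndarray, prep: _FoldPrep, threshold: float
) -> PanelEvaluation:
    y = prep.y
    degenerate = bool(np.all(probs == probs[0]))
    cm = _m.ConfusionMatrix.from_scores(y, probs, threshold)
    roc = _m.roc_curve_points(y, probs)
    pr = _m.pr_curve_points(y, probs)
    auc_r = 0.5 if degenerate else _m.auc_roc(y, probs)
    auc_p = _m.auc_pr(y, probs)
    return PanelEvaluation(
        panel=panel,
        probabilities=pd.Series(probs, index=prep.sample_ids, name="probability"),
        confusion=cm,
        metrics=_m.MetricSet.from_parts(cm, auc_r, auc_p),
        roc_points=roc,
        pr_points=pr,
        degenerate=degenerate,
    )


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return y


def evaluate_panel(
    X: pd.DataFrame,
    labels,
    panel,
    threshold: float = 0.5,
    lam: float = _DEFAULT_LAMBDA,
) -> PanelEvaluation:
    """Pooled-LOO evaluation of one protein subset.

    ``X`` is samples x proteins (log2 scale), ``labels`` is the binary
    target (1 = positive class, e.g. cognitively impaired).
    """
    panel = tuple(panel)
    if not panel:
        raise ValueError("panel is empty")
    missing = [p for p in panel if p not in X.columns]
    if missing:
        raise KeyError(f"panel proteins absent from matrix: {missing}")
    y = _as_labels(labels)
    prep = _prepare_folds(X[list(panel)], y)
    probs = _loo_probabilities(prep, np.arange(len(panel)), lam)
    return _evaluate_probs(panel, probs, prep, threshold)


def _rank_key(panel: tuple[str, ...], ms: _m.MetricSet):
    return (-ms.auc_roc, -ms.accuracy, len(panel), tuple(sorted(panel)))


@dataclass
class SearchResult:
    table: pd.DataFrame  # ranked panels with metric columns
    best: PanelEvaluation
    best_per_size: pd.DataFrame
    strategy: str

    @property
    def best_panel(self) -> tuple[str, ...]:
        return self.best.panel


def _result_from_evals(
    evals: list[tuple[tuple[str, ...], _m.MetricSet]],
    best_eval: PanelEvaluation,
    strategy: str,
) -> SearchResult:
    rows = []
    for panel, ms in sorted(evals, key=lambda e: _rank_key(e[0], e[1])):
        rows.append(
            {
                "panel": "+".join(sorted(panel)),
                "k": len(panel),
                "auc_roc": ms.auc_roc,
                "auc_pr": ms.auc_pr,
                "accuracy": ms.accuracy,
                "recall": ms.recall,
                "precision": ms.precision,
                "f1": ms.f1,
            }
        )
    table = pd.DataFrame(rows)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    best_per_size = table.groupby("k", as_index=False).first()
    return SearchResult(table, best_eval, best_per_size, strategy)


def exhaustive_search(
    X: pd.DataFrame,
    labels,
    candidates,
    threshold: float = 0.5,
    lam: float = _DEFAULT_LAMBDA,
    max_candidates: int = 20,
) -> SearchResult:
    """Evaluate every non-empty subset of ``candidates`` (2^k - 1 panels).

    Panels are ranked by auc_roc desc, accuracy desc, size asc, then
    lexicographically; per-size winners are reported alongside.
    """
    candidates = list(candidates)
    if not 1 <= len(candidates) <= max_candidates:
        raise ValueError(
            f"exhaustive search supports 1..{max_candidates} candidates "
            f"(got {len(candidates)}); use greedy_forward_search instead"
        )
    y = _as_labels(labels)
    prep = _prepare_folds(X[candidates], y)
    evals: list[tuple[tuple[str, ...], _m.MetricSet]] = []
    best_key = None
    best_eval: PanelEvaluation | None = None
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(range(len(candidates)), size):
            panel = tuple(candidates[i] for i in combo)
            probs = _loo_probabilities(prep, np.array(combo), lam)
            ev = _evaluate_probs(panel, probs, prep, threshold)
            evals.append((panel, ev.metrics))
            key = _rank_key(panel, ev.metrics)
            if best_key is None or key < best_key:
                best_key = key
                best_eval = ev
    assert best_eval is not None
    return _result_from_evals(evals, best_eval, "exhaustive")


def greedy_forward_search(
    X: pd.DataFrame,
    labels,
    candidates,
    threshold: float = 0.5,
    lam: float = _DEFAULT_LAMBDA,
) -> SearchResult:
    """Forward selection: grow the panel by the candidate that most improves
    the ranking key; stop when no addition raises auc_roc."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates")
    y = _as_labels(labels)
    prep = _prepare_folds(X[candidates], y)
    index_of = {c: i for i, c in enumerate(candidates)}

    current: tuple[str, ...] = ()
    current_eval: PanelEvaluation | None = None
    evals: list[tuple[tuple[str, ...], _m.MetricSet]] = []
    while True:
        best_step = None
        for c in candidates:
            if c in current:
                continue
            panel = current + (c,)
            cols = np.array([index_of[p] for p in panel])
            probs = _loo_probabilities(prep, cols, lam)
            ev = _evaluate_probs(panel, probs, prep, threshold)
            evals.append((panel, ev.metrics))
            key = _rank_key(panel, ev.metrics)
            if best_step is None or key < best_step[0]:
                best_step = (key, ev)
        if best_step is None:
            break
        _, ev = best_step
        if current_eval is not None and ev.metrics.auc_roc <= current_eval.metrics.auc_roc:
            break
        current = ev.panel
        current_eval = ev
    assert current_eval is not None
    return _result_from_evals(evals, current_eval, "greedy")
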