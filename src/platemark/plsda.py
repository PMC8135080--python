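"""PLS-DA (NIPALS) with variable importance in projection (VIP) scoring.

X is the samples x candidate-proteins block, autoscaled per column; Y is
the column-centered one-hot class matrix.  Components are extracted with
the classic NIPALS algorithm and deflation; VIP aggregates each
predictor's weight across components, weighted by the Y-variance each
component explains, so that the mean squared VIP over predictors is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GROUPS

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


@dataclass
class PLSDAModel:
    protein_ids: list[str]
    classes: list[str]
    n_components: int
    W: np.ndarray  # X weights, P x A, unit-norm columns
    P_load: np.ndarray  # X loadings, P x A
    Q: np.ndarray  # Y loadings, G x A
    T: np.ndarray  # X scores, N x A
    ssy: np.ndarray  # explained Y variance per component, length A
    x_mean: np.ndarray
    x_sd: np.ndarray
    sample_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.T,
            index=self.sample_ids,
            columns=[f"t{a+1}" for a in range(self.n_components)],
        )


def _class_order(groups: pd.Series) -> list[str]:
    present = list(pd.unique(groups))
    known = [g for g in GROUPS if g in present]
    other = sorted(g for g in present if g not in GROUPS)
    return known + other


def fit_plsda(
    X: pd.DataFrame, groups: pd.Series, n_components: int = 2
) -> PLSDAModel:
    """Fit a PLS-DA model by NIPALS with deflation.

    ``X`` is samples x proteins; ``groups`` gives the class per sample.
    Deterministic: the starting Y-score for each component is the residual
    Y column with the largest variance.
    """
    groups = groups.loc[X.index]
    classes = _class_order(groups)
    if len(classes) < 2:
        raise ValueError("need >=2 classes for PLS-DA")
    if X.shape[1] < 1:
        raise ValueError("need >=1 candidate protein")
    x = X.to_numpy(dtype=float)
    n, p = x.shape
    x_mean = x.mean(axis=0)
    x_sd = x.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(x_sd == 0)
    if len(zero_var):
        bad = [X.columns[i] for i in zero_var]
        raise ValueError(f"zero-variance candidate column(s): {bad[:5]}")
    xr = (x - x_mean) / x_sd
    y = np.zeros((n, len(classes)))
    for j, c in enumerate(classes):
        y[:, j] = (groups.to_numpy() == c).astype(float)
    yr = y - y.mean(axis=0)

    a_max = min(n_components, n - 1, p)
    W = np.zeros((p, a_max))
    P_load = np.zeros((p, a_max))
    Q = np.zeros((len(classes), a_max))
    T = np.zeros((n, a_max))
    ssy = np.zeros(a_max)
    n_fit = 0
    for a in range(a_max):
        u = yr[:, np.argmax(yr.var(axis=0))].copy()
        if np.linalg.norm(u) < 1e-12:
            break  # Y residual exhausted
        t_old = np.zeros(n)
        w = q = t = None
        for _ in range(_NIPALS_MAX_ITER):
            w = xr.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                w = None
                break
            w /= nw
            t = xr @ w
            q = yr.T @ t / (t @ t)
            u = yr @ q / (q @ q)
            if np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        if w is None or q is None or (t @ t) < 1e-24:
            break
        p_load = xr.T @ t / (t @ t)
        W[:, a] = w
        P_load[:, a] = p_load
        Q[:, a] = q
        T[:, a] = t
        ssy[a] = (q @ q) * (t @ t)
        xr = xr - np.outer(t, p_load)
        yr = yr - np.outer(t, q)
        n_fit = a + 1
    if n_fit == 0:
        raise ValueError("NIPALS extracted no components (degenerate input)")
    return PLSDAModel(
        protein_ids=list(X.columns),
        classes=classes,
        n_components=n_fit,
        W=W[:, :n_fit],
        P_load=P_load[:, :n_fit],
        Q=Q[:, :n_fit],
        T=T[:, :n_fit],
        ssy=ssy[:n_fit],
        x_mean=x_mean,
        x_sd=x_sd,
        sample_ids=list(X.index),
    )


def vip_scores(model: PLSDAModel) -> pd.Series:
    """VIP_j = sqrt(P * sum_a ssy_a * w_ja^2 / sum_a ssy_a).

    W columns are unit-norm, so sum_j VIP_j^2 = P exactly.
    """
    p = model.W.shape[0]
    num = (model.W**2) @ model.ssy
    vip = np.sqrt(p * num / model.ssy.sum())
    return pd.Series(vip, index=model.protein_ids, name="vip")


def select_candidates(vip: pd.Series, threshold: float = 1.0) -> list[str]:
    """Proteins with VIP strictly above threshold, VIP-descending
    (ties broken by protein id)."""
    passed = vip[vip > threshold]
    return sorted(passed.index, key=lambda pid: (-passed[pid], pid))
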