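"""Normalization, left-censored imputation, and per-protein group t-tests.

The stage mirrors the standard Perseus workflow for reporter-intensity
matrices: log2 transform, median centering of each sample column, random
downshifted-normal imputation of missing values, then two-sided two-sample
t-tests per protein for each group contrast.  Differential expression is
defined by raw p < alpha (no multiple-testing correction); a Benjamini-
Hochberg column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONTRASTS, GROUPS, ProteomeMatrix, contrast_name


def filter_by_coverage(matrix: ProteomeMatrix, min_group_frac: float = 0.7) -> ProteomeMatrix:
    """Drop proteins observed in fewer than ``min_group_frac`` of samples of
    any group (the quantified-in-each-group filter)."""
    keep = pd.Series(True, index=matrix.values.index)
    for g in GROUPS:
        cols = matrix.samples_in(g)
        if not cols:
            continue
        frac = matrix.values[cols].notna().mean(axis=1)
        keep &= frac >= min_group_frac
    values = matrix.values.loc[keep]
    return ProteomeMatrix(values, matrix.group.copy(), matrix.mmse.copy())


def normalize_columns(values: pd.DataFrame, already_log2: bool = False) -> pd.DataFrame:
    """Log2 transform (unless ``already_log2``) and median-center each sample
    column to the global median.  Idempotent on already-log2 input."""
    if already_log2:
        v = values.astype(float)
    else:
        arr = values.to_numpy(dtype=float)
        if np.nanmin(arr) <= 0:
            raise ValueError("raw abundances must be strictly positive for log2")
        v = np.log2(values.astype(float))
    all_missing = v.columns[v.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"sample column(s) entirely missing: {list(all_missing)}")
    col_medians = v.median(axis=0, skipna=True)
    global_median = float(np.nanmedian(v.to_numpy()))
    return v.sub(col_medians, axis=1) + global_median


def impute_downshifted(
    values: pd.DataFrame,
    rng: np.random.Generator,
    width: float = 0.3,
    downshift: float = 1.8,
) -> pd.DataFrame:
    """Replace missing log2 entries, per column, with draws from
    Normal(col_mean - downshift*col_sd, (width*col_sd)^2).

    Observed entries are never modified.
    """
    out = values.astype(float).copy()
    for col in out.columns:
        x = out[col]
        obs = x.dropna()
        n_miss = x.isna().sum()
        if n_miss == 0:
            continue
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has <2 observed values; cannot impute")
        mu = obs.mean()
        sd = obs.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_miss)
        out.loc[x.isna(), col] = draws
    return out


@dataclass
class DEComparison:
    """Per-protein test results for one ordered contrast (reference, test)."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # columns: mean_a, mean_b, log2fc, t, p, p_adj_BH, direction

    @property
    def name(self) -> str:
        return contrast_name(self.contrast)

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p"] < alpha]


def t_test_per_protein(
    values: pd.DataFrame,
    group: pd.Series,
    contrast: tuple[str, str],
    equal_var: bool = True,
) -> DEComparison:
    """Two-sided two-sample t-test per protein on log2 values.

    ``contrast`` is (reference a, test b); log2fc and the t statistic are
    oriented as mean_b - mean_a.  Student (pooled variance) by default,
    Welch with ``equal_var=False``.
    """
    a, b = contrast
    for g in (a, b):
        if g not in GROUPS:
            raise ValueError(f"unknown group label {g!r}")
    cols_a = list(group.index[group == a])
    cols_b = list(group.index[group == b])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"need >=2 samples per group for contrast {contrast}")
    xa = values[cols_a].to_numpy(dtype=float)
    xb = values[cols_b].to_numpy(dtype=float)
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise ValueError("t-test input contains missing values; impute first")
    t, p = stats.ttest_ind(xb, xa, axis=1, equal_var=equal_var)
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    log2fc = mean_b - mean_a
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj_BH": stats.false_discovery_control(p, method="bh"),
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=values.index,
    )
    return DEComparison(contrast=tuple(contrast), table=table)


@dataclass
class DESummary:
    """Significant-set bookkeeping across contrasts at a fixed alpha."""

    alpha: float
    counts: pd.DataFrame  # index contrast name, columns n_up / n_down / n_sig
    significant: dict[str, set[str]]
    overlap_ctrl: set[str]
    union_ctrl: set[str]
    union_all: set[str]


def summarize_de(comparisons: list[DEComparison], alpha: float = 0.05) -> DESummary:
    """Count up/down DE proteins per contrast and form the Ctrl-referenced
    overlap/union plus the all-contrast union (total differential set)."""
    universe = None
    for c in comparisons:
        idx = set(c.table.index)
        universe = idx if universe is None else universe
        if idx != universe:
            raise ValueError("comparisons must share a protein universe")
    sig: dict[str, set[str]] = {}
    rows = []
    for c in comparisons:
        s = c.table[c.table["p"] < alpha]
        sig[c.name] = set(s.index)
        rows.append(
            {
                "contrast": c.name,
                "n_up": int((s["direction"] == "up").sum()),
                "n_down": int((s["direction"] == "down").sum()),
                "n_sig": len(s),
            }
        )
    counts = pd.DataFrame(rows).set_index("contrast")
    ctrl_refd = [c.name for c in comparisons if c.contrast[0] == "Ctrl"]
    ctrl_sets = [sig[n] for n in ctrl_refd]
    overlap_ctrl = set.intersection(*ctrl_sets) if ctrl_sets else set()
    union_ctrl = set.union(*ctrl_sets) if ctrl_sets else set()
    union_all = set.union(*sig.values()) if sig else set()
    return DESummary(
        alpha=alpha,
        counts=counts,
        significant=sig,
        overlap_ctrl=overlap_ctrl,
        union_ctrl=union_ctrl,
        union_all=union_all,
    )


def run_all_contrasts(
    values: pd.DataFrame, group: pd.Series, equal_var: bool = True
) -> list[DEComparison]:
    return [t_test_per_protein(values, group, c, equal_var) for c in CONTRASTS]
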