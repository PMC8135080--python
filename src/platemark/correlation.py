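"""Per-protein Pearson correlation with the MMSE score and candidate
integration with the differential-expression results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def pearson_vs_mmse(
    values: pd.DataFrame, mmse: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r of every protein against MMSE, with exact-t p-values.

    Returns a frame indexed by protein with columns r, p, n, cls
    (NC = negative and p < alpha, PC = positive and p < alpha, else ns)
    and ``valid`` (False for zero-variance proteins, which get r = NaN and
    are excluded from classification).
    """
    if mmse.isna().any():
        raise ValueError("MMSE must be present for all samples")
    y = mmse.loc[values.columns].to_numpy(dtype=float)
    x = values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("correlation input contains missing values; impute first")
    n = x.shape[1]
    if n < 3:
        raise ValueError("need >=3 samples for a correlation p-value")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sy = float(np.sqrt((yc**2).sum()))
    if sy == 0:
        raise ValueError("MMSE has zero variance")
    sx = np.sqrt((xc**2).sum(axis=1))
    valid = sx > 0
    r = np.full(x.shape[0], np.nan)
    r[valid] = (xc[valid] @ yc) / (sx[valid] * sy)
    r = np.clip(r, -1.0, 1.0)
    p = np.full_like(r, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[valid] * np.sqrt((n - 2) / (1.0 - r[valid] ** 2))
    p[valid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    cls = np.where(
        valid & (p < alpha), np.where(r < 0, "NC", "PC"), "ns"
    )
    return pd.DataFrame(
        {"r": r, "p": p, "n": n, "cls": cls, "valid": valid}, index=values.index
    )


@dataclass
class CandidateSet:
    """Proteins that are both MMSE-correlated and differential, ranked by
    |r| descending (ties broken by protein id)."""

    table: pd.DataFrame  # index protein; columns r, p + de flags
    excluded: list[str] = field(default_factory=list)

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def build_candidates(
    corr_table: pd.DataFrame,
    de_union: set[str],
    alpha: float = 0.05,
    exclude=(),
    de_significant: dict[str, set[str]] | None = None,
) -> CandidateSet:
    """Intersect MMSE-correlated proteins (p < alpha) with the DE union.

    ``exclude`` removes proteins by id (e.g. a pathway-based exclusion
    list); ``de_significant`` adds one boolean flag column per contrast.
    """
    sig_corr = set(
        corr_table.index[(corr_table["valid"]) & (corr_table["p"] < alpha)]
    )
    members = sig_corr & set(de_union)
    excluded = sorted(members & set(exclude))
    members -= set(exclude)
    tbl = corr_table.loc[sorted(members), ["r", "p"]].copy()
    if de_significant:
        for name, ids in sorted(de_significant.items()):
            tbl[f"de_{name}"] = tbl.index.isin(ids)
    order = sorted(tbl.index, key=lambda pid: (-abs(tbl.at[pid, "r"]), pid))
    return CandidateSet(table=tbl.loc[order], excluded=excluded)


def candidate_corr_matrix(values: pd.DataFrame, candidates) -> pd.DataFrame:
    """Symmetric pairwise Pearson matrix over candidate proteins."""
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need >=2 candidates for a correlation matrix")
    x = values.loc[candidates].to_numpy(dtype=float)
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=candidates, columns=candidates)
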