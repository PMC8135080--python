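"""Trajectory clustering of differential proteins across ordered groups.

Each differential protein is summarized by its (Ctrl, MCI, AD) mean log2
abundance triple, standardized to mean 0 / SD 1, and the standardized
profiles are partitioned with k-means (k=3, seeded multi-start).  Clusters
are labeled by archetype: monotone_down, down_up (minimum at the middle
group), monotone_up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .cohort import GROUPS

ARCHETYPES = ("monotone_down", "down_up", "monotone_up")

#: cluster ids follow the archetype order above
ARCHETYPE_CLUSTER_ID = {a: i + 1 for i, a in enumerate(ARCHETYPES)}


def _standardize(triple: np.ndarray) -> np.ndarray:
    sd = triple.std(ddof=0)
    return (triple - triple.mean()) / sd


#: standardized template shapes used only for fallback labeling
_TEMPLATES = {
    "monotone_down": _standardize(np.array([1.0, 0.0, -1.0])),
    "down_up": _standardize(np.array([0.0, -1.0, 0.0])),
    "monotone_up": _standardize(np.array([-1.0, 0.0, 1.0])),
}

_FLAT_TOL = 1e-12


def compute_profiles(
    values: pd.DataFrame, group: pd.Series, de_ids
) -> pd.DataFrame:
    """Group-mean and standardized profiles for the given proteins.

    Returns a frame indexed by protein with columns mean_Ctrl/mean_MCI/
    mean_AD, z_Ctrl/z_MCI/z_AD and a ``flat`` flag (SD = 0 profiles, which
    are excluded from clustering).
    """
    de_ids = list(de_ids)
    if not de_ids:
        raise ValueError("de_ids is empty")
    missing = [p for p in de_ids if p not in values.index]
    if missing:
        raise KeyError(f"proteins absent from matrix: {missing[:5]}")
    means = pd.DataFrame(index=pd.Index(de_ids, name="protein"))
    for g in GROUPS:
        cols = list(group.index[group == g])
        means[f"mean_{g}"] = values.loc[de_ids, cols].mean(axis=1)
    m = means.to_numpy()
    sd = m.std(axis=1, ddof=0)
    flat = sd <= _FLAT_TOL
    z = np.zeros_like(m)
    z[~flat] = (m[~flat] - m[~flat].mean(axis=1, keepdims=True)) / sd[~flat, None]
    for j, g in enumerate(GROUPS):
        means[f"z_{g}"] = z[:, j]
    means["flat"] = flat
    return means


@dataclass
class ClusterResult:
    assignments: pd.Series  # protein -> cluster id in {1,2,3}
    archetypes: dict[int, str]  # cluster id -> archetype label
    centroids: pd.DataFrame  # index cluster id, columns z_Ctrl/z_MCI/z_AD
    flat_excluded: list[str]

    @property
    def sizes(self) -> dict[int, int]:
        return {c: int((self.assignments == c).sum()) for c in sorted(self.archetypes)}


def _label_centroids(centers: np.ndarray) -> list[str]:
    """Archetype per centroid; falls back to nearest-template matching."""
    labels: list[str | None] = []
    for c in centers:
        if c[0] > c[1] > c[2]:
            labels.append("monotone_down")
        elif c[0] < c[1] < c[2]:
            labels.append("monotone_up")
        elif c[1] < c[0] and c[1] < c[2]:
            labels.append("down_up")
        else:
            labels.append(None)
    if sorted(x for x in labels if x) != sorted(ARCHETYPES):
        cost = np.array(
            [[np.sum((c - _TEMPLATES[a]) ** 2) for a in ARCHETYPES] for c in centers]
        )
        rows, cols = linear_sum_assignment(cost)
        labels = [None] * len(centers)
        for r, c in zip(rows, cols):
            labels[r] = ARCHETYPES[c]
        warnings.warn(
            "centroids did not match distinct archetypes; "
            "labels assigned by nearest archetype template",
            stacklevel=2,
        )
    return labels  # type: ignore[return-value]


def cluster_k3(profiles: pd.DataFrame, seed: int = 0, n_starts: int = 20) -> ClusterResult:
    """k-means (k=3) on standardized profiles with seeded multi-start.

    Input rows are sorted by protein id before fitting, so the result is
    invariant to input ordering.  Flat profiles are excluded.
    """
    work = profiles.loc[~profiles["flat"]].sort_index()
    if len(work) < 3:
        raise ValueError("need >=3 non-flat profiles to cluster")
    z = work[[f"z_{g}" for g in GROUPS]].to_numpy()
    km = KMeans(n_clusters=3, n_init=n_starts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(z)
    labels = _label_centroids(km.cluster_centers_)
    raw_to_cluster = {i: ARCHETYPE_CLUSTER_ID[a] for i, a in enumerate(labels)}
    assignments = pd.Series(
        [raw_to_cluster[r] for r in raw], index=work.index, name="cluster"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_,
        columns=[f"z_{g}" for g in GROUPS],
        index=pd.Index([raw_to_cluster[i] for i in range(3)], name="cluster"),
    ).sort_index()
    archetypes = {ARCHETYPE_CLUSTER_ID[a]: a for a in labels}
    flat_excluded = list(profiles.index[profiles["flat"]])
    return ClusterResult(assignments, archetypes, centroids, flat_excluded)
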