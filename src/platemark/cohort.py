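"""Synthetic cohort generation with planted ground truth.

Builds protein x sample abundance matrices shaped like a three-group
(Ctrl / MCI / AD) cognition study: log-normal baseline abundances, three
planted trajectory archetypes across the ordered groups, proteins with a
controlled Pearson correlation to the MMSE score, a small "true panel"
separating impaired subjects from controls, and abundance-dependent
(left-censored) missingness.  Every planted structure is returned as
explicit ground truth so downstream stages can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("Ctrl", "MCI", "AD")

#: inclusive integer MMSE ranges per group
DEFAULT_MMSE_RANGES = {"Ctrl": (29, 30), "MCI": (18, 23), "AD": (2, 17)}

#: contrasts are (reference, test); fold change is mean(test) - mean(reference)
CONTRASTS = (("Ctrl", "MCI"), ("Ctrl", "AD"), ("MCI", "AD"))


def contrast_name(contrast: tuple[str, str]) -> str:
    a, b = contrast
    return f"{b}_vs_{a}"


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a synthetic cohort.

    ``effect_size`` is the log2 step applied at each group transition for
    trajectory proteins and the Ctrl-vs-impaired gap for panel proteins.
    ``target_corr`` is the absolute expected Pearson r of planted
    MMSE-correlated proteins; ``n_corr`` of them are planted with
    alternating signs.
    """

    n_ctrl: int = 9
    n_mci: int = 10
    n_ad: int = 9
    n_proteins: int = 3000
    n_cluster1: int = 160
    n_cluster2: int = 135
    n_cluster3: int = 65
    effect_size: float = 1.0
    mmse_ranges: dict = field(default_factory=lambda: dict(DEFAULT_MMSE_RANGES))
    panel_size: int = 4
    n_corr: int = 30
    target_corr: float = 0.55
    missing_rate: float = 0.0
    noise_sd: float = 0.5
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ctrl", "n_mci", "n_ad", "n_proteins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("n_cluster1", "n_cluster2", "n_cluster3", "panel_size", "n_corr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_planted = (
            self.n_cluster1
            + self.n_cluster2
            + self.n_cluster3
            + self.panel_size
            + self.n_corr
        )
        if n_planted > self.n_proteins:
            raise ValueError(
                f"planted proteins ({n_planted}) exceed n_proteins ({self.n_proteins})"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0.0 <= abs(self.target_corr) < 1.0:
            raise ValueError("target_corr must satisfy |r| < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if set(self.mmse_ranges) != set(GROUPS):
            raise ValueError(f"mmse_ranges must have keys {GROUPS}")
        for g, (lo, hi) in self.mmse_ranges.items():
            if not (0 <= lo <= hi <= 30):
                raise ValueError(f"MMSE range for {g} must lie within [0, 30]")

    @property
    def n_samples(self) -> int:
        return self.n_ctrl + self.n_mci + self.n_ad

    def replace(self, **kwargs) -> "CohortDesign":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ProteomeMatrix:
    """Abundance matrix (proteins x samples) with sample metadata."""

    values: pd.DataFrame
    group: pd.Series
    mmse: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.values.columns)
        if list(self.group.index) != samples or list(self.mmse.index) != samples:
            raise ValueError("group/mmse index must match matrix columns")
        unknown = set(self.group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if self.mmse.isna().any():
            raise ValueError("every sample needs an MMSE score")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.group.index[self.group == group])

    def copy(self) -> "ProteomeMatrix":
        return ProteomeMatrix(self.values.copy(), self.group.copy(), self.mmse.copy())


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    de_proteins maps contrast name -> set of proteins with a nonzero planted
    mean difference; cluster_assignment maps protein -> cluster id in
    {1, 2, 3}; mmse_correlated maps protein -> signed target Pearson r;
    true_panel lists the planted panel proteins.
    """

    de_proteins: dict[str, set[str]]
    cluster_assignment: dict[str, int]
    mmse_correlated: dict[str, float]
    true_panel: list[str]

    def __post_init__(self) -> None:
        bad = set(self.cluster_assignment.values()) - {1, 2, 3}
        if bad:
            raise ValueError(f"cluster ids must be in {{1,2,3}}, got {sorted(bad)}")
        planted_de = set().union(*self.de_proteins.values()) if self.de_proteins else set()
        if not set(self.true_panel) <= planted_de and self.true_panel:
            raise ValueError("true_panel must be a subset of planted DE proteins")

    @property
    def de_union(self) -> set[str]:
        if not self.de_proteins:
            return set()
        return set().union(*self.de_proteins.values())


def sample_mmse(group: str, rng: np.random.Generator, mmse_ranges=None) -> int:
    """Draw a uniform integer MMSE score from the group's inclusive range."""
    ranges = DEFAULT_MMSE_RANGES if mmse_ranges is None else mmse_ranges
    if group not in ranges:
        raise ValueError(f"unknown group {group!r}")
    lo, hi = ranges[group]
    return int(rng.integers(lo, hi + 1))


# log2 offsets per (role, group); trajectory steps are +/- effect_size per
# group transition, panel proteins drop by effect_size in both impaired groups
_ROLE_OFFSETS = {
    "cluster1": {"Ctrl": 1.0, "MCI": 0.0, "AD": -1.0},
    "cluster2": {"Ctrl": 0.0, "MCI": -1.0, "AD": 0.0},
    "cluster3": {"Ctrl": -1.0, "MCI": 0.0, "AD": 1.0},
    "panel": {"Ctrl": 0.0, "MCI": -1.0, "AD": -1.0},
}


def generate_cohort(design: CohortDesign) -> tuple[ProteomeMatrix, GroundTruth]:
    """Generate a synthetic cohort and its ground truth.

    Deterministic given ``design.seed``.  Baseline log2 abundances are
    Normal(baseline_mean, baseline_sd) per protein; residual noise is
    Normal(0, noise_sd) per cell; planted roles add group offsets or an
    MMSE-locked term on the log2 scale; the returned matrix is on the raw
    (2**log2) scale.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    p = design.n_proteins

    sample_ids = (
        [f"C{i+1:02d}" for i in range(design.n_ctrl)]
        + [f"M{i+1:02d}" for i in range(design.n_mci)]
        + [f"A{i+1:02d}" for i in range(design.n_ad)]
    )
    groups = (
        ["Ctrl"] * design.n_ctrl + ["MCI"] * design.n_mci + ["AD"] * design.n_ad
    )
    group = pd.Series(groups, index=sample_ids, name="group")
    mmse = pd.Series(
        [sample_mmse(g, rng, design.mmse_ranges) for g in groups],
        index=sample_ids,
        name="mmse",
        dtype=int,
    )

    protein_ids = [f"P{i:05d}" for i in range(p)]
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=p)
    log2 = baseline[:, None] + rng.normal(0.0, design.noise_sd, size=(p, n))

    # scatter planted roles over the protein index deterministically
    perm = rng.permutation(p)
    cuts = np.cumsum(
        [design.n_cluster1, design.n_cluster2, design.n_cluster3,
         design.panel_size, design.n_corr]
    )
    idx_c1, idx_c2, idx_c3, idx_panel, idx_corr = np.split(perm[: cuts[-1]], cuts[:-1])

    group_arr = np.asarray(groups)
    cluster_assignment: dict[str, int] = {}
    for cid, idx, role in ((1, idx_c1, "cluster1"), (2, idx_c2, "cluster2"),
                           (3, idx_c3, "cluster3")):
        offs = np.array([_ROLE_OFFSETS[role][g] for g in group_arr]) * design.effect_size
        log2[idx] += offs[None, :]
        for i in idx:
            cluster_assignment[protein_ids[i]] = cid

    offs = np.array([_ROLE_OFFSETS["panel"][g] for g in group_arr]) * design.effect_size
    log2[idx_panel] += offs[None, :]
    true_panel = [protein_ids[i] for i in idx_panel]

    # planted MMSE correlation: add beta * z(MMSE) so that the expected
    # Pearson r equals target_corr: beta = sd_noise * r / sqrt(1 - r^2)
    mmse_correlated: dict[str, float] = {}
    if design.n_corr > 0 and design.target_corr != 0:
        z = mmse.to_numpy(dtype=float)
        z = (z - z.mean()) / z.std(ddof=0)
        r = abs(design.target_corr)
        beta = design.noise_sd * r / np.sqrt(1.0 - r * r)
        signs = np.resize([1.0, -1.0], design.n_corr)
        log2[idx_corr] += (signs[:, None] * beta) * z[None, :]
        for s, i in zip(signs, idx_corr):
            mmse_correlated[protein_ids[i]] = float(s) * r

    de_proteins: dict[str, set[str]] = {contrast_name(c): set() for c in CONTRASTS}
    if design.effect_size != 0:
        role_ids = {
            "cluster1": [protein_ids[i] for i in idx_c1],
            "cluster2": [protein_ids[i] for i in idx_c2],
            "cluster3": [protein_ids[i] for i in idx_c3],
            "panel": true_panel,
        }
        for role, ids in role_ids.items():
            offsets = _ROLE_OFFSETS[role]
            for a, b in CONTRASTS:
                if offsets[a] != offsets[b]:
                    de_proteins[contrast_name((a, b))].update(ids)

    values = pd.DataFrame(
        np.exp2(log2), index=protein_ids, columns=sample_ids
    )
    matrix = ProteomeMatrix(values, group, mmse)
    if design.missing_rate > 0:
        matrix = inject_missing(matrix, design.missing_rate, rng)

    truth = GroundTruth(
        de_proteins=de_proteins,
        cluster_assignment=cluster_assignment,
        mmse_correlated=mmse_correlated,
        true_panel=true_panel if design.effect_size != 0 else [],
    )
    return matrix, truth


def inject_missing(
    matrix: ProteomeMatrix, missing_rate: float, rng: np.random.Generator
) -> ProteomeMatrix:
    """Set entries to NaN with abundance-dependent (left-censored) odds.

    Per-protein missingness probability decreases linearly with mean
    abundance rank, averaging ``missing_rate`` over the matrix, so low
    abundance proteins lose far more cells than high abundance ones.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if missing_rate == 0.0:
        return matrix
    values = matrix.values.to_numpy(dtype=float).copy()
    p = values.shape[0]
    mean_abund = np.nanmean(values, axis=1)
    rank = np.empty(p, dtype=float)
    rank[np.argsort(mean_abund, kind="stable")] = np.arange(p)
    prob = np.clip(2.0 * missing_rate * (1.0 - (rank + 0.5) / p), 0.0, 0.95)
    mask = rng.random(values.shape) < prob[:, None]
    values[mask] = np.nan
    out = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    return ProteomeMatrix(out, matrix.group.copy(), matrix.mmse.copy())


def impaired_labels(group: pd.Series) -> pd.Series:
    """Binary target: 1 for cognitively impaired (MCI or AD), 0 for Ctrl."""
    unknown = set(group) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return (group != "Ctrl").astype(int)
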