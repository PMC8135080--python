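"""Hypergeometric over-representation analysis against GMT gene sets."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...).

    Duplicate members within a line are dropped; malformed lines raise with
    their line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected "
                    f">=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: empty gene set at line {lineno}")
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(m)
            sets[name] = list(seen)
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def ora(
    target_ids,
    background_ids,
    collection: GeneSetCollection,
    min_overlap: int = 3,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    For each set, with background size N, set size K (restricted to the
    background), target size n and overlap k, p = P(X >= k).  Results are
    filtered to k >= min_overlap and p < alpha and sorted by p ascending.
    A BH-adjusted column over all tested sets is included for information.
    """
    target = set(target_ids)
    background = set(background_ids)
    offenders = sorted(target - background)
    if offenders:
        raise ValueError(f"target ids not in background: {offenders[:10]}")
    n_bg = len(background)
    n_target = len(target)
    rows = []
    for name, members in collection.sets.items():
        in_bg = background & set(members)
        overlap = sorted(target & in_bg)
        k = len(overlap)
        big_k = len(in_bg)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_target)) if big_k else 1.0
        rows.append(
            {
                "set": name,
                "k": k,
                "K": big_k,
                "n": n_target,
                "N": n_bg,
                "p": min(p, 1.0),
                "overlap": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj_BH"] = stats.false_discovery_control(df["p"], method="bh")
        df = df[(df["k"] >= min_overlap) & (df["p"] < alpha)]
        df = df.sort_values(["p", "set"]).reset_index(drop=True)
    return df
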