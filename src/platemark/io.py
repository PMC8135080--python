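"""TSV readers/writers for matrices, sample sheets and ground truth."""

from __future__ import annotations

import pandas as pd

from .cohort import GroundTruth, ProteomeMatrix


def write_matrix(matrix: ProteomeMatrix, matrix_path, samples_path) -> None:
    df = matrix.values.copy()
    df.index.name = "protein"
    df.to_csv(matrix_path, sep="\t")
    sheet = pd.DataFrame({"group": matrix.group.copy(), "mmse": matrix.mmse.copy()})
    sheet.index = sheet.index.rename("sample_id")
    sheet.to_csv(samples_path, sep="\t")


def read_matrix(matrix_path, samples_path) -> ProteomeMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index.name = None
    values.columns.name = None
    sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
    sheet.index.name = None
    missing = [c for c in ("group", "mmse") if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet = sheet.loc[list(values.columns)]
    return ProteomeMatrix(values, sheet["group"], sheet["mmse"].astype(int))


def write_ground_truth(truth: GroundTruth, path) -> None:
    proteins = sorted(
        set(truth.cluster_assignment)
        | set(truth.mmse_correlated)
        | set(truth.true_panel)
        | truth.de_union
    )
    contrasts = sorted(truth.de_proteins)
    rows = []
    for pid in proteins:
        row = {
            "protein": pid,
            "cluster": truth.cluster_assignment.get(pid, 0),
            "target_r": truth.mmse_correlated.get(pid, 0.0),
            "in_panel": int(pid in truth.true_panel),
        }
        for c in contrasts:
            row[f"de_{c}"] = int(pid in truth.de_proteins[c])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    de_cols = [c for c in df.columns if c.startswith("de_")]
    de = {
        c[3:]: set(df.loc[df[c] == 1, "protein"]) for c in de_cols
    }
    cluster = {
        r.protein: int(r.cluster) for r in df.itertuples() if r.cluster != 0
    }
    corr = {
        r.protein: float(r.target_r) for r in df.itertuples() if r.target_r != 0.0
    }
    panel = list(df.loc[df["in_panel"] == 1, "protein"])
    return GroundTruth(de, cluster, corr, panel)
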