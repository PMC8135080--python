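"""End-to-end pipeline: preprocess -> DE -> clustering -> correlation ->
(optional) enrichment -> PLS-DA/VIP -> panel search, with a TSV report
bundle and full parameter logging for exact replay."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, enrichment, io, panel, plsda, preprocess, trajectory
from .cohort import ProteomeMatrix, impaired_labels

log = logging.getLogger("platemark")


@dataclass
class PipelineConfig:
    matrix: str = ""
    samples: str = ""
    gmt: str | None = None
    out_dir: str = "platemark_out"
    alpha_de: float = 0.05
    alpha_corr: float = 0.05
    min_group_coverage: float = 0.7
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    equal_var: bool = True
    cluster_starts: int = 20
    vip_threshold: float = 1.0
    n_components: int = 2
    ora_min_overlap: int = 3
    ora_alpha: float = 0.01
    threshold: float = 0.5
    strategy: str = "exhaustive"
    exclude: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage_seeds(master: int, n: int = 4) -> list[int]:
    """Fan the master seed out to per-stage seeds (documented derivation:
    SeedSequence(master).spawn)."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]


@dataclass
class PipelineResult:
    config: PipelineConfig
    de_summary: preprocess.DESummary
    clusters: trajectory.ClusterResult | None
    corr_table: pd.DataFrame
    candidates: correlation.CandidateSet
    enrichment_table: pd.DataFrame | None
    vip: pd.Series | None
    selected: list[str]
    search: panel.SearchResult | None
    summary: pd.DataFrame


def run_pipeline(
    config: PipelineConfig, matrix: ProteomeMatrix | None = None
) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "params.yaml")
    seed_impute, seed_cluster, *_ = _stage_seeds(config.seed)

    if matrix is None:
        matrix = io.read_matrix(config.matrix, config.samples)
    log.info(
        "input: %d proteins x %d samples", len(matrix.protein_ids), len(matrix.sample_ids)
    )

    # --- preprocess -------------------------------------------------------
    matrix = preprocess.filter_by_coverage(matrix, config.min_group_coverage)
    log.info(
        "coverage filter (>=%.0f%% per group): %d proteins retained",
        100 * config.min_group_coverage, len(matrix.protein_ids),
    )
    values = preprocess.normalize_columns(matrix.values)
    values = preprocess.impute_downshifted(
        values,
        np.random.default_rng(seed_impute),
        width=config.impute_width,
        downshift=config.impute_downshift,
    )
    norm = values.copy()
    norm.index.name = "protein"
    norm.to_csv(out / "normalized_matrix.tsv", sep="\t")

    # --- differential expression -----------------------------------------
    comparisons = preprocess.run_all_contrasts(values, matrix.group, config.equal_var)
    de_long = []
    for c in comparisons:
        t = c.table.copy()
        t.insert(0, "contrast", c.name)
        t.index.name = "protein"
        de_long.append(t.reset_index())
    pd.concat(de_long).to_csv(out / "de_results.tsv", sep="\t", index=False)
    de_summary = preprocess.summarize_de(comparisons, config.alpha_de)
    de_summary.counts.to_csv(out / "de_summary.tsv", sep="\t")
    log.info(
        "DE at p<%g: %s; union %d proteins",
        config.alpha_de,
        de_summary.counts["n_sig"].to_dict(),
        len(de_summary.union_all),
    )

    # --- trajectory clustering -------------------------------------------
    clusters = None
    if len(de_summary.union_all) >= 3:
        profiles = trajectory.compute_profiles(
            values, matrix.group, sorted(de_summary.union_all)
        )
        clusters = trajectory.cluster_k3(
            profiles, seed=seed_cluster, n_starts=config.cluster_starts
        )
        cl = pd.DataFrame(
            {
                "cluster": clusters.assignments,
                "archetype": clusters.assignments.map(clusters.archetypes),
            }
        )
        cl.index.name = "protein"
        cl.to_csv(out / "clusters.tsv", sep="\t")
        clusters.centroids.to_csv(out / "centroids.tsv", sep="\t")
        log.info("cluster sizes: %s", clusters.sizes)

    # --- MMSE correlation and candidates ---------------------------------
    corr_table = correlation.pearson_vs_mmse(values, matrix.mmse, config.alpha_corr)
    ct = corr_table.copy()
    ct.index.name = "protein"
    ct.to_csv(out / "correlation.tsv", sep="\t")
    n_nc = int((corr_table["cls"] == "NC").sum())
    n_pc = int((corr_table["cls"] == "PC").sum())
    log.info("MMSE-correlated at p<%g: %d NC, %d PC", config.alpha_corr, n_nc, n_pc)
    candidates = correlation.build_candidates(
        corr_table,
        de_summary.union_all,
        alpha=config.alpha_corr,
        exclude=config.exclude,
        de_significant=de_summary.significant,
    )
    cand_tbl = candidates.table.copy()
    cand_tbl.index.name = "protein"
    cand_tbl.to_csv(out / "candidates.tsv", sep="\t")
    log.info("candidates (DE & MMSE-correlated): %d", len(candidates))
    if len(candidates) >= 2:
        cm = correlation.candidate_corr_matrix(values, candidates.proteins)
        cm.stack().rename("r").rename_axis(["protein_a", "protein_b"]).to_csv(
            out / "candidate_correlations.tsv", sep="\t"
        )

    # --- enrichment (optional) -------------------------------------------
    enrichment_table = None
    if config.gmt:
        collection = enrichment.read_gmt(config.gmt)
        enrichment_table = enrichment.ora(
            sorted(de_summary.union_all),
            matrix.protein_ids,
            collection,
            min_overlap=config.ora_min_overlap,
            alpha=config.ora_alpha,
        )
        enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        log.info("enrichment: %d sets pass", len(enrichment_table))
    else:
        log.info("enrichment: skipped (no GMT configured)")

    # --- PLS-DA / VIP -----------------------------------------------------
    vip = None
    selected: list[str] = []
    if len(candidates) >= 1:
        X = values.loc[candidates.proteins].T
        model = plsda.fit_plsda(X, matrix.group, config.n_components)
        vip = plsda.vip_scores(model)
        model.scores_frame().to_csv(out / "plsda_scores.tsv", sep="\t")
        v = vip.to_frame()
        v.index.name = "protein"
        v.to_csv(out / "plsda_vip.tsv", sep="\t")
        selected = plsda.select_candidates(vip, config.vip_threshold)
        log.info("VIP>%g: %d of %d candidates", config.vip_threshold, len(selected), len(vip))

    # --- panel search -----------------------------------------------------
    search = None
    if selected:
        labels = impaired_labels(matrix.group)
        X = values.loc[selected].T
        strategy = config.strategy
        if strategy == "exhaustive" and len(selected) > 20:
            log.warning("%d candidates > 20; falling back to greedy search", len(selected))
            strategy = "greedy"
        if strategy == "exhaustive":
            search = panel.exhaustive_search(
                X, labels.to_numpy(), selected, threshold=config.threshold
            )
        elif strategy == "greedy":
            search = panel.greedy_forward_search(
                X, labels.to_numpy(), selected, threshold=config.threshold
            )
        else:
            raise ValueError(f"unknown search strategy {config.strategy!r}")
        search.table.to_csv(out / "panels.tsv", sep="\t")
        search.best_per_size.to_csv(out / "panels_best_per_size.tsv", sep="\t", index=False)
        best = search.best
        best.probabilities.rename_axis("sample_id").to_frame().assign(
            label=labels.to_numpy()
        ).to_csv(out / "best_panel_probabilities.tsv", sep="\t")
        fpr, tpr = best.roc_points
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
            out / "best_panel_roc.tsv", sep="\t", index=False
        )
        rec, prec = best.pr_points
        pd.DataFrame({"recall": rec, "precision": prec}).to_csv(
            out / "best_panel_pr.tsv", sep="\t", index=False
        )
        log.info(
            "best panel %s: auc_roc=%.3f accuracy=%.3f",
            "+".join(best.panel), best.metrics.auc_roc, best.metrics.accuracy,
        )

    # --- summary ----------------------------------------------------------
    rows = [
        ("n_proteins_tested", len(matrix.protein_ids)),
        ("n_samples", len(matrix.sample_ids)),
        ("de_union", len(de_summary.union_all)),
        ("de_overlap_ctrl_contrasts", len(de_summary.overlap_ctrl)),
        ("n_nc", n_nc),
        ("n_pc", n_pc),
        ("n_candidates", len(candidates)),
        ("n_vip_selected", len(selected)),
    ]
    for name, c in de_summary.counts.iterrows():
        rows.append((f"de_{name}_up", int(c["n_up"])))
        rows.append((f"de_{name}_down", int(c["n_down"])))
    if clusters is not None:
        for cid, size in clusters.sizes.items():
            rows.append((f"cluster{cid}_size", size))
    if search is not None:
        best = search.best
        rows += [
            ("best_panel", "+".join(best.panel)),
            ("best_auc_roc", round(best.metrics.auc_roc, 3)),
            ("best_auc_pr", round(best.metrics.auc_pr, 3)),
            ("best_accuracy", round(best.metrics.accuracy, 3)),
            ("best_recall", round(best.metrics.recall, 3)),
            ("best_precision", round(best.metrics.precision, 3)),
            ("best_f1", round(best.metrics.f1, 3)),
        ]
    summary = pd.DataFrame(rows, columns=["key", "value"]).set_index("key")
    summary.to_csv(out / "summary.tsv", sep="\t")

    return PipelineResult(
        config=config,
        de_summary=de_summary,
        clusters=clusters,
        corr_table=corr_table,
        candidates=candidates,
        enrichment_table=enrichment_table,
        vip=vip,
        selected=selected,
        search=search,
        summary=summary,
    )
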