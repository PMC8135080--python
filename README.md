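# platemark

Biomarker panel discovery from labeled proteomic abundance matrices.

Given a protein × sample abundance matrix (TSV), a sample sheet with a
three-level cognition group (`Ctrl` / `MCI` / `AD`) and a per-subject MMSE
score, and optionally a GMT gene-set file, the pipeline runs:

1. **preprocess** — per-group coverage filter, log2 + per-column median
   centering, Perseus-style downshifted-normal imputation of missing
   values, and two-sample t-tests per protein for each group contrast
   (raw p < 0.05 defines differential expression; a BH column is emitted
   for information).
2. **trajectory** — k-means (k = 3) on standardized (Ctrl, MCI, AD)
   mean-profiles of the differential proteins, labeled by archetype
   (monotone-down, down-up, monotone-up).
3. **correlation** — Pearson r of every protein against MMSE with exact-t
   p-values, NC/PC classification, and intersection with the DE union
   into a |r|-ranked candidate list (optional exclusion list), plus the
   candidate–candidate correlation matrix.
4. **enrichment** (optional) — hypergeometric over-representation of the
   DE union against GMT gene sets (overlap ≥ 3, p < 0.01 by default).
5. **plsda** — from-scratch NIPALS PLS-DA on the candidates with VIP
   scoring; candidates with VIP > 1 advance.
6. **panel search** — exhaustive (≤ 20 candidates; greedy beyond)
   leave-one-out evaluation of every candidate subset with a balanced,
   L2-penalized logistic classifier: pooled held-out probabilities,
   confusion matrix, ROC AUC (trapezoid, ties half-credited), PR AUC
   (step rule), ranked panel report.

A synthetic-cohort generator (`platemark.cohort`) plants trajectory
clusters, MMSE-correlated proteins, a true biomarker panel and
left-censored missingness with full ground truth, so every stage is
testable without any external data.

## CLI

```bash
# simulate a cohort with planted ground truth
platemark simulate --seed 1 --out-dir cohort/

# full pipeline + report bundle
platemark report --matrix cohort/matrix.tsv --samples cohort/samples.tsv \
    --out-dir out/ --seed 1

# individual stages
platemark de        --matrix cohort/matrix.tsv --samples cohort/samples.tsv
platemark cluster   --matrix cohort/matrix.tsv --samples cohort/samples.tsv
platemark correlate --matrix cohort/matrix.tsv --samples cohort/samples.tsv
platemark enrich    --matrix ... --samples ... --gmt sets.gmt
platemark plsda     --matrix ... --samples ... --candidates cands.txt
platemark search    --matrix ... --samples ... --candidates cands.txt
```

`platemark report` also accepts a YAML config (`--config`), with CLI
flags overriding individual keys; every run writes `params.yaml` so it
can be replayed exactly. All outputs are TSV.

## Layout

- `src/platemark/cohort.py` — synthetic cohorts + ground truth
- `src/platemark/preprocess.py` — normalization, imputation, t-tests
- `src/platemark/trajectory.py` — trajectory clustering
- `src/platemark/correlation.py` — MMSE correlation + candidates
- `src/platemark/enrichment.py` — GMT reader + hypergeometric ORA
- `src/platemark/plsda.py` — NIPALS PLS-DA + VIP
- `src/platemark/metrics.py`, `src/platemark/panel.py` — LOO panel search
- `src/platemark/pipeline.py`, `src/platemark/cli.py` — orchestration
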