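# sahr — tumor malignancy scoring by aggregated hazard ratios

`sahr` evaluates the malignant level of individual tumors from bulk
RNA-seq, for computational oncologists who have a gene-by-sample count
matrix and patient follow-up but no validated molecular grading scheme
for their cancer type.

The method rests on an empirical observation: genes dysregulated in
tumors do not relate to survival in one uniform way. Crossing the
tumor-vs-normal direction of each differentially expressed gene (DEG)
with the hazard ratio of its median-split patient groups yields four
behavioral classes:

| DE direction | higher expression → worse survival | category             |
|--------------|------------------------------------|----------------------|
| up           | yes                                | oncogene-like        |
| up           | no                                 | up-regulated-saver   |
| down         | yes                                | down-regulated-saver |
| down         | no                                 | suppressor-like      |

The **SAHR** (Score of Aggregated Hazard Ratio) of a tumor sums the
oriented hazard ratios of a trained gene panel, each signed by whether
the tumor sits on the risky side of the gene's expression cutoff:

```
SAHR = Σᵢ δᵢ · HRᵢ ,   δᵢ ∈ {+1, −1}
```

with δ = +1 when expression exceeds the training-cohort median for
oncogene-like and down-regulated-saver genes (and below it for the other
two classes). The panel takes the 20/20/10/10 smallest-p genes of the
four categories (hazard ratios above 20 are discarded as unreliable).
Tumors with SAHR > 0 form the predicted higher-malignancy group. Because
cutoff comparisons are rank-based, a panel transfers to another
expression platform by intersecting genes, re-anchoring cutoffs at the
new cohort's medians and freezing the training hazard ratios.

The package implements the whole chain — median-of-ratios normalization,
Welch-test DE mining with Benjamini-Hochberg control, in-house
Kaplan-Meier / Efron-tie Cox / log-rank / Kruskal-Wallis statistics,
panel training, scoring, transfer and stage-stratified evaluation — plus
a synthetic-cohort generator with planted ground truth so every stage is
testable without access to real patient data.

## Worked example

Simulate a 500-gene cohort (400 tumors, 50 adjacent normals, ten planted
genes per category with per-gene hazard ratio 2.5, 30% censoring), run
the full pipeline, and evaluate on the held-out half:

```python
from sahr import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo_run", simulate=True,
    simulation=SimulationConfig(seed=7), seed=7,
)
res = run_pipeline(cfg)
r = res.overall
print(len(res.model),
      f"HR={r.fit.hr:.3f} CI=({r.fit.hr_ci[0]:.3f},{r.fit.hr_ci[1]:.3f})",
      f"p={r.fit.wald_p:.3g}")
```

prints

```
20 HR=2.691 CI=(1.909,3.792) p=1.59e-08
```

meaning: 40 of 500 genes passed the DE filters, 20 of them were
prognosis-associated on the 200 training tumors and entered the panel,
and on the 200 held-out tumors the SAHR-positive group (n=103) died
2.69 times faster than the SAHR-negative group (n=97) — the score
recovers the planted malignancy axis. The stage-stratified report shows
the same separation inside early (I–II, HR=2.94) and late (III–IV,
HR=2.24) stages, i.e. the score adds information beyond staging (stages
are independent of expression in this simulation, so the
Kruskal-Wallis score-vs-stage trend is null, p=0.70).

The same steps are available as CLI subcommands:

```bash
sahr simulate --out-dir cohort --seed 7
sahr deg --expression cohort/counts.tsv --clinical cohort/clinical.tsv --out deg.tsv
sahr catalog --expression cohort/counts.tsv --clinical cohort/clinical.tsv \
             --deg-table deg.tsv --out catalog.tsv
sahr train --catalog catalog.tsv --out model.tsv
sahr score --model model.tsv --expression cohort/counts.tsv --out scores.tsv
sahr evaluate --scores scores.tsv --clinical cohort/clinical.tsv --out report.tsv
```

`sahr transfer` re-anchors a model on a new cohort's expression table;
`sahr pipeline --config run.yaml` drives everything from one YAML file.

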