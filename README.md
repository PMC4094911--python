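# morphindex

A two-block hierarchical OPLS discriminant pipeline that condenses regional
MRI morphometry (34 bilaterally-averaged cortical thickness measures and 23
ICV-normalised subcortical/global volumes) into a single continuous
per-subject **severity index**: near 0 for control-like morphometry, near 1
for disease-like morphometry, with values strictly above 0.5 labelled
*AD-like*. The package covers the full analysis chain:

- **`morphindex.synthetic`** — seeded synthetic cohorts with the structure
  the analysis assumes: medial-temporal-dominated group-mean shifts,
  inter-regional correlation (global + per-block factors), ICV scaling of
  volumes, per-group 12-month decline, and an APOE-e4 severity shift within
  the MCI group.
- **`morphindex.preprocessing`** — hemisphere averaging, ICV normalisation
  of volumes (thickness untouched), and frozen mean-centring/unit-variance
  scaling (training statistics re-applied verbatim to new data).
- **`morphindex.opls`** — from-scratch single-y OPLS (one predictive
  component plus orthogonal components), stratified k-fold cross-validation
  with Q2(Y) = 1 − PRESS/SSY (Q2 > 0.05 deemed significant), greedy
  orthogonal-component selection, and |loading|-based variable importance.
- **`morphindex.hierarchical`** — separate thickness and volume block
  models whose scores feed a top-level OPLS; its prediction is the index.
- **`morphindex.evaluation`** — confusion-count sensitivity/specificity
  (integer percent, half-up), empirical ROC/AUC with Hanley–McNeil SE, and
  the combined classification/conversion-prediction report.
- **`morphindex.longitudinal`** — annual rate of change (12-month index
  difference), average index, pattern-of-atrophy stratification, rank-sum /
  Spearman / paired tests, one-way ANOVA on rates and z-scored APOE
  stratification.
- **`morphindex.io` / `morphindex.pipeline` / `morphindex.cli`** — TSV
  tables, JSON model serialisation, YAML run configs, and a reproducibility
  manifest.

## CLI

```bash
# full demo: simulate -> fit -> index -> evaluate -> longitudinal
morphindex run-all --seed 1 --out-dir demo_run

# or stage by stage
morphindex simulate --seed 1 --out cohort.tsv
# training table must contain baseline AD/CTL rows only
morphindex fit --table train.tsv --model-out model.json --cv-out cv.tsv
morphindex index --model model.json --table cohort.tsv --out index.tsv
morphindex evaluate --index index.tsv --table cohort.tsv --cv-index cv.tsv --out report.tsv
morphindex longitudinal --index index.tsv --out longit.tsv
```

`run-all` writes the cohort, model JSON, per-subject index TSV, the
classification/prediction report, longitudinal derivations and statistics,
and `manifest.json` (config hash + versions); identical config + seed
reproduce every artifact bit-identically.

## Conventions

- Class coding CTL = 0, AD = 1; the index is the raw top-model prediction
  and is *not* clipped to [0, 1].
- Ties at the 0.5 cut are CTL-like (strictly-above rule).
- Sample SD (n − 1) everywhere; missing values are rejected, not imputed.
- Baseline AD/CTL metrics use out-of-fold CV predictions; follow-up and all
  MCI metrics use direct application of the final trained model.
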