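# pnstrat

Stratification of tumour cohorts by proteostasis-network (PN) gene
expression.

Bulk RNA-seq cohorts of cutaneous melanoma (and other tumours) split into
subtypes with distinct expression programmes of the ~428 "core PN" genes —
chaperones and co-chaperones, ubiquitin–proteasome components, and
autophagy factors.  `pnstrat` implements the full analysis that defines
and characterises these subtypes, plus a synthetic-cohort generator with
planted ground truth so every stage can be validated end to end:

1. **Purity adjustment** — bulk expression mixes tumour and stromal
   signal, so each gene's log2 expression is regressed on the per-sample
   tumour-purity estimate (OLS with intercept) and the residuals are used
   for clustering.
2. **Ward clustering** — samples are co-clustered with PN genes
   (Ward.D2 on Euclidean distances); sample clusters with lower mean
   expression of the anchor gene block are labelled **A**, the rest
   **B** (subtypes A1, A2, … merge into A/B).
3. **Composite differential expression** — a gene is called
   lower/higher in A only if a pooled-variance Student *t*-test on log
   expression **and** a negative-binomial count test both give raw
   *p* < 0.05 and Benjamini–Hochberg *q* < 0.1, with linear fold change
   A/B below 0.8 or above 1.25 and a consistent direction.  The count
   test is a simplified NB Wald test: median-of-ratios size factors,
   per-gene method-of-moments dispersion (floored at 1e−8), delta-method
   standard error on the log mean ratio.
4. **Resampling nulls** — (a) the DE-called fraction of the PN set is
   compared against the same statistic on random gene sets of equal size
   drawn without replacement (BH re-applied within each set); (b) the
   overlap of two DE gene lists is tested by permutation against
   independent uniform subsets, with the exact hypergeometric tail
   P(X ≥ k) as the analytic oracle.  Empirical p-values use the count
   convention #{draw ≥ observed}/n, so they are exact multiples of 1/n.
5. **Annotation** — chaperone-family and compartment breakdowns of the
   calls, per-sample mean set-expression contrasts (e.g. the small heat
   shock proteins), transcription-factor target coverage of the DE list,
   and exact 2×k Fisher tests.
6. **Survival** — Kaplan–Meier curves and the log-rank test between
   subtypes (optionally truncated at an analysis horizon, e.g. 3 years),
   Cox proportional hazards with age/stage/gender, and clinical-attribute
   association (Fisher for categorical, *t* for numeric, with the 0–3
   pigmentation score recoded to low/high at 0,1 vs 2,3).

The synthetic generator plants two latent sample groups, negative-binomial
counts with symmetric fold changes concentrated in a PN-like gene set,
purity confounding via a per-gene stromal effect scaled by (1 − purity),
and exponential survival with a group hazard ratio — the ground truth is
returned alongside the data.

## Worked example

```python
from pnstrat import run_pipeline

report = run_pipeline({
    "synthetic": {"seed": 7},                   # default 50+50-sample cohort
    "null": {"n_iter": 1000, "set_size": 428},
    "seed": 7,
})
```

The report (one JSON-serialisable section per stage) contains, for this
seed:

```
groups: {'A': 48, 'B': 52}   ARI vs truth: 0.921
DE calls: 53 lower, 77 higher, 298 unchanged (30.4% of the PN set)
sensitivity: 0.934   empirical FDR: 0.023
random-set null: draws mean 0.1374, observed 0.3061, p_emp = 0.0
log-rank: statistic 15.73, p = 7.30e-05
Cox group-B hazard ratio: 2.86 (p = 1.0e-05)
```

Reading: clustering on purity-adjusted residuals recovers the two planted
groups almost exactly (adjusted Rand 0.92); the composite caller flags
30.4% of the PN set versus 13.7% for random gene sets of the same size, so
no random set in 1000 draws reached the PN set's DE fraction (p_emp = 0);
and the planted survival contrast (true hazard ratio 2.5) is detected by
both the log-rank test and the covariate-adjusted Cox model.

The same stages are exposed as a CLI:

```sh
pnstrat simulate --seed 7 --outdir cohort/
pnstrat adjust  --fpkm cohort/fpkm.tsv --purity cohort/purity.tsv --out residuals.tsv
pnstrat cluster --residuals residuals.tsv --pn-sets pn.gmt --out groups.tsv
pnstrat de      --counts cohort/counts.tsv --fpkm cohort/fpkm.tsv \
                --groups groups.tsv --genes pn.gmt:pn_core --out de.tsv
pnstrat survival --clinical cohort/clinical.tsv --groups groups.tsv --out surv.json
pnstrat run     --config config.yaml --out report.json   # everything at once
```

Inputs are plain text: genes × samples TSV matrices (first header cell
`gene_id`), Broad-dialect GMT gene sets, and a clinical TSV with columns
`sample_id, time_years, event, age, gender, stage, pigmentation_score,
subsequent_metastasis`.

## Layout

```
src/pnstrat/
  datamodel.py   containers + TSV/GMT/JSON readers and writers
  synthetic.py   cohort generator with planted ground truth
  purity.py      log transform + per-gene purity residualisation
  stratify.py    Ward clustering, A/B labelling, merging, PCA overlay
  diffexp.py     t-test, NB Wald test, BH, fold change, composite call
  nulls.py       random-gene-set null and overlap permutation test
  annotation.py  family/compartment breakdowns, TF coverage, exact Fisher
  survival.py    KM + log-rank, Cox PH, clinical associations
  pipeline.py    end-to-end orchestration into one JSON report
  cli.py         click command-line interface
```

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
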