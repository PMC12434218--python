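# nutriscore

Cumulative nutritional-intensity scoring and cohort analysis for
paediatric haematopoietic stem-cell transplant (HSCT), CAR-T and stem-cell
gene therapy.

## The problem

Children undergoing transplant or cellular therapy routinely need
escalating nutritional support — from routine dietetic review through oral
supplements, enteral (tube) feeding, parenteral nutrition (PN) and
individually compounded ("bespoke") PN — yet there is no standard way to
quantify how *much* dietetic intervention a patient actually received.
`nutriscore` implements a time-weighted intensity index for exactly this:
each support level *j* carries a weight *w<sub>j</sub>* reflecting
escalating clinical effort

| level | routine review | oral support | enteral | PN | bespoke PN |
|---|---|---|---|---|---|
| weight | 1 | 2 | 4 | 6 | 7 |

and a patient's cumulative score over the first 100 post-transplant days
(day 0 = infusion) is

```
AUC_i = Σ_j  w_j · d_ij
```

where *d<sub>ij</sub>* is the number of days patient *i* spent on
intervention *j* inside the window. Days without dietetic contact score 0.
The score behaves like the area under the patient's support-level step
curve, integrating both invasiveness and duration into one number
(0–700 for a single modality under default weights).

Around the index the package provides:

- **`nutriscore.scoring`** — episode data model, interval-based scoring in
  two overlap conventions (`additive`, `max_per_day`), the Day +100
  "≥ PN" endpoint, and censoring rules for incomplete follow-up.
- **`nutriscore.synthetic_cohort`** — a covariate-stratified discrete-time
  Markov generator of synthetic cohorts (no patient data ship with the
  package), hand-calibrated so stratum score medians resemble a real
  paediatric transplant service.
- **`nutriscore.cohort_stats`** — Table-1-style summaries, bootstrap
  median CIs, t/ANOVA (plus rank-based) group tests, chi-square/Fisher
  proportion comparisons.
- **`nutriscore.regression`** — bivariable and multivariable logistic
  regression (IRLS, Wald odds ratios, per-100-unit OR transform,
  separation detection with a Firth fallback), ROC/AUC discrimination and
  forest-plot data.
- **`nutri`** — a CLI binding the pipeline: simulate → score → summarize
  → regress.

## Worked example

Score one patient with 10 days of routine review, 20 days of enteral
feeding and 5 days of PN:

```python
from nutriscore import (
    InterventionEpisode, PatientRecord, SupportLevel, compute_patient_auc,
)

rec = PatientRecord(
    patient_id="demo",
    episodes=[
        InterventionEpisode("demo", SupportLevel.ROUTINE, 0, 9),
        InterventionEpisode("demo", SupportLevel.ENTERAL, 10, 29),
        InterventionEpisode("demo", SupportLevel.PN, 30, 34),
    ],
)
res = compute_patient_auc(rec)
print(res.auc)                 # 120.0  (= 10*1 + 20*4 + 5*6)
print(res.level_at_last_day)   # SupportLevel.NONE — no support on day 99
```

Run the whole pipeline on a simulated 131-patient cohort:

```bash
$ nutri run --seed 1 --out-dir demo
nutriscore event=simulate n=131 seed=1
nutriscore event=score read=131 excluded_censored=0 scored=131
nutriscore event=summarize subgroups=14
nutriscore event=regress n=114 auc_roc=0.847
pipeline complete: scored 131/131 (0 censored) -> demo
```

`demo/` then holds the episode/covariate/score CSVs, a cohort summary
(this run: overall median score 331, IQR 189.5–470; 87.0% allogeneic),
per-subgroup medians with bootstrap CIs, the multivariable model table,
ROC points and a JSON fit report. The report for this run shows the model
discriminating Day +100 ≥ PN need with AUC-ROC 0.847, and a per-100-unit
odds ratio for the score of 2.05 (95% CI 1.37–3.06, p < 0.001) — i.e. the
odds of still needing parenteral support at Day +100 roughly double for
every 100 extra score points.

The same stages are available separately (`nutri simulate`, `nutri
score`, `nutri summarize`, `nutri regress`) for use with real episode and
covariate tables; see `nutri <cmd> --help` for the file formats.

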