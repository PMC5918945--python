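# bht — Brain Health Test screening toolkit

Implementation of the Brain Health Test (BHT), a two-stage dementia
screening instrument for primary care, together with the diagnostic
statistics used to validate it and a calibrated synthetic-cohort simulator.

The instrument has two parts:

1. **Risk evaluation.** A weighted risk score (RS, 1–18 points) over age
   bin, sex, and eight comorbidity/history factors, plus a **high-risk
   triage rule**: a subject proceeds to cognitive testing if they report
   memory decline (self or informant), need assistance managing money or
   medications, or have RS ≥ 8.
2. **Short cognitive test (BHT-cog, 0–16 points).** Orientation to time
   (0–4), immediate recall of five items (0–5), categorical verbal fluency
   binned to 0–2 points (<5 animals → 0, 5–8 → 1, ≥9 → 2), and delayed
   recall (0–5). A score **below** the cutoff (default 10) is
   screen-positive.

The final two-stage decision is the conjunction: positive iff high-risk
*and* cognitive score below the cutoff.

## Layout

| module           | contents                                                              |
|------------------|-----------------------------------------------------------------------|
| `bht.instrument` | scoring rules: `risk_score`, `is_high_risk`, `bht_cog_score`, `classify_cog`, `two_stage_classify` |
| `bht.validation` | `confusion_metrics`, `odds_ratio_woolf` (Woolf CI, Haldane–Anscombe zero-cell correction), `roc_curve` (trapezoid AUC ≡ tie-corrected Mann–Whitney, Hanley–McNeil CI), `optimal_cutoff` (Youden), `pearson_r`, `build_2x2` |
| `bht.cohort`     | cohort CSV read/write with validation and exclusion accounting, group summaries, packaged reference summary of the published validation cohort (166 healthy / 225 MCI / 422 dementia) |
| `bht.simulate`   | seedable three-group cohort generator calibrated to the published group distributions, optional latent-severity coupling |
| `bht.cli`        | `bht score | triage | validate | simulate | report`                    |

## CLI

```sh
# synthetic cohort, seed echoed in the CSV header
bht simulate --out cohort.csv --seed 42

# per-subject risk score, triage flag, cognitive score and decision
bht score cohort.csv -o scored.csv --cutoff 10 --rs-threshold 8

# diagnostic-accuracy report: ROC/AUC per contrast, metrics at the cutoff,
# headline odds ratios, education-stratified sub-reports
bht validate cohort.csv --format json -o report.json

# descriptive group summary
bht report cohort.csv
```

Cohort CSV schema (header mandatory, booleans 0/1, missing optional values
empty, group labels `healthy|mci|dementia|unknown`): `subject_id, group,
age, sex, education_lt6, bmi_lt18, stroke, diabetes, hypertension,
hyperlipidemia, head_trauma_loc, depression, memory_decline_subject,
memory_decline_informant, memory_impairment_doctor,
needs_assistance_money_meds, orientation_time, immediate_recall,
fluency_count, delayed_recall, mmse, cdr`. Lines starting with `#` are
ignored.

## Notes

- The published healthy-group hypertension count is misprinted (930); the
  packaged summary encodes 93, consistent with the printed 56% prevalence.
- The published triage specificity (44%) disagrees with the published
  counts (77/166 = 46.4%); this package reproduces the count-derived value
  and treats only the sensitivity figure as authoritative.
- Simulator item scores are clipped-and-rounded normals (only group
  means/SDs are published), so simulated group totals sit within about half
  a point of the published totals; the dependence structure between risk
  factors and cognition is unpublished and exposed as the `coupling`
  parameter rather than guessed.
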