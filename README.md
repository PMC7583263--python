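# cinrisk

Risk stratification of stage I endometrial carcinoma from chromosomal
instability (CIN) expression signatures.

Endometrial carcinoma is usually cured by surgery, but the choice of
adjuvant therapy for stage I disease — observation (OB), vaginal
brachytherapy (VBT) or external-beam radiotherapy (EBRT) — rests on
clinicopathological factors that leave many patients over- or
under-treated. Chromosomal instability, measured by the CIN25/CIN70
expression signatures (the 25 and 70 genes most correlated with total
functional aneuploidy in solid tumours), tracks most adverse prognostic
factors. Two mutations break the pattern: *POLE*-mutant tumours carry high
CIN signatures yet excellent outcomes, and *CTNNB1*-mutant tumours carry
low CIN signatures yet poor outcomes. Once those two mutations are handled
explicitly, the CIN signatures become strongly prognostic inside each
radiotherapy subgroup, and an integrated model combining pathology, CIN
level and POLE/CTNNB1 status stratifies stage I endometrioid carcinoma
into four tiers (low / intermediate / high / ultrahigh) mapped to OB, VBT,
EBRT and EBRT plus systemic therapy.

`cinrisk` implements that analysis as a tested library and CLI:

- **Signature scoring** — per-dataset Z-score normalization
  (`z_g = (x_g − mean_g)/sd_g` per gene row) and per-sample signature score
  `CIN_k(i) = (1/|G_k|) Σ_{g∈G_k} z_{gi}` for the shipped CIN25/CIN70 gene
  lists or custom lists.
- **Rule engines** — exclusion handling, the five-factor adjuvant
  radiotherapy classifier, the guidelines risk group, and the integrated
  four-tier model driven by a configurable YAML rule table with per-patient
  rule traces.
- **Survival analysis** — Kaplan–Meier, k-group log-rank,
  cumulative/dynamic time-dependent ROC with Kaplan–Meier censoring
  adjustment (`sens(c) = (1−S_c(t))·P(M>c)/(1−S(t))`), Youden-index cutoff
  selection, and Cox models that add `x·log(t)` terms for covariates
  failing the Schoenfeld proportional-hazards test.
- **Meta-analysis** — Cohen's d / Hedges' g standardized mean differences
  with inverse-variance fixed-effects pooling
  (`d̂ = Σw_i d_i / Σw_i`, `w_i = 1/SE_i²`) and forest-plot tables.
- **Synthetic cohorts** — a generator in which a single latent CIN factor
  drives signature-gene expression and exponential event hazards, with the
  anomalous POLE (high CIN, protective) and CTNNB1 (low CIN, hazardous)
  patterns built in and full ground truth recorded for recovery tests.

## Worked example

```python
from cinrisk import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(out_dir="out", seed=7,
                     simulation=SimConfig(n_patients=800, seed=7))
manifest = run_pipeline(cfg)
print(manifest["counts"]["subgroup_sizes"])
print(manifest["cutoffs"]["OB"])
```

prints

```
{'VBT': 292, 'OB': 275, 'EBRT': 233}
{'signature': 'CIN70', 'n_subgroup': 275, 'n_derivation': 175,
 'n_events_horizon': 26, 'auc': 0.772209, 'cutoff': -0.285114,
 'youden_j': 0.605956}
```

Of 800 simulated stage I patients, 275 fall in the observation subgroup;
its CIN70 cutoff is derived from the 175 members wild-type for both POLE
and CTNNB1 (the mutants are tiered by mutation rules instead), with a
5-year disease-free-survival AUC of 0.77. The run directory contains
`scores.tsv`, `stratification.tsv` (with rule traces), `cutoffs.json`,
`km_dfs_by_tier.tsv` and a `manifest.json` echoing the seed and the row
counts at every filter step; the Kaplan–Meier 5-year DFS estimates by tier
for this run are 0.91 (low), 0.60 (intermediate), 0.46 (high) and 0.32
(ultrahigh).

The same flow is available from the shell:

```bash
cinrisk simulate --seed 7 --out cohort/
cinrisk score --expression cohort/expression.tsv --out scores.tsv
cinrisk run-all --seed 7 --out out/
```

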