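# Methods

## Signature scoring

Expression matrices are standardized gene-wise within one dataset:
`z_gi = (x_gi − mean_g) / sd_g`, with the population (n) denominator by
default (`ddof` is configurable). Standardization never crosses datasets,
so scores from different platforms are comparable only on the Z scale.
Constant gene rows cannot be standardized; they are set to all-zero
(score-neutral) with a logged warning rather than dropped, so that
coverage counts stay stable. A signature score is the unweighted mean of
the Z-scores of the signature genes present in the matrix; matching is
case-insensitive, missing genes are skipped, and coverage below 80%
triggers a warning but not an error. Z-scores are averaged (rather than
Z-scoring per-sample averages): averaging standardized genes weights each
gene equally regardless of its dynamic range, which is the point of a
fixed signature.

The shipped CIN25/CIN70 lists are the top-25 and top-70
total-functional-aneuploidy correlates from the pan-cancer genomic
instability literature, CIN25 being the head of CIN70. Legacy identifiers
were modernised to current HGNC symbols where the rename is one-to-one;
three ambiguous legacy IDs are kept verbatim. Users may substitute any
one-symbol-per-line list.

## Adjuvant-radiotherapy and guidelines classifiers

Both classifiers are total functions of (histotype, grade, stage IA/IB,
age) on cleaned stage I records:

- OB: IA endometrioid (EEC) grade 1–2, or IB EEC grade 1–2 under age 60.
- EBRT: IB EEC grade 3, or any stage I non-EEC.
- VBT: the remainder (IB EEC grade 1–2 at ≥ 60, IA EEC grade 3).
- Guidelines risk: low = IA EEC G1–2; intermediate = IB EEC G1–2;
  high-intermediate = IA EEC G3; high = IB EEC G3 or non-EEC.

Age exactly 60 is assigned to the ≥ 60 (VBT) branch, matching the age
stratification used for the cohort tables. Records are excluded, in fixed
order with the first reason logged, for incomplete/invalid classification
or survival fields, other malignancies, and positive surgical margins.
Lymphovascular space invasion is not modelled (unavailable in the
reference cohort), and only stage I receives integrated tiers.

## Integrated four-tier model

The integrated model is an ordered rule table per subgroup over three
predicates: POLE mutation, CTNNB1 mutation, and the dichotomized CIN
level (score strictly above the subgroup cutoff ⇒ High; ties go Low,
which maximizes the High group under the ">" convention). The default
table uses CIN70 in OB and CIN25 in VBT/EBRT:

- OB: POLE-mut → low; wild-type/wild-type: CIN70 Low → low, High →
  intermediate; CTNNB1-mut: CIN70 Low → intermediate, High → high.
- VBT: POLE-mut → low; otherwise CIN25 Low → intermediate, High → high.
- EBRT (EEC only): CTNNB1-mut → ultrahigh; CTNNB1-wt/POLE-mut → high;
  otherwise CIN25 Low → high, High → ultrahigh.

POLE takes precedence over CTNNB1 in OB/VBT (POLE mutants in those
subgroups have essentially no events); CTNNB1 takes precedence in EBRT,
where it is the dominant adverse factor. The table is data (YAML), is
validated for exhaustiveness over all 2×2×2 predicate cells, and every
assignment records a rule trace. Tiers map to treatments low → OB,
intermediate → VBT, high → EBRT, ultrahigh → EBRT + systemic therapy.
Cutoffs are inputs to the engine, never recomputed inside it, keeping
classification a pure function.

In the pipeline, each subgroup's cutoff is derived on a mutation-excluded
derivation set — OB without POLE or CTNNB1 mutants, VBT without POLE
mutants, EBRT without CTNNB1 mutants — and then applied to all members of
the subgroup; the excluded mutants receive their tier from the mutation
rules. A subgroup with fewer than `min_events_for_cutoff` (default 3)
horizon events is skipped with a warning.

## Survival analysis

Kaplan–Meier estimation, k-group log-rank tests and Cox
partial-likelihood fits (Efron tie handling) are delegated to lifelines.
The time-dependent ROC is the cumulative-case / dynamic-control estimator
with Kaplan–Meier censoring adjustment: cases at horizon *t* are events at
or before *t* (inclusive), controls are subjects event-free beyond *t*,
and for each observed threshold *c*

    sens(c) = (1 − S_c(t)) · P(M > c) / (1 − S(t))
    spec(c) = 1 − S_c(t) · P(M > c) / S(t)

where S is the all-sample and S_c the above-threshold Kaplan–Meier
survival. The KM variant was chosen over nearest-neighbour smoothing for
determinism (no span parameter). Under heavy censoring the raw estimates
need not be monotone; the curve is monotonized by a running maximum along
falling thresholds before the trapezoidal AUC, which leaves the
uncensored case — where the estimator reduces exactly to the empirical
ROC and the AUC to the Mann–Whitney statistic — untouched. Cutoffs
maximize the Youden index (sens + spec − 1), ties broken toward the
smallest threshold; the closest-to-(0,1) criterion was considered and
rejected as it optimizes a distance with no decision-theoretic weighting.

Cox fits check proportional hazards via the Schoenfeld-residual test with
log-time transform at α = 0.05; violating covariates are re-entered as
`x·log(t)` interactions (the common default functional form) after
splitting follow-up into counting-process episodes at the distinct event
times, which preserves risk sets exactly. Monotone-likelihood/separation
failures are flagged and refit with a small ridge penalty, with CIs
reported as unbounded. Fits require at least one more event than
covariates; below that the error advises a penalized or reduced model.
Analysis horizons default to 60 months (disease-free survival) and 120
months (overall survival).

## Meta-analysis

Per-study effects are Cohen's d with the pooled-SD denominator and
variance `(n1+n2)/(n1·n2) + d²/(2(n1+n2))`; Hedges'
`J = 1 − 3/(4(n1+n2) − 9)` is a switch, with Cohen's d the default (the
convention of the common fixed-effects forest-plot tooling). Pooling is
inverse-variance fixed effects with normal-theory 95% CIs (±1.96·SE);
Cochran's Q and I² are reported but no random-effects model is fitted, as
the analysis this package supports uses fixed effects only. The direction
convention puts the unfavourable arm second, so adverse factors yield
positive SMDs. SMDs are computed on the per-dataset Z scale, which is what
makes cross-platform pooling meaningful.

## Group comparisons

Two groups: Mann–Whitney U, exact for tie-free samples of ≤ 20 per arm,
otherwise the tie-corrected normal approximation. Three or more groups: a
Levene test (classic mean centring; median centring available) at α = 0.05
gates between one-way ANOVA with Tukey HSD and Welch-corrected ANOVA with
Games-Howell post hocs; the result records which path fired. Pearson
correlation, paired t and Pearson chi-square (no continuity correction)
complete the battery. No multiplicity correction is applied anywhere;
p values are two-sided with α = 0.05.

## Synthetic cohorts

The generator encodes the study conditions the analysis assumes. Each
patient draws grade (26/26/48%), histotype (85% EEC), stage IA/IB
(68/32%), age ~ N(64, 10) clipped to [30, 90], a molecular subtype
(POLE-mut 10%, MSI 34%, CNV-low 34%, CNV-high 22%) and mutation
indicators at marginal frequencies POLE 0.10, CTNNB1 0.24, PTEN 0.76,
PIK3CA 0.50, FGFR2 0.20, PPP2R1A 0.14 (the POLE flag is forced on for the
POLE-mut subtype). The latent CIN factor is the sum of covariate shifts
plus N(0, noise_sd = 0.6); default shifts (grade 2 +0.35, grade 3 +0.8,
non-EEC +0.6, IB +0.3, +0.08 per decade over 60, CNV-high +0.5, POLE
+0.8, CTNNB1 −0.6) reproduce the observed directions and produce
within-subgroup discrimination in the AUC 0.6–0.8 range; no published
effect sizes exist on this latent scale, so the magnitudes are this
package's calibration and are documented, not fitted to any test.
Signature genes (the shipped CIN70 list plus 30 pure-noise genes) express
`loading·z + N(0, 1)` with unit loadings, matching the equal-weight
averaging of the scoring step.

Event times are exponential with rate
`baseline·exp(β_cin·z + β_pole·POLE + β_ctnnb1·CTNNB1)` — DFS defaults
0.004/month, β = (0.8, −2.0, 0.9); OS defaults 0.002/month,
β = (0.7, −2.0, 1.0) — with independent exponential censoring at
0.012/month; observed time is the minimum. Exponential forms give
closed-form sanity checks and exact proportional hazards, so Cox recovery
tests have a well-defined truth. Time is in months; the 5-year DFS and
10-year OS horizons are 60 and 120. All randomness flows from a single
`numpy` Generator seeded by the config (default seed 20201022); identical
configs are bit-identical. Ground truth (per-patient latent CIN, the
generating log hazard ratios) is serialized alongside the data so recovery
tests never re-derive it.

What the generator does *not* emulate: genome-wide expression, platform
or batch effects, microarray noise, copy-number segments,
mutation–covariate correlations beyond those routed through the latent
factor, informative censoring, or competing risks. Passing tests
therefore demonstrate correctness of the estimators and rule engines
under the stated model, not performance on real cohorts.

Two-arm meta-study collections draw arm 1 ~ N(0, 1) and arm 2 ~
N(true SMD, 1); the default arm-size helper splits totals of 483 and 478
over nine studies, the scale of the grade meta-analysis.

## Problem sizes and numerical choices

Default test and acceptance problem sizes — 2000 null replicates for
test calibration, 200 replicates of n = 500 for Cox recovery, 100
replicates of n = 500 for the null AUC, ten 9-study collections for meta
recovery, and a single 2000-patient pipeline run — were chosen so the
Monte-Carlo error is small against each check's band while the whole
suite completes in about a minute. Oracle equivalences are asserted at
1e-9–1e-12; calibration bands at [0.03, 0.07] for size-0.05 tests. The
±0.07 meta-recovery band is approximately one pooled SE at the default
arm totals, so it is checked on the mean over the replicate collections
(each replicate additionally bounded at three pooled SEs), not on a
single draw. Survival times are floored at 1e-9 before Cox fitting;
thresholds for ROC curves are the observed unique scores.

## Known limitations

- The integrated rule table is a reconstruction: the branch for
  POLE-mutant EBRT patients and for CTNNB1-mutant/CIN-low OB patients is
  a documented design choice, configurable via YAML rather than
  hard-coded.
- The time-dependent ROC ships only the KM variant; nearest-neighbour
  smoothing is not implemented.
- No competing risks, frailty, interval censoring, or random-effects
  meta-analysis.
- Real-cohort numbers (subgroup sizes, printed AUCs and SMDs) depend on
  upstream portal exports and gene-mapping choices and are outside what
  the simulator can certify; the loader accepts such exports via a
  column-mapping block.
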