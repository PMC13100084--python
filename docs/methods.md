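# Methods

## Single-beat elastance (module `elastance`)

The effective arterial elastance is `Ea = 0.9·SAP/SV`, the end-systolic
pressure being approximated by 0.9 times the brachial systolic pressure; no
alternative Pes estimators are offered. End-systolic elastance uses the
single-beat method of Chen and colleagues: the normalised ventricular
elastance at ejection onset is

```
End(est) = 0.0275 − 0.165·EF + 0.3656·(DAP/Pes) + 0.515·End(avg)
End(avg) = Σ aᵢ·tNdⁱ  (i = 0..7),   tNd = PEP/TSP
```

with the group-averaged polynomial coefficients transcribed from the source
publication and kept in one constants block. EF enters as a fraction, PEP
and TSP in the same time unit. tNd outside [0.05, 0.60] — beyond where the
7th-order fit is trustworthy — is clipped with a warning, as is an End(est)
outside (0, 1). Then

```
Ees = [DAP − End(est)·Pes] / (End(est)·SV)        (mmHg/ml)
```

and `DAP ≤ End(est)·Pes` raises a "non-physiological elastance" error rather
than returning a negative slope.

**Numerical choice.** The coupling ratio is computed through the
cancellation identity `x/(DAP − x)` with `x = End(est)·Pes`. This is
algebraically `Ea/Ees` but independent of SV at the bit level, so the
SV-cancellation property holds exactly and the `ratio > 1` uncoupling flag
(strict inequality) cannot flip on a last-ulp difference introduced by the
stroke-volume quotient.

Stroke volume may be measured directly or derived as `π·(LVOT/2)²·VTI`; a
direct value wins, and a >20% disagreement between the two routes triggers
a warning. Aortic mechanics use the standard diameter-based conventions
(strain `(AoS−AoD)/AoD`, stiffness index `ln(SAP/DAP)/strain`,
distensibility `2·strain/PP` with 1 mmHg = 1333.22 dyn/cm²); a rigid aorta
returns zero strain and distensibility and an infinite stiffness index.

## Synthetic cohort (module `cohort`)

The generator emulates a pre-operative elective non-cardiac-surgery cohort.
Symmetric variables are normal (baseline MAP core 105 ± 13.5 mmHg);
variables summarised as median [IQR] are log-normal matched to those two
quantiles (age 57 [47–63] y, BMI 23 [21–25] kg/m², HR 75 [67–84] bpm,
propofol 2.0 [1.8–2.3] mg/kg, LVMI 81 [70–96] g/m², |GLS| 17.9 [16.4–19.3] %,
EDVi 55 [48–62] ml/m², ESVi 20.8 [18.7–24.0] ml/m², CI 2.7 [2.3–3.2]
l/min/m², SV median 65 ml); proportions are Bernoulli (female 57.5%, CCB
28.9%, hypertension 45.2%, COPD 1/405, ...). Pressures are built from a
normal MAP core and a truncated-normal pulse pressure so that
`MAP = (SAP + 2·DAP)/3` holds exactly. Covariates are otherwise independent
except two deliberate couplings: ASA class is a cumulative-logit ordinal
shifted by age (slope 0.5 per decade — this drifts the marginal III–IV share
from 16.3% to ≈19%, accepted as the price of the dependence), and the VAC
block is computed from the generated echo primitives by the same formulas
as `elastance`, so re-deriving it from a stored cohort reproduces it to
machine precision.

Two root-finding calibrations anchor the cohort:

1. the **PEP mean** (sd 12 ms, floor 25 ms) is solved so that
   `P(Ea/Ees > 1)` equals its target 42/405 ≈ 10.4% on a fixed 100,000-draw
   calibration sample — End(est) is monotone in tNd, so the prevalence is
   monotone in the PEP mean; the solution (~69 ms, tsp 390 ± 30 ms) also
   reproduces the published Ea ≈ 1.9 and Ees ≈ 2.4 mmHg/ml medians;
2. the **outcome intercept** is solved so the mean simulated PIH probability
   equals the target prevalence 161/405 = 39.8% given the configured
   log-odds effects (defaults: ASA III–IV ln 6.66, uncoupling ln 2.95, CCB
   ln 0.43, plus mild slopes of −0.02/mmHg MAP, ln 1.35 per age decade,
   −0.012 per g/m² LVMI on centred covariates).

All cohort draws come from one `numpy` Generator seeded by the spec;
calibration uses separate fixed internal seeds so the intercept depends only
on the parameters. GLS is made missing completely at random at 2% by
default to exercise the imputation rule.

**What the generator does not emulate:** covariate correlations beyond the
two above (real LVMI–MAP collinearity, age–comorbidity clustering),
measurement error in echo readings, the 14 further echo variables of the
source tables, informative missingness, and any post-induction dynamics.
Passing recovery tests therefore demonstrate the *statistical machinery* is
unbiased under the stated outcome model, not that the effect sizes would
replicate in new patients.

## Model stack (module `models`)

Clinical screening is an L1-penalised logistic path (saga, intercept
unpenalised) on standardised candidates, 10-fold stratified CV of out-of-fold
binomial deviance, penalty at the 1-SE rule. Selection is deterministic
given the seed.

The three nested models are binomial additive models (logit link):
categorical/binary terms parametric (reference = most frequent level),
continuous terms penalised cubic B-splines with basis dimension 10.
Smoothing parameters are selected per smooth by bounded coordinate descent
(two passes) minimising `AIC = −2·loglik + 2·edf`, the UBRE-type criterion
at fixed binomial scale; GCV-flavoured and marginal-likelihood criteria were
considered, but the installed GAM backend supports neither reliably, and the
AIC criterion is computed from quantities (hat-matrix trace, unpenalised
log-likelihood) the package controls directly. `edf` is the trace of the
penalised hat matrix; comparison degrees of freedom are edf differences and
are generally non-integer. With the penalty driven to infinity a smooth
collapses onto its linear null space, and the model provably reduces to
plain logistic regression (tested to <1e−3 in fitted probability).

LR χ² statistics use the unpenalised log-likelihood at the penalised fit,
against the intercept-only null. Partial effects return centred spline
contributions with pointwise ±1.96·SE bands from the penalised coefficient
covariance; categorical terms return their raw log-OR steps.

## Added value (module `added_value`)

* `FNI = 1 − LRχ²(reduced)/LRχ²(full)` — the adequacy complement. This
  definition makes adequacies multiply exactly along a nested chain
  (`1 − FNI_total = Π (1 − FNI_step)`), the identity asserted on every
  pipeline run; it jointly reproduces the published sequential values
  0.37 and 0.14 composing to 46%.
* Comparison p-values are upper-tail χ² probabilities at the (non-integer)
  edf difference.
* AUC is the Mann–Whitney estimator with midrank ties; DeLong's test uses
  placement-value covariances of the two paired score vectors, normal
  two-sided p, CI = Δ ± 1.96·SE. Identical score vectors return Δ = 0,
  p = 1 by convention; a zero variance with non-zero Δ is an error.
* Holm's step-down adjustment is applied once over the six-test family
  (three ΔAUC + three LR tests).
* Variable contributions: drop-one refit per term of the full model; the
  loss in LR χ² is normalised to sum to 100%. Point-estimate refits
  re-select their smoothing parameters; the B patient-level bootstrap
  resamples (default 2000 in the API, 200 in the default pipeline
  configuration to keep a single-CPU run in minutes) reuse the point
  estimate's smoothing parameters — treating the smoothing level as part of
  the estimator rather than re-optimised noise — and CIs are the 2.5/97.5
  percentiles of the renormalised shares. Resampling is simple (no
  stratification); resamples that lose an outcome class are redrawn.

## Design sample sizes (module `power`)

`n_for_proportion` is the closed-form precision bound
`⌈z²·p(1−p)/d²⌉` (383 at p = 0.53, d = 0.05, 95% confidence) with a
representation-robust ceiling; attrition inflates multiplicatively
(`⌈n·1.05⌉ = 403` — the alternative `n/0.95` convention gives 404 and is not
used). The AUC design uses the Hanley–McNeil variance under null (0.5) and
alternative with a 2:1 negative:positive ratio; at AUC 0.70, two-sided
α = 0.05, power 0.90 it requires 96 participants (64/32). The study this
replicates reports 93 (62/31) from an unnamed tool; the one-sided variant is
exposed but the discrepancy is documented rather than reverse-engineered.

## Descriptive comparisons (module `descriptives`)

Continuous variables are gated by Shapiro–Wilk at α = 0.05 **in both
groups** (Welch's t-test and mean ± SD if both pass, otherwise Wilcoxon
rank-sum and median [IQR]). Categorical variables use Pearson χ² *without*
continuity correction — the only convention consistent with the published
2×2 uncoupling p = 0.036 (Yates would give 0.053) — switching to Fisher's
exact test when any expected cell is < 5; r×c tables beyond 2×2 use a
seeded 20,000-permutation Monte-Carlo conditional test. Hygiene rules:
GLS is median-imputed only when < 5% is missing (error otherwise), and
binary covariates with fewer than five positive observations in either
outcome group are excluded from regression with a logged count.

## Pipeline (module `pipeline`, CLI `vac`)

`run_study` chains cohort → descriptives → hygiene → LASSO (baseline MAP is
always kept in the clinical block) → M0/Mecho/Mfull → comparisons → Holm →
contributions, asserting the FNI-composition and deviance-additivity
identities on every run. The default configuration is study-scale
(n = 405, bootstrap B = 200) with five echo smooths (LVMI, GLS, EDVi, ESVi,
CI) and the VAC block (Ea, Ees smooths + uncoupling flag); report CSVs
mirror journal rounding (AUC 3 dp, FNI 2 dp, p 3 dp) while `report.json`
keeps full precision and is byte-identical across reruns of one
configuration. Timings and the config hash go to a separate `run_log.json`.
Any stage failure raises a stage-tagged error and removes partial outputs.

## Known limitations

Smoothing-parameter selection is AIC-based and shared-backend-dependent;
edf differences can make an added block look slightly cheaper or dearer than
integer-df intuition suggests. The bootstrap holds smoothing fixed (see
above), so contribution CIs omit smoothing-selection variability. The
generator's independence structure understates real-world collinearity
(notably MAP–LVMI), so apparent AUCs on synthetic cohorts tend to run higher
than the published ones. In-sample (apparent) AUCs are used for the DeLong
comparisons, as in the replicated analysis; no optimism correction is
applied.
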