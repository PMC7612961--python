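# Methods

## Kinetic model

Regional binding is quantified with the simplified reference tissue model
(SRTM). For a target region with time–activity curve `C_T(t)` and a reference
region (cerebellar cortical gray matter in the original design) `C_ref(t)`:

    C_T(t) = R1 · C_ref(t) + (k2 − R1·k2a) · (C_ref ⊛ exp(−k2a t)),

where `R1` is the delivery ratio, `k2` (1/min) the reference efflux rate,
`k2a = k2/(1 + BP_ND)` the apparent target washout rate, and
`BP_ND = k2/k2a − 1` the nondisplaceable binding potential.

The basis-function fit grids `k2a` logarithmically — default
`[0.006, 0.6] min⁻¹`, 100 points, spanning physiological washout for
flortaucipir-class tracers — precomputes one convolution basis per grid
point, solves the two-parameter linear least-squares subproblem at each, and
keeps the minimum-RSS grid point. Ties resolve to the lowest grid index
(harmless: in the tied identity case every grid point maps to the same
`BP_ND`). Negative `θ2` (BP_ND < 0) is allowed, matching real tracer
behaviour; `BP_ND ≤ −1` is a failed fit.

Numerics: the convolution uses an exponential-kernel trapezoidal recursion on
a fine internal grid (0.05 min) augmented with the frame midpoints, and the
model is read off *at the frame midpoints*. Evaluating simulator and fitter
at the same points makes the identity limit (`R1 = 1, BP_ND = 0`) exact to
machine precision and keeps forward/inverse consistency independent of frame
widths. Against an independent 0.01-min quadrature oracle the forward curves
agree to well under 0.5% per frame.

Partial-volume correction divides each regional PET value by the mean
regional GM+WM tissue fraction (frame-constant), before kinetic modelling;
left/right `BP_ND` are averaged bilaterally, with a logged single-side
fallback when one hemisphere is missing.

## w-scores

Per region, an OLS normative model is fitted on controls with age and a
single PET/MRI-vs-rest scanner indicator (the two covariates named for this
design; others can be supplied but are off by default). The w-score is the
subject's residual divided by the control residual SD. The residual SD uses
denominator `n − p` (switchable to `n − 1`); with `n − p` the control
w-scores have mean exactly 0 and sample SD `√((n−p)/(n−1)) ≈ 0.97` at
`n = 39`. If only one scanner class is present the indicator is dropped with
a warning. A residual SD indistinguishable from zero is rejected as a
degenerate normative model.

## Abnormality thresholds

The data-driven rule reproduces the first split of a conditional-inference
tree with diagnosis as the binary response and the region's w-score as the
sole predictor. Candidate cuts are midpoints between consecutive sorted
unique w-scores; each is scored by the 2×2 chi-square (group × side); global
significance comes from permuting diagnosis labels (default 9999
permutations, add-one p estimator) and comparing the observed maximal
statistic against the permutation distribution of maxima (max-T correction).
Only the first split is kept — one cut per region; ties in the statistic take
the smallest midpoint; the permutation seed is part of the configuration.

If no split reaches `α = 0.05`, the region falls back to `w = 1.645`, the
one-sided standard-normal critical value at P = 0.05 (in the original
analysis this happened for the occipital lobe). A *non-positive* significant
cut is also treated as "not identified": abnormality here means elevated
binding, and the strict severity rule `w > 2τ` requires `τ > 0`. The SD-based
alternative places the cut at `k` control SDs; on the w-score scale that is
exactly `τ = k` (default `k = 2`, configurable — the original multiplier is
not printed in the text and is flagged unverified).

## Staging automaton

Four composites: GP (globus pallidus), CER (cerebellar white matter +
dentate nucleus), FR (middle frontal gyrus), OCC (lingual gyrus + cuneus);
striatum and subthalamic nucleus are excluded (off-target binding).
Composites aggregate subregion severities by maximum; the occipital pair can
alternatively be combined as a mean w-score against a single cut
(`occ_combined`), switchable because the granularity of the original
occipital rule is ambiguous.

Severity per region: `0` if `w ≤ τ`, `1` if `τ < w ≤ 2τ`, `2` if `w > 2τ`
(boundaries inclusive on the lower severity). Step 1 maps presence
(severity > 0) cumulatively: none → no stage; GP only → I/II; GP +
(FR or CER), OCC absent → III/IV; GP + OCC + (FR or CER) → V/VI; GP absent
with anything else present → unclassifiable. OCC-positive without FR/CER
violates the cumulative sequence; such subjects are staged at V/VI and
flagged *atypical* rather than rejected (the original cohort staged 41/42
while reporting 4 atypical patterns). Step 2 splits each pair on the
relevant severity (GP for I/II, max(FR, CER) for III/IV, OCC for V/VI).

Numeric coding for correlation analyses: no stage = 0, I–VI = 1–6;
step-1-only results use pair midpoints (1.5/3.5/5.5); unclassifiable is
excluded. A subject with missing regional values is staged only when every
completion of the missing severities yields the same outcome; otherwise
flagged `unclassifiable_missing`, distinct from the sequence-violating
`unclassifiable`.

All 3⁴ = 81 severity vectors map to exactly one outcome; the numeric stage is
non-decreasing in every severity coordinate, step 2 refines step 1, and
raising any `τ` can only lower stages — verified by exhaustive enumeration in
the test suite.

## Validation statistics

PSPRS-by-stage one-way fixed-effects ANOVA (groups below 2 members dropped).
Spearman rank agreement between the numeric in vivo and postmortem stages
uses midranks; the p-value is an exact tie-aware permutation enumeration for
n ≤ 9 (the donation-subset size) and asymptotic otherwise. The residualised
correlation regresses each ordinal staging variable by OLS on PSPRS and the
PET-to-death interval and correlates the residual vectors — linear OLS on
ordinal codes mirrors the original description verbatim; fidelity was chosen
over statistical optimality. `proportion_le` is the fraction of complete
autopsy pairs with in vivo ≤ postmortem stage.

## Synthetic cohorts

The generator emulates the study conditions: 39 controls (age 65.8 ± 8.2 y)
and 42 patients (age 70.3 ± 7.0 y; PSPRS 36.6 ± 14.2; scanner mix matching
the reported PET/MRI / PET/CT / PET counts), true stages drawn from the
observed substage mix (2, 8, 9, 17, 5 over I–V, plus a small stage-VI mass),
and a 9/42 donation subset with PET-to-death interval N(2.45, 0.98²) floored
at 0.1 y. Regional `BP_ND` is control baseline + cumulative stage elevation
+ age slope (0.002/y) + PET/MRI offset (0.05) + Gaussian noise; stored
left/right values are diluted by the per-region GM+WM fraction so the
pipeline's partial-volume correction is exercised on the way back. Postmortem
stage is the true stage plus a Poisson progression increment with mean
0.5/year × interval, capped at VI — encoding "in vivo ≤ postmortem" as the
construction. PSPRS is independent of stage by default (the original null
finding), with an optional coupling coefficient for power checks.

The patient-cohort regional distributions are free parameters, not estimates
of the original data (which are not deposited): baselines 0.12–0.25 with SD
0.10, elevations 0.30 (mild) and 0.60 (severe) — i.e. 3 and 6 control SDs,
centred in the SD-rule severity bands. What passing tests show is therefore
that the *pipeline logic* behaves as specified under its own assumptions;
they say nothing about flortaucipir's empirical sensitivity, off-target
binding, or inter-regional correlation of real data (regional noise is
independent by default; a shared subject-level random effect is switchable).

The parameter-recovery experiment (`experiments.recovery_cohort_config`)
uses patient noise 0.02 (≈ 0.2 w-score SDs) and 200 controls: the large
control sample keeps sampling error of the normative residual SD — a factor
separate from the staging logic under test — from smearing the severity
bands. Under these conditions step-2 staging recovers the generating stage
for ≥ 98% of patients across seeds. With default (realistic) noise, recovery
drops to roughly half — stage bands one noise-SD wide cannot be read off
reliably, which is itself a faithful property of this design.

## Problem sizes

Test-suite and acceptance runs use the study's own cohort sizes (39 + 42),
100 replicates for the split-search null level, and 1000 end-to-end
replicates for the ANOVA level; the full suite runs in well under a minute
on one CPU.

## Known limitations

- No voxelwise simulation, atlas geometry, scanner physics, or image-level
  partial-volume effects; region-level values are the unit of analysis.
- The threshold search implements exactly one split per region; no deeper
  tree growth, multiway splits, or surrogate splits.
- OLS on ordinal stage codes (residualised correlation) is a deliberate
  fidelity choice, not a recommendation.
- The SD-rule multiplier default (k = 2) is unverified against the original
  supplementary analysis.
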