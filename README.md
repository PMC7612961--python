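# pspstage

In vivo staging of progressive supranuclear palsy (PSP) tau pathology from
regional flortaucipir PET, built as a tested, reusable pipeline and exercised
end to end on synthetic cohorts.

PSP is a 4-repeat tauopathy whose postmortem pathology follows a stereotyped
cumulative sequence — globus pallidus first, then frontal cortex and
cerebellum, finally the occipital lobe — codified as a six-stage scheme
(Kovacs staging). This package implements the analytic pipeline that attempts
to reproduce that staging in vivo from PET:

1. **Kinetics** — regional nondisplaceable binding potential
   `BP_ND = k2/k2a − 1` from dynamic time–activity curves via a basis-function
   implementation of the simplified reference tissue model
   `C_T(t) = R1·C_ref(t) + (k2 − R1·k2a)·(C_ref ⊛ e^{−k2a t})`,
   with CSF partial-volume correction (division by the regional GM+WM tissue
   fraction) and bilateral averaging.
2. **w-scores** — covariate-adjusted z-scores against a control cohort:
   `w = (BP_ND − (β0 + β_age·age + β_scan·[PET/MRI])) / s_resid`, with the
   normative OLS fitted on controls.
3. **Thresholds** — per-region abnormality cuts `τ_r` found as the first split
   of a conditional-inference-style search (chi-square over all candidate
   midpoints, max-T permutation test); regions without a significant split
   fall back to `w = 1.645` (one-sided normal critical value, P = 0.05); an
   SD-rule alternative (`τ = k` control SDs) is also provided.
4. **Staging** — a two-step automaton: step 1 maps the binary presence
   pattern across GP, cerebellum (white matter + dentate), middle frontal
   gyrus and occipital lobe (lingual + cuneus) to stage pairs I/II, III/IV,
   V/VI (unclassifiable if the pallidal anchor is missing); step 2 refines
   within the pair using the 3-level severity scale (`w > τ`: mild/moderate,
   `w > 2τ`: moderate/severe).
5. **Validation** — ANOVA of clinical severity (PSPRS) across stages,
   Spearman agreement between in vivo and postmortem stage, the same
   correlation after residualising both on PSPRS and the PET-to-death
   interval, and the fraction of autopsy cases with in vivo ≤ postmortem.

A seeded synthetic-data module generates cohorts with the statistical
structure this analysis assumes (cumulative regional elevation, age and
scanner effects, a brain-donation subset), so every stage is testable without
patient data.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (seed 1):

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_fit_kinetics.py
python analysis/03_wscores_thresholds.py 1
python analysis/04_stage_cohort.py
python analysis/05_validate_staging.py
```

which prints (abridged):

```
cohort: 81 subjects (42 patients)
donation subset: 9 patients, interval 2.59 +/- 0.86 y
gp         BP_ND = 0.598  (R1 = 0.995, k2a = 0.0643/min)
gp         tau = 2.241  [data_driven]  (max-T permutation p = 0.0001)
occ_ling   tau = 1.645  [fallback]
patients step 1: {'III/IV': 29, 'V/VI': 10, 'I/II': 3}
patients step 2: {'IV': 23, 'V': 6, 'III': 6, 'VI': 4, 'I': 2, 'II': 1}
controls step 1: {'no_stage': 34, 'unclassifiable': 5}
ANOVA of PSPRS across step-2 stages: F = 0.50, p = 0.738
in vivo vs postmortem stage (n = 9): Spearman r = 0.399 (exact p = 0.33)
in vivo <= postmortem in 89% of autopsy cases
```

Reading: the SRTM fit recovers the generating `BP_ND = 0.6` for the pallidal
TAC; the split search finds data-driven thresholds for the pallidal,
cerebellar and frontal regions but not the occipital subregions, which fall
back to 1.645; most patients land in stage III/IV; severity is unrelated to
stage (PSPRS is generated independently of stage by default — the null world);
and in vivo stage is ≤ the postmortem stage in 8 of 9 donors, with weak rank
agreement.

The same steps are available as a CLI (`pspstage simulate | fit-kinetics |
wscore | thresholds | stage | validate | run`), with `run` driven by a YAML
config.

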