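"""Simulation experiments over the staging pipeline.

These drivers define the study conditions under which the pipeline's
operating characteristics are measured: parameter recovery of true stages,
type-I behaviour of the threshold finder under the null, and the level of
the severity ANOVA when clinical scores are generated independently of stage
(the null world matching the study's negative finding).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import regions as R
from .staging import stage_cohort
from .synthetic import CohortConfig, generate_cohort
from .thresholds import sd_threshold, split_search
from .validate import anova_by_stage
from .wscores import fit_wscore_model, wscore_table

__all__ = [
    "recovery_cohort_config",
    "stage_synthetic_cohort",
    "staging_recovery_rate",
    "null_threshold_detection_rate",
    "null_anova_rejection_rate",
]


def recovery_cohort_config(seed: int, n_controls: int = 200, n_patients: int = 100) -> CohortConfig:
    """Large-effect, low-noise generator settings for parameter recovery.

    Regional elevations sit at 3 (mild) and 6 (severe) control SDs, centred in
    the SD-rule severity bands (tau = 2, 2*tau = 4 on the w-score scale);
    patient-specific noise is 0.02 BP_ND so w-score noise is ~0.2 SD.  The
    control sample is large (200) so that sampling error in the normative
    model's residual SD — a separate factor from the staging logic under
    test — does not smear the severity bands.
    """
    return CohortConfig(
        n_controls=n_controls,
        n_patients=n_patients,
        patient_noise_sd={sub: 0.02 for sub in R.SUBREGIONS},
        lateral_sd=0.005,
        seed=seed,
    )


def stage_synthetic_cohort(
    config: CohortConfig, k_sd: float = 2.0, ddof_mode: str = "n-p"
) -> pd.DataFrame:
    """Generate, w-score (models fit on the cohort's own controls), and stage
    a synthetic cohort with SD-based thresholds; returns the staging table
    joined with the generating truth."""
    df = generate_cohort(config)
    # generator stores CSF-diluted left/right values; undo and average
    for sub in R.SUBREGIONS:
        left = df[R.bpnd_left_col(sub)] / df[R.gmwm_col(sub)]
        right = df[R.bpnd_right_col(sub)] / df[R.gmwm_col(sub)]
        df[R.bpnd_col(sub)] = 0.5 * (left + right)
    models = {sub: fit_wscore_model(df, sub, ddof_mode=ddof_mode) for sub in R.SUBREGIONS}
    wtable = wscore_table(df, models)
    thresholds = {sub: sd_threshold(sub, k_sd) for sub in R.SUBREGIONS}
    staged = stage_cohort(wtable, thresholds)
    return staged.merge(
        df[["subject_id", "psprs", "true_stage", "postmortem_stage", "interval_y"]],
        on="subject_id",
        how="left",
    )


def staging_recovery_rate(seed: int, n_patients: int = 100) -> float:
    """Fraction of patients whose step-2 stage equals the generating stage."""
    staged = stage_synthetic_cohort(recovery_cohort_config(seed, n_patients=n_patients))
    pat = staged[staged["group"] == "patient"]
    return float((pat["numeric_stage"] == pat["true_stage"]).mean())


def null_threshold_detection_rate(
    n_reps: int = 100,
    n_per_group: int = 40,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Fraction of null replicates (both groups N(0,1)) where the permutation
    split search declares a significant threshold; should track alpha."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([False, True], n_per_group)
    hits = 0
    for _ in range(n_reps):
        w = rng.standard_normal(2 * n_per_group)
        res = split_search(w, labels, n_perm=n_perm, seed=rng)
        hits += res.p_value < alpha
    return hits / n_reps


def null_anova_rejection_rate(
    n_reps: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Level of the PSPRS-by-stage ANOVA when severity is generated
    independently of stage (stage-severity coupling 0), staged end to end
    with SD-based thresholds."""
    rng = np.random.default_rng(seed)
    rejections = 0
    valid = 0
    for _ in range(n_reps):
        cfg = CohortConfig(seed=int(rng.integers(2**31 - 1)), psprs_stage_coupling=0.0)
        staged = stage_synthetic_cohort(cfg)
        pat = staged[
            (staged["group"] == "patient")
            & ~staged["step2"].isin(["unclassifiable", "unclassifiable_missing"])
        ]
        try:
            _, p, _ = anova_by_stage(pat["psprs"], pat["step2"])
        except ValueError:
            continue
        valid += 1
        rejections += p < alpha
    if valid == 0:
        raise RuntimeError("no valid ANOVA replicates")
    return rejections / valid
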