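"""Seeded synthetic cohorts and dynamic TACs for the PSP staging pipeline.

The generator emulates the study design the analysis assumes: a healthy
control cohort and a PSP patient cohort with regional flortaucipir BP_ND that
elevates cumulatively along the pallidal -> frontal/cerebellar -> occipital
sequence, additive age and scanner (PET/MRI vs non-PET/MRI) effects, clinical
severity scores, and a brain-donation subset whose postmortem stage is at
least the true stage at scan.

Stored left/right BP_ND values are deliberately diluted by the regional
gray+white-matter tissue fraction, so the pipeline's partial-volume correction
(division by that fraction) recovers the tissue-level signal.

All randomness flows through one ``numpy.random.default_rng(seed)``; identical
configs produce byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regions as R
from .tac import SRTMParams, TimeActivityCurve, default_reference_curve, srtm_forward

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "simulate_tac",
    "default_reference_curve",
    "SRTMParams",
    "TimeActivityCurve",
]

# Scanner mix observed in the study cohorts (PET/MRI, PET/CT, PET).
_CONTROL_SCANNER_COUNTS = {"petmr": 24, "petct": 7, "pet": 8}
_PATIENT_SCANNER_COUNTS = {"petmr": 22, "petct": 13, "pet": 7}

_DEFAULT_MEANS = {
    "gp": 0.25, "cer_wm": 0.20, "cer_dn": 0.22,
    "fr": 0.15, "occ_ling": 0.12, "occ_cun": 0.12,
}
_DEFAULT_SDS = {sub: 0.10 for sub in R.SUBREGIONS}
# (mild, severe) elevations in BP_ND units: ~3 and ~6 control SDs, so that on
# the w-score scale mild sits between 2 and 4 SDs and severe above 4, matching
# the SD-based severity rule with k = 2.
_DEFAULT_EFFECTS = {sub: (0.30, 0.60) for sub in R.SUBREGIONS}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the study's cohort descriptives."""

    n_controls: int = 39
    n_patients: int = 42
    #: probability of true stages I..VI; default proportional to the observed
    #: substage mix (2, 8, 9, 17, 5) plus a small stage-VI mass
    stage_distribution: tuple[float, ...] = (2 / 42, 8 / 42, 9 / 42, 17 / 42, 5 / 42, 1 / 42)
    control_region_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    control_region_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    #: per-region (mild, severe) additive BP_ND elevation
    stage_effect_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    #: patient-specific regional noise SD; None -> same as control spread
    patient_noise_sd: dict | None = None
    lateral_sd: float = 0.02  # left/right asymmetry noise, BP_ND units
    subject_effect_sd: float = 0.0  # optional shared subject-level random effect
    age_slope: float = 0.002  # BP_ND per year
    scanner_offset: float = 0.05  # BP_ND, PET/MRI vs non-PET/MRI
    control_age_mean: float = 65.8
    control_age_sd: float = 8.2
    patient_age_mean: float = 70.3
    patient_age_sd: float = 7.0
    psprs_mean: float = 36.6
    psprs_sd: float = 14.2
    #: PSPRS points per true-stage unit; 0 reproduces the study's null world
    psprs_stage_coupling: float = 0.0
    donation_fraction: float = 9 / 42
    interval_mean_y: float = 2.45
    interval_sd_y: float = 0.98
    #: expected postmortem stage increments per year of PET-to-death interval
    progression_rate_per_y: float = 0.5
    gmwm_mean: float = 0.85
    gmwm_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        dist = np.asarray(self.stage_distribution, dtype=float)
        if dist.size != 6 or np.any(dist < 0) or not np.isfinite(dist).all():
            raise ValueError("stage_distribution must be 6 nonnegative finite entries")
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("stage_distribution must sum to 1 within 1e-9")
        for name in ("control_age_sd", "patient_age_sd", "psprs_sd", "interval_sd_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.donation_fraction <= 1:
            raise ValueError("donation_fraction must lie in [0, 1]")
        for sub in R.SUBREGIONS:
            if not np.isfinite(self.control_region_means[sub]):
                raise ValueError(f"non-finite control mean for {sub}")
            if not self.control_region_sds[sub] > 0:
                raise ValueError(f"control SD for {sub} must be positive")
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be nonnegative")

    def noise_sd(self, sub: str, patient: bool) -> float:
        if patient and self.patient_noise_sd is not None:
            return float(self.patient_noise_sd[sub])
        return float(self.control_region_sds[sub])


def _scanner_labels(n: int, counts: dict[str, int], rng: np.random.Generator) -> np.ndarray:
    """Scanner labels with marginals proportional to the study mix, shuffled."""
    total = sum(counts.values())
    labels: list[str] = []
    for name, c in counts.items():
        labels.extend([name] * int(round(c / total * n)))
    while len(labels) < n:
        labels.append("petmr")
    labels = labels[:n]
    arr = np.array(labels)
    rng.shuffle(arr)
    return arr


def _regional_block(
    cfg: CohortConfig,
    rng: np.random.Generator,
    stages: np.ndarray,
    ages: np.ndarray,
    scanners: np.ndarray,
    patient: bool,
) -> dict[str, np.ndarray]:
    """Left/right stored BP_ND and GM+WM fraction columns for one group."""
    n = stages.size
    cols: dict[str, np.ndarray] = {}
    subject_eff = rng.normal(0.0, cfg.subject_effect_sd, n) if cfg.subject_effect_sd > 0 else np.zeros(n)
    is_petmr = (scanners == "petmr").astype(float)
    for sub in R.SUBREGIONS:
        comp = R.SUBREGION_TO_COMPOSITE[sub]
        sev = np.array([R.true_severity(comp, int(s)) for s in stages])
        mild, severe = cfg.stage_effect_sizes[sub]
        elevation = np.where(sev == 1, mild, np.where(sev == 2, severe, 0.0))
        tissue = (
            cfg.control_region_means[sub]
            + cfg.age_slope * (ages - cfg.control_age_mean)
            + cfg.scanner_offset * is_petmr
            + subject_eff
            + elevation
            + rng.normal(0.0, cfg.noise_sd(sub, patient), n)
        )
        left = tissue + rng.normal(0.0, cfg.lateral_sd, n)
        right = tissue + rng.normal(0.0, cfg.lateral_sd, n)
        gmwm = np.clip(rng.normal(cfg.gmwm_mean, cfg.gmwm_sd, n), 0.5, 1.0)
        # stored values are CSF-diluted; pvc_correct undoes the division
        cols[R.bpnd_left_col(sub)] = left * gmwm
        cols[R.bpnd_right_col(sub)] = right * gmwm
        cols[R.gmwm_col(sub)] = gmwm
    return cols


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one tidy cohort table, one row per subject.

    Controls carry true stage 0 ("none"); each patient's regional BP_ND is the
    control baseline plus the cumulative stage elevation plus covariate terms
    and noise.  A ``donation_fraction`` subset of patients receives a
    postmortem stage >= the true stage at scan (nonnegative Poisson
    progression, capped at VI) and a PET-to-death interval drawn from the
    configured normal, floored at 0.1 years.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_controls == 0:
        warnings.warn("cohort generated with no controls; w-score fitting will reject it")

    frames = []
    # controls
    n_c = config.n_controls
    ages_c = rng.normal(config.control_age_mean, config.control_age_sd, n_c)
    scan_c = _scanner_labels(n_c, _CONTROL_SCANNER_COUNTS, rng)
    stages_c = np.zeros(n_c, dtype=int)
    block_c = _regional_block(config, rng, stages_c, ages_c, scan_c, patient=False)
    df_c = pd.DataFrame(
        {
            "subject_id": [f"c{i + 1:03d}" for i in range(n_c)],
            "group": "control",
            "phenotype": "control",
            "age_y": ages_c,
            "scanner": scan_c,
            "psprs": np.nan,
            "true_stage": stages_c,
            **block_c,
        }
    )
    frames.append(df_c)

    # patients
    n_p = config.n_patients
    stages_p = rng.choice(np.arange(1, 7), size=n_p, p=np.asarray(config.stage_distribution))
    ages_p = rng.normal(config.patient_age_mean, config.patient_age_sd, n_p)
    scan_p = _scanner_labels(n_p, _PATIENT_SCANNER_COUNTS, rng)
    mean_stage = float(np.arange(1, 7) @ np.asarray(config.stage_distribution))
    psprs = np.clip(
        rng.normal(config.psprs_mean, config.psprs_sd, n_p)
        + config.psprs_stage_coupling * (stages_p - mean_stage),
        0.0,
        100.0,
    )
    block_p = _regional_block(config, rng, stages_p, ages_p, scan_p, patient=True)
    df_p = pd.DataFrame(
        {
            "subject_id": [f"p{i + 1:03d}" for i in range(n_p)],
            "group": "patient",
            "phenotype": "PSP-RS",
            "age_y": ages_p,
            "scanner": scan_p,
            "psprs": psprs,
            "true_stage": stages_p,
            **block_p,
        }
    )
    # postmortem subset: in vivo true stage <= postmortem stage by construction
    n_donate = int(round(config.donation_fraction * n_p))
    pm_stage = np.full(n_p, np.nan)
    interval = np.full(n_p, np.nan)
    if n_donate > 0:
        donors = rng.choice(n_p, size=n_donate, replace=False)
        iv = np.maximum(rng.normal(config.interval_mean_y, config.interval_sd_y, n_donate), 0.1)
        inc = rng.poisson(config.progression_rate_per_y * iv)
        pm_stage[donors] = np.minimum(stages_p[donors] + inc, 6)
        interval[donors] = iv
    df_p["postmortem_stage"] = pm_stage
    df_p["interval_y"] = interval
    df_c["postmortem_stage"] = np.nan
    df_c["interval_y"] = np.nan
    frames.append(df_p)

    out = pd.concat(frames, ignore_index=True)
    return out


def simulate_tac(
    params: SRTMParams,
    reference: TimeActivityCurve,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    dt: float = 0.05,
    region_label: str = "target",
) -> TimeActivityCurve:
    """Forward-simulate a target TAC from the SRTM given a reference TAC.

    Noise-free output is the SRTM model evaluated at the frame midpoints;
    ``noise_sd`` adds i.i.d. Gaussian noise per frame.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    activity = srtm_forward(params, reference, dt=dt)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        activity = activity + rng.normal(0.0, noise_sd, activity.size)
    return reference.with_activity(activity, region_label=region_label)
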