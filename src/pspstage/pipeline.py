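"""End-to-end staging pipeline: BP_ND table -> w-scores -> thresholds ->
stages -> validation report, with all intermediate artifacts written out."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from . import regions as R
from .staging import stage_cohort
from .thresholds import derive_thresholds
from .validate import (
    AgreementReport,
    anova_by_stage,
    proportion_le,
    residualized_correlation,
    spearman_agreement,
)
from .wscores import fit_wscore_model, wscore_table

__all__ = ["PipelineConfig", "preprocess_bpnd", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    cohort_csv: str = ""
    outdir: str = "results/pipeline"
    regions: tuple[str, ...] = R.SUBREGIONS
    threshold_method: str = "data_driven"  # data_driven | sd_based
    alpha: float = 0.05
    n_perm: int = 9999
    k_sd: float = 2.0
    seed: int = 0
    occ_combined: bool = False
    min_controls: int = 10
    ddof_mode: str = "n-p"

    def validate(self) -> None:
        if self.threshold_method not in ("data_driven", "sd_based"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        for comp, subs in R.COMPOSITES.items():
            if not any(s in self.regions for s in subs):
                raise ValueError(f"region specification is missing the {comp} composite")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = io.load_yaml(path) or {}
        cfg = cls(**raw)
        if isinstance(cfg.regions, list):
            cfg.regions = tuple(cfg.regions)
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preprocess_bpnd(df: pd.DataFrame, regions=R.SUBREGIONS) -> pd.DataFrame:
    """Partial-volume-correct and bilaterally average wide left/right columns.

    Tables already carrying a bilateral ``{region}_bpnd`` column pass through
    unchanged for that region.
    """
    out = df.copy()
    for sub in regions:
        if R.bpnd_col(sub) in out.columns:
            continue
        lcol, rcol, gcol = R.bpnd_left_col(sub), R.bpnd_right_col(sub), R.gmwm_col(sub)
        if lcol not in out.columns or rcol not in out.columns:
            raise ValueError(f"no bilateral or left/right BP_ND columns for region {sub!r}")
        left = out[lcol].to_numpy(dtype=float)
        right = out[rcol].to_numpy(dtype=float)
        if gcol in out.columns:
            frac = out[gcol].to_numpy(dtype=float)
            if np.any(frac <= 0) or np.any(frac > 1):
                raise ValueError(f"gm+wm fraction out of (0, 1] for region {sub!r}")
            left = left / frac
            right = right / frac
        both = np.nanmean(np.column_stack([left, right]), axis=1)
        if np.isnan(both).any():
            warnings.warn(f"region {sub!r}: missing values on both sides for some subjects")
        out[R.bpnd_col(sub)] = both
    return out


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Execute w-scores -> thresholds -> staging -> validation.

    Returns a dict of in-memory artifacts; everything is also written under
    ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = io.read_cohort(config.cohort_csv)

    df = preprocess_bpnd(cohort, config.regions)
    controls = df[df["group"] == "control"]
    if len(controls) < config.min_controls:
        raise ValueError(f"wscores: need >= {config.min_controls} controls, got {len(controls)}")

    models = {
        sub: fit_wscore_model(df, sub, min_controls=config.min_controls, ddof_mode=config.ddof_mode)
        for sub in config.regions
    }
    wtable = wscore_table(df, models)

    thresholds = derive_thresholds(
        wtable,
        method=config.threshold_method,
        regions=config.regions,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=config.seed,
        k_sd=config.k_sd,
    )
    staged = stage_cohort(wtable, thresholds, occ_combined=config.occ_combined)
    staged = staged.merge(
        df[["subject_id", "psprs", "true_stage", "postmortem_stage", "interval_y"]]
        if {"true_stage", "postmortem_stage", "interval_y"} <= set(df.columns)
        else df[["subject_id", "psprs"]],
        on="subject_id",
        how="left",
    )

    report = _validation_report(staged)

    io.write_cohort(wtable, outdir / "wscores.csv")
    io.write_wscore_models(models, outdir / "wscore_models.json")
    from .thresholds import thresholds_to_json

    thresholds_to_json(thresholds, outdir / "thresholds.json")
    io.write_cohort(staged, outdir / "staging.csv")
    io.write_json(report.to_dict() if report is not None else {}, outdir / "report.json")
    io.write_json(
        {"config": asdict(config), "config_sha256": config.digest(), "seed": config.seed},
        outdir / "provenance.json",
    )
    return {
        "wscores": wtable,
        "models": models,
        "thresholds": thresholds,
        "staging": staged,
        "report": report,
    }


def _validation_report(staged: pd.DataFrame) -> AgreementReport | None:
    """Severity ANOVA over patients plus postmortem agreement when available."""
    patients = staged[staged["group"] == "patient"]
    anova_F = anova_p = float("nan")
    means: dict = {}
    try:
        classifiable = patients[~patients["step2"].isin(["unclassifiable", "unclassifiable_missing"])]
        anova_F, anova_p, means = anova_by_stage(classifiable["psprs"], classifiable["step2"])
    except (ValueError, KeyError):
        pass

    sp_r = sp_p = res_r = res_p = prop = float("nan")
    n_pairs = 0
    if "postmortem_stage" in patients.columns:
        donors = patients[np.isfinite(patients["postmortem_stage"].astype(float))]
        n_pairs = int(np.isfinite(donors["numeric_stage"].astype(float)).sum())
        try:
            sp_r, sp_p = spearman_agreement(donors["numeric_stage"], donors["postmortem_stage"])
        except ValueError:
            pass
        try:
            res_r, res_p = residualized_correlation(
                donors["numeric_stage"], donors["postmortem_stage"],
                donors["psprs"], donors["interval_y"],
            )
        except ValueError:
            pass
        try:
            prop = proportion_le(donors["numeric_stage"], donors["postmortem_stage"])
        except ValueError:
            pass
    return AgreementReport(
        n_pairs=n_pairs,
        spearman_r=sp_r,
        spearman_p=sp_p,
        residual_r=res_r,
        residual_p=res_p,
        prop_le=prop,
        anova_F=anova_F,
        anova_p=anova_p,
        group_means=means,
    )
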