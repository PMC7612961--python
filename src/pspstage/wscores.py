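"""Covariate-adjusted w-scores from control-cohort normative models.

For each subregion, an ordinary least-squares model of control bilateral
BP_ND on age and a PET/MRI scanner indicator defines the expected normal
value; a subject's w-score is the residual divided by the control residual
standard deviation (denominator n - p by default):

    w = (observed - (b0 + b_age * age + b_scanner * [PET/MRI])) / s_resid

A w-score is therefore a z-score referenced to controls after removing the
age and scanner effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import regions as R

__all__ = ["WScoreModel", "SubjectRecord", "fit_wscore_model", "compute_wscore", "wscore_table"]


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's covariates, scores, and regional values."""

    subject_id: str
    group: str  # control | patient
    age: float  # years
    scanner: str  # petmr | petct | pet
    region_values: dict  # subregion -> bilateral post-PVC BP_ND
    phenotype: str = ""
    psprs: float | None = None
    true_stage: int | None = None
    postmortem_stage: int | None = None
    interval_y: float | None = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.psprs is not None and not np.isnan(self.psprs) and not 0 <= self.psprs <= 100:
            raise ValueError("psprs must lie in [0, 100]")
        if (self.postmortem_stage is None) != (
            self.interval_y is None or (isinstance(self.interval_y, float) and np.isnan(self.interval_y))
        ):
            raise ValueError("interval_y must be present iff postmortem_stage is present")

    @property
    def is_petmr(self) -> bool:
        return self.scanner == "petmr"

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        pm = row.get("postmortem_stage")
        pm_missing = pm is None or (isinstance(pm, float) and np.isnan(pm))
        return cls(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age=float(row["age_y"]),
            scanner=str(row["scanner"]),
            region_values={sub: float(row[R.bpnd_col(sub)]) for sub in R.SUBREGIONS if R.bpnd_col(sub) in row},
            phenotype=str(row.get("phenotype", "")),
            psprs=None if pd.isna(row.get("psprs")) else float(row["psprs"]),
            true_stage=None if pd.isna(row.get("true_stage")) else int(row["true_stage"]),
            postmortem_stage=None if pm_missing else int(pm),
            interval_y=None if pm_missing else float(row["interval_y"]),
        )


@dataclass(frozen=True)
class WScoreModel:
    """Per-region normative model fitted on controls."""

    region: str
    intercept: float
    age_coefficient: float  # BP_ND per year
    scanner_coefficient: float  # BP_ND, PET/MRI indicator (0 if term dropped)
    residual_sd: float  # BP_ND units
    n_controls: int
    has_scanner_term: bool = True

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be strictly positive")

    def predict(self, age, is_petmr) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        ind = np.asarray(is_petmr, dtype=float)
        return self.intercept + self.age_coefficient * age + self.scanner_coefficient * ind

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "intercept": self.intercept,
            "age_coefficient": self.age_coefficient,
            "scanner_coefficient": self.scanner_coefficient,
            "residual_sd": self.residual_sd,
            "n_controls": self.n_controls,
            "has_scanner_term": self.has_scanner_term,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WScoreModel":
        return cls(**d)


def fit_wscore_model(
    controls: pd.DataFrame,
    region: str,
    min_controls: int = 10,
    ddof_mode: str = "n-p",
) -> WScoreModel:
    """OLS of control bilateral BP_ND on age and the PET/MRI indicator.

    If only one scanner class is represented, the scanner term is dropped with
    a warning.  ``ddof_mode`` selects the residual-SD denominator: ``"n-p"``
    (default) or ``"n-1"``.
    """
    col = R.bpnd_col(region)
    if col not in controls.columns:
        raise KeyError(f"missing regional value column {col!r}")
    sub = controls.loc[controls["group"] == "control", ["age_y", "scanner", col]].dropna()
    n = len(sub)
    if n < min_controls:
        raise ValueError(f"need >= {min_controls} controls for region {region!r}, got {n}")
    y = sub[col].to_numpy(dtype=float)
    age = sub["age_y"].to_numpy(dtype=float)
    petmr = (sub["scanner"] == "petmr").to_numpy(dtype=float)

    has_scanner = bool(0 < petmr.sum() < n)
    if not has_scanner:
        warnings.warn(
            f"region {region!r}: only one scanner class among controls; scanner term dropped"
        )
        X = sm.add_constant(np.column_stack([age]))
    else:
        X = sm.add_constant(np.column_stack([age, petmr]))
    p = X.shape[1]
    if n < p + 2:
        raise ValueError(f"too few controls ({n}) for {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"rank-deficient design for region {region!r}")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    ddof = p if ddof_mode == "n-p" else 1
    residual_sd = float(np.sqrt(resid @ resid / (n - ddof)))
    scale = max(1.0, float(np.abs(y).mean()))
    if residual_sd <= 1e-10 * scale or not np.isfinite(residual_sd):
        raise ValueError(f"degenerate normative model for region {region!r}: zero residual variance")
    params = fit.params
    return WScoreModel(
        region=region,
        intercept=float(params[0]),
        age_coefficient=float(params[1]),
        scanner_coefficient=float(params[2]) if has_scanner else 0.0,
        residual_sd=residual_sd,
        n_controls=n,
        has_scanner_term=has_scanner,
    )


def compute_wscore(model: WScoreModel, subject: "SubjectRecord | pd.Series", value: float | None = None) -> float:
    """w-score of one subject's regional value under a normative model."""
    if isinstance(subject, SubjectRecord):
        age, is_petmr = subject.age, subject.is_petmr
        if value is None:
            value = subject.region_values[model.region]
    else:
        age = float(subject["age_y"])
        is_petmr = subject["scanner"] == "petmr"
        if value is None:
            value = float(subject[R.bpnd_col(model.region)])
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    return float((value - float(model.predict(age, is_petmr))) / model.residual_sd)


def wscore_table(df: pd.DataFrame, models: dict[str, WScoreModel]) -> pd.DataFrame:
    """Append one w-score column per modelled region (vectorised)."""
    out = df.copy()
    age = df["age_y"].to_numpy(dtype=float)
    petmr = (df["scanner"] == "petmr").to_numpy(dtype=float)
    for region, model in models.items():
        vals = df[R.bpnd_col(region)].to_numpy(dtype=float)
        out[R.wscore_col(region)] = (vals - model.predict(age, petmr)) / model.residual_sd
    return out
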