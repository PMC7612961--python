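"""Two-step in vivo staging automaton.

Step 1 assigns a coarse stage from the binary presence pattern across the
four composite regions, following the cumulative postmortem sequence
(GP -> FR/CER -> OCC):

* all absent                      -> no stage
* GP absent but anything present  -> unclassifiable (violates the sequence)
* GP only                         -> stage I/II
* GP + (FR or CER), OCC absent    -> stage III/IV
* GP + OCC + (FR or CER)          -> stage V/VI
* GP + OCC, FR and CER absent     -> stage V/VI, flagged atypical

Step 2 refines the pair using the 3-level severity scale (w <= tau: 0;
tau < w <= 2*tau: 1; w > 2*tau: 2): I/II splits on GP severity, III/IV on
max(FR, CER), V/VI on OCC severity.  Composites aggregate their subregions
by maximum severity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import regions as R
from .thresholds import ThresholdEntry

__all__ = [
    "StageAssignment",
    "severity_score",
    "aggregate_composite",
    "assign_stage_step1",
    "assign_substage",
    "stage_from_severity",
    "stage_cohort",
    "STEP1_NUMERIC",
    "STEP2_NUMERIC",
]

STEP1_NUMERIC = {"no_stage": 0.0, "I/II": 1.5, "III/IV": 3.5, "V/VI": 5.5}
STEP2_NUMERIC = {"no_stage": 0.0, "I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0, "V": 5.0, "VI": 6.0}


@dataclass(frozen=True)
class StageAssignment:
    subject_id: str
    severity: dict  # composite -> {0,1,2}
    step1: str
    step2: str
    atypical: bool
    numeric_stage: float  # NaN for unclassifiable

    @property
    def numeric_step1(self) -> float:
        return STEP1_NUMERIC.get(self.step1, float("nan"))


def severity_score(w: float, tau: float) -> int:
    """3-level severity of one w-score under threshold tau.

    0 if w <= tau; 1 if tau < w <= 2*tau; 2 if w > 2*tau.  Boundaries are
    inclusive on the lower severity (strict ">" rule).
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    if not np.isfinite(w):
        raise ValueError("non-finite w-score")
    if w <= tau:
        return 0
    if w <= 2.0 * tau:
        return 1
    return 2


def aggregate_composite(subregion_severities) -> int:
    """Composite severity = maximum over its subregions."""
    sevs = list(subregion_severities)
    if not sevs:
        raise ValueError("empty subregion severity list")
    if any(s not in (0, 1, 2) for s in sevs):
        raise ValueError("severities must be in {0, 1, 2}")
    return max(sevs)


def assign_stage_step1(presence: dict) -> tuple[str, bool]:
    """Coarse stage and atypical flag from the binary presence pattern."""
    missing = [c for c in R.COMPOSITES if c not in presence]
    if missing:
        raise ValueError(f"missing composite presence for {missing}")
    gp, cer, fr, occ = (int(bool(presence[c])) for c in ("GP", "CER", "FR", "OCC"))
    if gp == 0:
        if cer or fr or occ:
            return "unclassifiable", False
        return "no_stage", False
    if occ:
        # OCC involvement without frontal/cerebellar involvement breaks the
        # cumulative sequence; staged at the highest supported level, flagged.
        return "V/VI", not (fr or cer)
    if fr or cer:
        return "III/IV", False
    return "I/II", False


def assign_substage(step1: str, severity: dict) -> str:
    """Refine a step-1 pair into a single stage using the 3-level scale."""
    if step1 in ("no_stage", "unclassifiable"):
        return step1
    gp = severity["GP"]
    frcer = max(severity["FR"], severity["CER"])
    occ = severity["OCC"]
    if step1 == "I/II":
        if gp == 0:
            raise ValueError("step1 I/II inconsistent with GP severity 0")
        return "I" if gp == 1 else "II"
    if step1 == "III/IV":
        if frcer == 0:
            raise ValueError("step1 III/IV inconsistent with absent FR and CER")
        return "III" if frcer == 1 else "IV"
    if step1 == "V/VI":
        if occ == 0:
            raise ValueError("step1 V/VI inconsistent with absent OCC")
        return "V" if occ == 1 else "VI"
    raise ValueError(f"unknown step1 stage {step1!r}")


def stage_from_severity(severity: dict, subject_id: str = "") -> StageAssignment:
    """Full two-step assignment from a composite severity vector."""
    presence = {c: int(severity[c] > 0) for c in R.COMPOSITES}
    step1, atypical = assign_stage_step1(presence)
    step2 = assign_substage(step1, severity)
    numeric = STEP2_NUMERIC.get(step2, float("nan"))
    return StageAssignment(
        subject_id=subject_id,
        severity=dict(severity),
        step1=step1,
        step2=step2,
        atypical=atypical,
        numeric_stage=numeric,
    )


def _composite_severity(
    wrow: pd.Series, thresholds: dict[str, ThresholdEntry]
) -> tuple[dict, list[str]]:
    """Per-composite severity; returns (severity dict, missing subregions)."""
    severity: dict[str, int] = {}
    missing: list[str] = []
    for comp, subs in R.COMPOSITES.items():
        sevs = []
        for sub in subs:
            w = wrow.get(R.wscore_col(sub), float("nan"))
            if w is None or (isinstance(w, float) and np.isnan(w)):
                missing.append(sub)
                continue
            sevs.append(severity_score(float(w), thresholds[sub].tau))
        severity[comp] = aggregate_composite(sevs) if sevs else -1  # -1: unknown
    return severity, missing


def _stage_with_missing(severity: dict, subject_id: str) -> StageAssignment:
    """Stage a subject whose severity vector has unknown (-1) composites.

    The subject is staged only if every completion of the unknown entries
    yields the same step-2 outcome; otherwise flagged `unclassifiable_missing`
    (distinct from the sequence-violating `unclassifiable`).
    """
    unknown = [c for c, s in severity.items() if s == -1]
    outcomes = set()
    assignments = []
    for combo in itertools.product((0, 1, 2), repeat=len(unknown)):
        sev = dict(severity)
        sev.update(dict(zip(unknown, combo)))
        a = stage_from_severity(sev, subject_id)
        outcomes.add((a.step1, a.step2, a.atypical))
        assignments.append(a)
    if len(outcomes) == 1:
        return assignments[0]
    return StageAssignment(
        subject_id=subject_id,
        severity=dict(severity),
        step1="unclassifiable_missing",
        step2="unclassifiable_missing",
        atypical=False,
        numeric_stage=float("nan"),
    )


def stage_cohort(
    wtable: pd.DataFrame,
    thresholds: dict[str, ThresholdEntry],
    occ_combined: bool = False,
) -> pd.DataFrame:
    """Stage every subject of a w-score table; controls are staged identically.

    ``occ_combined=True`` thresholds the mean of the two occipital subregion
    w-scores against a single ``occ`` threshold entry (fallback 1.645 if no
    such entry is configured) instead of taking the per-subregion maximum.
    """
    needed = [s for s in R.SUBREGIONS]
    absent = [s for s in needed if s not in thresholds]
    if absent and not (occ_combined and set(absent) <= {"occ_ling", "occ_cun"}):
        raise ValueError(f"missing thresholds for regions {absent}")
    rows = []
    for _, row in wtable.iterrows():
        sid = str(row["subject_id"])
        severity, missing = _composite_severity(row, thresholds)
        if occ_combined:
            wl = row.get(R.wscore_col("occ_ling"), float("nan"))
            wc = row.get(R.wscore_col("occ_cun"), float("nan"))
            tau_occ = thresholds["occ"].tau if "occ" in thresholds else 1.645
            if np.isnan(wl) or np.isnan(wc):
                severity["OCC"] = -1
            else:
                severity["OCC"] = severity_score(0.5 * (float(wl) + float(wc)), tau_occ)
        if any(s == -1 for s in severity.values()):
            a = _stage_with_missing(severity, sid)
        else:
            a = stage_from_severity(severity, sid)
        rec = {
            "subject_id": sid,
            "group": row.get("group", ""),
            **{f"sev_{c}": a.severity.get(c, -1) for c in R.COMPOSITES},
            "step1": a.step1,
            "step2": a.step2,
            "atypical": a.atypical,
            "numeric_stage": a.numeric_stage,
            "numeric_step1": a.numeric_step1,
        }
        for sub in R.SUBREGIONS:
            col = R.wscore_col(sub)
            if col in row:
                rec[col] = row[col]
        rows.append(rec)
    return pd.DataFrame(rows)
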