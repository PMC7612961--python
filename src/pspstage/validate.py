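"""Validation statistics for the in vivo staging.

Covers the analyses used to test whether the PET-derived stage behaves like a
true pathology stage: a one-way ANOVA of clinical severity (PSPRS) across
stages, Spearman rank agreement between in vivo and postmortem stage, the
same correlation after residualising both staging variables on PSPRS and the
PET-to-death interval, and the fraction of autopsy cases with
in vivo <= postmortem stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "anova_by_stage",
    "spearman_agreement",
    "residualized_correlation",
    "proportion_le",
]


@dataclass(frozen=True)
class AgreementReport:
    n_pairs: int
    spearman_r: float
    spearman_p: float
    residual_r: float
    residual_p: float
    prop_le: float
    anova_F: float
    anova_p: float
    group_means: dict  # stage label -> mean PSPRS

    def to_dict(self) -> dict:
        return asdict(self)


def anova_by_stage(psprs, stages, min_group_size: int = 2):
    """One-way fixed-effects ANOVA of PSPRS across stage groups.

    Groups smaller than ``min_group_size`` are dropped; at least two groups
    must remain.  Returns (F, p, group_means).
    """
    s = pd.Series(np.asarray(psprs, dtype=float))
    g = pd.Series(list(stages))
    ok = s.notna() & g.notna()
    s, g = s[ok], g[ok]
    groups = {lab: s[g == lab].to_numpy() for lab in g.unique()}
    groups = {lab: v for lab, v in groups.items() if v.size >= min_group_size}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 stage groups with enough members")
    vals = list(groups.values())
    if all(np.var(v) == 0 for v in vals):
        raise ValueError("zero within-group variance in every group")
    F, p = stats.f_oneway(*vals)
    means = {str(lab): float(v.mean()) for lab, v in groups.items()}
    return float(F), float(p), means


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman r (tie-aware midranks).

    Enumerates all n! permutations of one rank vector; feasible for n <= 9.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c @ rx_c) * (ry_c * ry_c).sum(axis=1))
    r_perm = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))


def spearman_agreement(invivo, postmortem, exact_max_n: int = 9):
    """Spearman rank correlation between two numeric stage vectors.

    Midrank ties; p-value by exact permutation enumeration for n <= 9
    (``exact_max_n``), large-sample approximation otherwise.  NaN entries
    (e.g. unclassifiable subjects) are excluded pairwise.
    """
    x = np.asarray(invivo, dtype=float)
    y = np.asarray(postmortem, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in a stage vector")
    r, p_asym = stats.spearmanr(x, y)
    if x.size <= exact_max_n:
        p = _exact_spearman_p(x, y, float(r))
    else:
        p = float(p_asym)
    return float(r), p


def residualized_correlation(invivo, postmortem, psprs, interval_y, exact_max_n: int = 9):
    """Spearman correlation of staging residuals after removing covariates.

    Each (numeric-coded) staging variable is regressed by OLS on PSPRS and
    the PET-to-death interval; the Spearman correlation of the two residual
    vectors is returned.  Complete cases only; n >= 5 required.
    """
    arrs = [np.asarray(a, dtype=float) for a in (invivo, postmortem, psprs, interval_y)]
    ok = np.logical_and.reduce([np.isfinite(a) for a in arrs])
    x, y, z1, z2 = (a[ok] for a in arrs)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    X = np.column_stack([np.ones(n), z1, z2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if np.allclose(rx, 0.0, atol=1e-10) or np.allclose(ry, 0.0, atol=1e-10):
        raise ValueError("staging variable is an exact function of the covariates; residuals degenerate")
    r, p_asym = stats.spearmanr(rx, ry)
    p = _exact_spearman_p(rx, ry, float(r)) if n <= exact_max_n else float(p_asym)
    return float(r), p


def proportion_le(invivo, postmortem) -> float:
    """Fraction of complete pairs with in vivo stage <= postmortem stage."""
    x = np.asarray(invivo, dtype=float)
    y = np.asarray(postmortem, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no complete in vivo / postmortem pairs")
    return float(np.mean(x[ok] <= y[ok]))
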