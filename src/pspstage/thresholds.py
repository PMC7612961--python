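"""Per-region abnormality thresholds on the w-score scale.

The data-driven rule mimics the first split of a conditional-inference tree
with diagnosis as the binary response and the regional w-score as the sole
predictor: candidate cut points are midpoints between consecutive sorted
unique w-scores; each is scored by the chi-square statistic of the 2x2
(group x side-of-split) table; global significance is assessed by permuting
the group labels and comparing the observed maximal statistic with the
permutation distribution of maximal statistics (max-T correction over cut
points).  Only the first split is used, one cut point per region.

When no significant split exists, the fallback threshold is the one-sided
standard-normal critical value at P = 0.05, w = 1.645.  The SD-based
alternative places the cut at a preselected number of control SDs, which on
the w-score scale is simply tau = k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import regions as R

__all__ = [
    "FALLBACK_W",
    "SplitSearch",
    "ThresholdEntry",
    "find_threshold",
    "split_search",
    "resolve_threshold",
    "sd_threshold",
    "derive_thresholds",
    "thresholds_to_json",
    "thresholds_from_json",
]

#: One-sided standard-normal critical value at P = 0.05.
FALLBACK_W = 1.645


class SplitSearch(NamedTuple):
    """Full result of the permutation split search."""

    cut: float
    statistic: float
    p_value: float


@dataclass(frozen=True)
class ThresholdEntry:
    """One region's abnormality cut with provenance."""

    region: str
    tau: float  # w-score threshold
    source: str  # data_driven | fallback | sd_based
    p_value: float | None = None
    k_sd: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau):
            raise ValueError("tau must be finite")
        if self.source == "fallback" and abs(self.tau - FALLBACK_W) > 1e-12:
            raise ValueError("fallback entries must use tau = 1.645")
        if self.source == "sd_based" and (self.k_sd is None or abs(self.tau - self.k_sd) > 1e-12):
            raise ValueError("sd_based entries must carry k_sd with tau = k_sd")


def _chi2_scan(w_sorted: np.ndarray, y_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square of the 2x2 table for every between-observation boundary.

    Boundaries falling inside ties get statistic -inf (not valid cut points).
    Returns (midpoints, statistics), ordered by ascending cut.
    """
    n = w_sorted.size
    n1 = float(y_sorted.sum())
    n0 = n - n1
    a = np.cumsum(y_sorted)[:-1]  # group-1 count at or below the boundary
    left = np.arange(1, n, dtype=float)
    b = n1 - a
    c = left - a
    d = n0 - c
    denom = n1 * n0 * left * (n - left)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    valid = w_sorted[1:] != w_sorted[:-1]
    chi2 = np.where(valid, chi2, -np.inf)
    mids = 0.5 * (w_sorted[1:] + w_sorted[:-1])
    return mids, chi2


def split_search(
    wscores: Sequence[float],
    is_patient: Sequence[bool],
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> SplitSearch:
    """Best first split and its max-T permutation p-value.

    Ties in the statistic resolve to the smallest midpoint.  The p-value uses
    the add-one estimator (1 + #{perm max >= observed max}) / (n_perm + 1).
    """
    w = np.asarray(wscores, dtype=float)
    y = np.asarray(is_patient, dtype=bool)
    if w.shape != y.shape or w.ndim != 1:
        raise ValueError("wscores and group labels must be 1-D and equal length")
    if not np.isfinite(w).all():
        raise ValueError("non-finite w-scores")
    if y.all() or not y.any():
        raise ValueError("both groups must be present")
    if np.unique(w).size < 2:
        raise ValueError("all w-scores identical; no candidate split exists")
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")

    order = np.argsort(w, kind="mergesort")
    ws, ys = w[order], y[order].astype(float)
    mids, chi2 = _chi2_scan(ws, ys)
    best = int(np.argmax(chi2))  # first occurrence -> smallest midpoint
    obs = float(chi2[best])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)
    n = ws.size
    n1 = ys.sum()
    n0 = n - n1
    a = np.cumsum(perm, axis=1)[:, :-1]
    left = np.arange(1, n, dtype=float)
    d = n0 - (left - a)
    b = n1 - a
    c = left - a
    denom = n1 * n0 * left * (n - left)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_perm = n * (a * d - b * c) ** 2 / denom
    valid = ws[1:] != ws[:-1]
    chi2_perm = np.where(valid, chi2_perm, -np.inf)
    perm_max = chi2_perm.max(axis=1)
    p = float((1 + np.sum(perm_max >= obs - 1e-12)) / (n_perm + 1))
    return SplitSearch(cut=float(mids[best]), statistic=obs, p_value=p)


def find_threshold(
    wscores: Sequence[float],
    is_patient: Sequence[bool],
    alpha: float = 0.05,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> float | None:
    """Data-driven threshold, or None when the split is not significant."""
    res = split_search(wscores, is_patient, n_perm=n_perm, seed=seed)
    return res.cut if res.p_value < alpha else None


def resolve_threshold(
    region: str, data_driven: float | None, p_value: float | None = None
) -> ThresholdEntry:
    """Data-driven cut when available, else the 1.645 fallback."""
    if data_driven is not None:
        return ThresholdEntry(region=region, tau=float(data_driven), source="data_driven", p_value=p_value)
    return ThresholdEntry(region=region, tau=FALLBACK_W, source="fallback")


def sd_threshold(region: str, k_sd: float = 2.0) -> ThresholdEntry:
    """SD-based cut: control mean + k*SD, which on the w-score scale is w = k."""
    if not k_sd > 0:
        raise ValueError("k_sd must be positive")
    return ThresholdEntry(region=region, tau=float(k_sd), source="sd_based", k_sd=float(k_sd))


def derive_thresholds(
    wtable: pd.DataFrame,
    method: str = "data_driven",
    regions: Sequence[str] = R.SUBREGIONS,
    alpha: float = 0.05,
    n_perm: int = 9999,
    seed: int | None = None,
    k_sd: float = 2.0,
) -> dict[str, ThresholdEntry]:
    """Per-region threshold set over a table carrying group and w columns."""
    out: dict[str, ThresholdEntry] = {}
    rng = np.random.default_rng(seed)
    for region in regions:
        if method == "sd_based":
            out[region] = sd_threshold(region, k_sd)
            continue
        col = R.wscore_col(region)
        sub = wtable[[col, "group"]].dropna()
        res = split_search(
            sub[col].to_numpy(), (sub["group"] == "patient").to_numpy(),
            n_perm=n_perm, seed=rng,
        )
        cut = res.cut if res.p_value < alpha else None
        # abnormality means *elevated* binding: a non-positive cut is not a
        # meaningful pathology threshold (and breaks the 2*tau severity rule),
        # so the region falls back to the 1.645 critical value
        if cut is not None and cut <= 0:
            cut = None
        out[region] = resolve_threshold(region, cut, p_value=res.p_value if cut is not None else None)
    return out


def thresholds_to_json(thresholds: dict[str, ThresholdEntry], path) -> None:
    with open(path, "w") as fh:
        json.dump({r: asdict(e) for r, e in thresholds.items()}, fh, indent=2)


def thresholds_from_json(path) -> dict[str, ThresholdEntry]:
    with open(path) as fh:
        raw = json.load(fh)
    return {r: ThresholdEntry(**d) for r, d in raw.items()}
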