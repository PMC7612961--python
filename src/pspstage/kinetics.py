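"""Regional BP_ND estimation: CSF partial-volume correction, basis-function
SRTM fitting, and bilateral averaging.

The basis-function SRTM fit grids the apparent target washout rate k2a
(logarithmically by default), precomputes one convolution basis
B(t; k2a) = C_ref (*) exp(-k2a t) per grid point, solves the linear
least-squares subproblem C_T ~ theta1*C_ref + theta2*B at each, and keeps the
grid point with minimal residual sum of squares.  Parameter mapping:
R1 = theta1, k2 = theta2 + theta1*k2a, BP_ND = k2/k2a - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tac import TimeActivityCurve, _exp_convolve_multi, _fine_grid

__all__ = [
    "BasisConfig",
    "SRTMFit",
    "pvc_correct",
    "fit_srtm_basis",
    "bilateral_average",
]


@dataclass(frozen=True)
class BasisConfig:
    """Logarithmic k2a grid for the basis-function SRTM fit.

    The default range [0.006, 0.6] 1/min spans physiological washout for
    flortaucipir-class tracers.
    """

    k2a_min: float = 0.006  # 1/min
    k2a_max: float = 0.6  # 1/min
    n_basis: int = 100
    dt: float = 0.05  # internal convolution resolution, minutes

    def __post_init__(self) -> None:
        if not (0 < self.k2a_min < self.k2a_max):
            raise ValueError("require 0 < k2a_min < k2a_max")
        if self.n_basis < 10:
            raise ValueError("n_basis must be >= 10")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def grid(self) -> np.ndarray:
        return np.geomspace(self.k2a_min, self.k2a_max, self.n_basis)


@dataclass(frozen=True)
class SRTMFit:
    """Result of a basis-function SRTM fit for one region."""

    R1: float
    k2: float  # 1/min
    k2a: float  # 1/min, on the basis grid
    bp_nd: float
    rss: float
    basis_index: int
    region_label: str = ""


def pvc_correct(value, gmwm_fraction):
    """CSF partial-volume correction: divide the regional PET value by the
    mean regional gray-plus-white-matter tissue fraction.

    Accepts scalars or arrays; the fraction must lie in (0, 1].
    """
    frac = np.asarray(gmwm_fraction, dtype=float)
    if np.any(~np.isfinite(frac)) or np.any(frac <= 0) or np.any(frac > 1):
        raise ValueError("gmwm_fraction must lie in (0, 1]")
    out = np.asarray(value, dtype=float) / frac
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(out)
    return out


def fit_srtm_basis(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    basis: BasisConfig | None = None,
) -> SRTMFit:
    """Fit the SRTM to a target TAC against a reference TAC.

    Target and reference must share the framing scheme and have at least four
    frames.  Ties in RSS across the grid resolve to the lowest k2a index.
    Negative theta2 (BP_ND below 0) is permitted; BP_ND <= -1 is rejected as a
    failed fit.
    """
    basis = basis or BasisConfig()
    if not target.same_framing(reference):
        raise ValueError("target and reference must share an identical framing scheme")
    if target.n_frames < 4:
        raise ValueError("need at least 4 frames")
    if np.allclose(reference.activity, 0.0):
        raise ValueError("degenerate (constant-zero) reference curve")

    t, c_ref_fine = _fine_grid(reference, basis.dt)
    grid = basis.grid
    conv = _exp_convolve_multi(t, c_ref_fine, grid)  # (K, J)
    idx = np.searchsorted(t, reference.midpoints)
    c_ref = c_ref_fine[idx]
    bases = conv[:, idx]  # (K, n_frames)

    y = target.activity
    best = None
    for k, b in enumerate(bases):
        design = np.column_stack([c_ref, b])
        theta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < 2:
            continue
        resid = y - design @ theta
        rss = float(resid @ resid)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, k, theta)
    if best is None:
        raise ValueError("rank-deficient basis problem for every grid point")
    rss, k, (theta1, theta2) = best
    if not np.isfinite(rss):
        raise ValueError("non-finite residual sum of squares")
    k2a = float(grid[k])
    r1 = float(theta1)
    k2 = float(theta2 + theta1 * k2a)
    bp_nd = k2 / k2a - 1.0
    if bp_nd <= -1.0:
        raise ValueError(f"failed fit: BP_ND = {bp_nd:.3f} <= -1")
    return SRTMFit(
        R1=r1, k2=k2, k2a=k2a, bp_nd=bp_nd, rss=rss, basis_index=k,
        region_label=target.region_label,
    )


def rss_profile(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    basis: BasisConfig | None = None,
) -> np.ndarray:
    """Residual sum of squares at every k2a grid point (diagnostic)."""
    basis = basis or BasisConfig()
    t, c_ref_fine = _fine_grid(reference, basis.dt)
    conv = _exp_convolve_multi(t, c_ref_fine, basis.grid)
    idx = np.searchsorted(t, reference.midpoints)
    c_ref = c_ref_fine[idx]
    y = target.activity
    out = np.empty(basis.n_basis)
    for k in range(basis.n_basis):
        design = np.column_stack([c_ref, conv[k, idx]])
        theta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ theta
        out[k] = resid @ resid
    return out


def bilateral_average(left: float | None, right: float | None) -> float:
    """Average left/right regional BP_ND; fall back to the present side.

    With exactly one side missing (None/NaN) the other side is returned and a
    warning is emitted; both missing is an error.
    """
    lm = left is None or (isinstance(left, float) and np.isnan(left))
    rm = right is None or (isinstance(right, float) and np.isnan(right))
    if lm and rm:
        raise ValueError("both left and right values are missing")
    if lm or rm:
        present = right if lm else left
        warnings.warn("one hemisphere missing; using the other side alone", stacklevel=2)
        return float(present)  # type: ignore[arg-type]
    return 0.5 * (float(left) + float(right))
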