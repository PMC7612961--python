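"""Region scheme for in vivo PSP tau staging.

The staging scheme evaluates four composite regions that mirror the postmortem
progression of 4-repeat tau pathology: globus pallidus (GP), cerebellum
(CER: white matter + dentate nucleus), middle frontal gyrus (FR), and occipital
lobe (OCC: lingual gyrus + cuneus).  The striatum and subthalamic nucleus are
excluded because of known flortaucipir off-target binding.

Measured (thresholded) units are the six subregions; composites aggregate
subregion severities by maximum.
"""

from __future__ import annotations

#: Subregions carrying their own bilateral BP_ND value and w-score threshold.
SUBREGIONS: tuple[str, ...] = ("gp", "cer_wm", "cer_dn", "fr", "occ_ling", "occ_cun")

#: Composite staging regions -> their subregions.
COMPOSITES: dict[str, tuple[str, ...]] = {
    "GP": ("gp",),
    "CER": ("cer_wm", "cer_dn"),
    "FR": ("fr",),
    "OCC": ("occ_ling", "occ_cun"),
}

SUBREGION_TO_COMPOSITE: dict[str, str] = {
    sub: comp for comp, subs in COMPOSITES.items() for sub in subs
}

#: True stage at which a composite first becomes involved (mild); one stage
#: later it is moderate/severe.  GP: I/II, FR+CER: III/IV, OCC: V/VI.
STAGE_OF_ONSET: dict[str, int] = {"GP": 1, "CER": 3, "FR": 3, "OCC": 5}

ROMAN = {0: "none", 1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI"}
ROMAN_TO_INT = {v: k for k, v in ROMAN.items()}


def true_severity(composite: str, stage: int) -> int:
    """3-level severity of `composite` for a subject at true stage `stage`.

    Stage 0 means no pathology (control).  Involvement is cumulative: a region
    is mild at its onset stage and moderate/severe from the following stage on.
    """
    if stage < 0 or stage > 6:
        raise ValueError(f"stage must be in 0..6, got {stage}")
    onset = STAGE_OF_ONSET[composite]
    if stage < onset:
        return 0
    if stage == onset:
        return 1
    return 2


def bpnd_left_col(sub: str) -> str:
    return f"{sub}_bpnd_left"


def bpnd_right_col(sub: str) -> str:
    return f"{sub}_bpnd_right"


def gmwm_col(sub: str) -> str:
    return f"{sub}_gmwm"


def bpnd_col(sub: str) -> str:
    """Bilateral, partial-volume-corrected BP_ND column."""
    return f"{sub}_bpnd"


def wscore_col(sub: str) -> str:
    return f"{sub}_w"
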