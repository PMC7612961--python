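"""Validation statistics for the in vivo staging.

Computes the PSPRS-by-stage ANOVA over patients, the Spearman agreement
between in vivo and postmortem stage in the donation subset, the same
correlation after residualising both staging variables on PSPRS and the
PET-to-death interval, and the fraction of cases with in vivo <= postmortem
stage.  Writes results/validation.json.

In the generator's default world PSPRS is independent of stage, so the ANOVA
should (at the 5% level, most seeds) fail to reject — the structure of the
original negative finding.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pspstage import io
from pspstage.validate import (
    anova_by_stage,
    proportion_le,
    residualized_correlation,
    spearman_agreement,
)

OUT = Path("results")


def main() -> None:
    staged = pd.read_csv(OUT / "staging.csv")
    pat = staged[staged["group"] == "patient"]
    classifiable = pat[~pat["step2"].isin(["unclassifiable", "unclassifiable_missing"])]

    F, p, means = anova_by_stage(classifiable["psprs"], classifiable["step2"])
    print(f"ANOVA of PSPRS across step-2 stages: F = {F:.2f}, p = {p:.3f}")
    print("  stage means:", {k: round(v, 1) for k, v in means.items()})

    donors = pat[np.isfinite(pat["postmortem_stage"])]
    r, sp_p = spearman_agreement(donors["numeric_stage"], donors["postmortem_stage"])
    rr, rp = residualized_correlation(
        donors["numeric_stage"], donors["postmortem_stage"],
        donors["psprs"], donors["interval_y"],
    )
    prop = proportion_le(donors["numeric_stage"], donors["postmortem_stage"])
    print(f"in vivo vs postmortem stage (n = {len(donors)}): "
          f"Spearman r = {r:.3f} (exact p = {sp_p:.2f})")
    print(f"after removing PSPRS + interval: r = {rr:.3f} (p = {rp:.2f})")
    print(f"in vivo <= postmortem in {100 * prop:.0f}% of autopsy cases")

    io.write_json(
        {"anova_F": F, "anova_p": p, "stage_means": means,
         "spearman_r": r, "spearman_p": sp_p,
         "residual_r": rr, "residual_p": rp, "prop_le": prop,
         "n_pairs": int(len(donors))},
        OUT / "validation.json",
    )
    print("wrote results/validation.json")


if __name__ == "__main__":
    main()
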