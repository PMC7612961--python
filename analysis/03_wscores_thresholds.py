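"""w-scores and per-region abnormality thresholds.

Applies CSF partial-volume correction and bilateral averaging, fits the
control normative models (age + PET/MRI indicator), converts every subject's
regional BP_ND to w-scores, and derives data-driven thresholds with the
permutation-tested first split (falling back to w = 1.645 where no split is
significant — in the original analysis this happened for the occipital lobe).

Writes results/wscores.csv, results/wscore_models.json, results/thresholds.json.
"""

import sys
import warnings
from pathlib import Path

from pspstage import io
from pspstage import regions as R
from pspstage.pipeline import preprocess_bpnd
from pspstage.thresholds import derive_thresholds, thresholds_to_json
from pspstage.wscores import fit_wscore_model, wscore_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    warnings.filterwarnings("ignore")
    df = preprocess_bpnd(io.read_cohort(OUT / "cohort.csv"))
    models = {sub: fit_wscore_model(df, sub) for sub in R.SUBREGIONS}
    wtable = wscore_table(df, models)
    io.write_cohort(wtable, OUT / "wscores.csv")
    io.write_wscore_models(models, OUT / "wscore_models.json")

    thresholds = derive_thresholds(wtable, method="data_driven", n_perm=9999, seed=SEED)
    thresholds_to_json(thresholds, OUT / "thresholds.json")
    for region, e in thresholds.items():
        p = "" if e.p_value is None else f"  (max-T permutation p = {e.p_value:.4f})"
        print(f"{region:10s} tau = {e.tau:.3f}  [{e.source}]{p}")


if __name__ == "__main__":
    main()
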