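import numpy as np
import pytest

from pspstage import regions as R
from pspstage.synthetic import CohortConfig, default_reference_curve, generate_cohort
from pspstage.wscores import fit_wscore_model, wscore_table


@pytest.fixture(scope="session")
def reference():
    return default_reference_curve(duration_min=90.0, n_frames=20)


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort with the study's sizes and default generator conditions."""
    return generate_cohort(CohortConfig(seed=11))


def add_bilateral(df):
    """Undo the generator's CSF dilution and average hemispheres."""
    out = df.copy()
    for sub in R.SUBREGIONS:
        left = out[R.bpnd_left_col(sub)] / out[R.gmwm_col(sub)]
        right = out[R.bpnd_right_col(sub)] / out[R.gmwm_col(sub)]
        out[R.bpnd_col(sub)] = 0.5 * (left + right)
    return out


@pytest.fixture(scope="session")
def wscored_cohort(study_cohort):
    df = add_bilateral(study_cohort)
    models = {sub: fit_wscore_model(df, sub) for sub in R.SUBREGIONS}
    return wscore_table(df, models), models
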