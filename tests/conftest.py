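import numpy as np
import pytest

import threatgaze as tg
from threatgaze import selection

#: Conventional seed for all stochastic recovery checks.
RECOVERY_SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    """Default two-group synthetic cohort (21 controls, 15 patients)."""
    return tg.generate_cohort(master_seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def cohort_fits(default_cohort):
    """Per-subject M1 and M2 fits for both groups of the default cohort."""
    return {
        label: tg.fit_cohort(default_cohort.group_trials(label), ("M1", "M2"))
        for label in ("control", "patient")
    }


@pytest.fixture(scope="session")
def cohort_bms(cohort_fits):
    """Random-effects BMS result per group."""
    out = {}
    for label, fits in cohort_fits.items():
        ev = selection.evidence_matrix(fits)
        out[label] = (ev, selection.rfx_bms(ev, mc_seed=RECOVERY_SEED))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
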