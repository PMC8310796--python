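import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from adrebound import growthmodel, rebound, simcohort

warnings.filterwarnings("ignore", category=UserWarning)

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate synthetic cohort shared across read-only tests."""
    cfg = simcohort.SimConfig(n_children=300, seed=11)
    anthro, cov, geno, truth = simcohort.generate_cohort(cfg)
    return cfg, anthro, cov, geno, truth


@pytest.fixture(scope="session")
def fitted_cohort(small_cohort):
    """Growth fits, curves and AR table for the shared cohort."""
    _, anthro, _, _, truth = small_cohort
    eligible, exclusions = growthmodel.eligibility_filter(anthro)
    records = anthro[anthro.child_id.isin(eligible)]
    fits = {
        sex: growthmodel.fit_cubic_mixed(records, sex=sex)
        for sex in ("male", "female")
    }
    curves = pd.concat(
        [growthmodel.predict_curves(f) for f in fits.values()], ignore_index=True
    )
    ar_table, counts = rebound.ar_for_cohort(curves, exclusions)
    return fits, curves, ar_table, counts, exclusions, truth


def grid_argmin_last_local_min(coefs, window, step=1.0):
    """Independent AR oracle: exhaustive grid search for the last interior
    local minimum of the cubic over the window."""
    lo, hi = window
    ages = np.arange(lo, hi + step / 2, step)
    c0, c1, c2, c3 = coefs
    v = c0 + c1 * ages + c2 * ages**2 + c3 * ages**3
    interior = np.where((v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:]))[0] + 1
    if len(interior) == 0:
        return None
    return float(ages[interior[-1]])


def random_rebound_curves(rng, n):
    """Curves drawn from the simulator's own family (peak-then-nadir)."""
    ar = rng.uniform(700.0, 4600.0, n)
    peak = np.clip(rng.normal(270.0, 40.0, n), 60.0, 0.5 * ar)
    c3 = 4.45e-11 * np.exp(rng.normal(0.0, 0.25, n))
    c2 = -1.5 * c3 * (peak + ar)
    c1 = 3.0 * c3 * peak * ar
    c0 = rng.normal(2.74, 0.05, n)
    return np.column_stack([c0, c1, c2, c3]), ar
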