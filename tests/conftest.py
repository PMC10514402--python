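import warnings
from dataclasses import replace

import numpy as np
import pytest

from thiomon.cohort import (CodedEvent, LabResult, PrescriptionEvent,
                            default_true_model, generate_cohort)
from thiomon.imputation import ImputedStack, mice_impute

# lifelines emits convergence chatter on deliberately degenerate fixtures
warnings.filterwarnings("ignore", module="lifelines")


@pytest.fixture(scope="session")
def truth_complete():
    """Generating model with missingness switched off (complete data)."""
    return replace(default_true_model(), missingness={})


@pytest.fixture(scope="session")
def complete_cohort(truth_complete):
    return generate_cohort(1500, truth_complete, seed=42).drop(columns=["reason"])


@pytest.fixture(scope="session")
def complete_stack(complete_cohort):
    """Stack of two identical complete datasets (degenerate imputation)."""
    return ImputedStack([complete_cohort, complete_cohort.copy()], seed=0,
                        iterations=0)


@pytest.fixture(scope="session")
def missing_cohort():
    return generate_cohort(900, seed=11).drop(columns=["reason"])


@pytest.fixture(scope="session")
def imputed_stack(missing_cohort):
    return mice_impute(missing_cohort, m=3, iterations=3, seed=5)


def random_streams(rng, n_prescriptions=8, n_labs=6, n_codes=2, span=900):
    """A random longitudinal record for one subject (for oracle tests)."""
    dates = np.sort(rng.integers(0, span, n_prescriptions))
    prescriptions = [PrescriptionEvent("s", int(d), "azathioprine", 100.0)
                     for d in dates]
    analytes = ["wbc", "neutrophils", "platelets", "alt", "ast", "creatinine"]
    ranges = {"wbc": (2.0, 10.0), "neutrophils": (0.8, 6.0),
              "platelets": (80.0, 400.0), "alt": (10.0, 200.0),
              "ast": (10.0, 200.0), "creatinine": (50.0, 140.0)}
    labs = []
    for _ in range(n_labs):
        a = analytes[rng.integers(0, len(analytes))]
        lo, hi = ranges[a]
        labs.append(LabResult("s", int(rng.integers(0, span)), a,
                              float(lo + (hi - lo) * rng.random())))
    codes = [CodedEvent("s", int(rng.integers(0, span)), bool(rng.random() < 0.5))
             for _ in range(n_codes)]
    return prescriptions, labs, codes
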