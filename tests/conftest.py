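import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import tli_ntcp as T

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic bilateral cohort with its ground truth."""
    lobes, truth = T.generate_cohort(T.CohortConfig(seed=7))
    return T.cohort_to_frame(lobes), truth


@pytest.fixture(scope="session")
def large_cohort():
    """2000-lobe cohort for parameter-recovery checks."""
    lobes, truth = T.generate_cohort(T.CohortConfig(n_patients=1000, seed=21))
    return T.cohort_to_frame(lobes), truth


@pytest.fixture
def step_curve():
    """Hand curve with an interior shoulder: (0,100),(50,50),(70,1),(75,0)."""
    return T.DVHCurve("hand", np.array([0.0, 50.0, 70.0, 75.0]),
                      np.array([100.0, 50.0, 1.0, 0.0]))


def bilateral_fixture_cohort() -> pd.DataFrame:
    """132-patient bilateral cohort with exactly 21 patients censored by
    death/repeat RT before 50 months: 17 injured patients (4 bilateral),
    every other uninjured lobe followed past 50 months."""
    rows = []

    def add(pid, side, time, event, reason):
        rows.append({"patient_id": pid, "side": side, "time_months": time,
                     "event": event, "censor_reason": reason})

    pid = 0
    for i in range(4):          # bilateral injuries
        pid += 1
        add(f"P{pid}", "left", 19 + 3 * i, 1, None)
        add(f"P{pid}", "right", 25 + 3 * i, 1, None)
    for i in range(13):         # unilateral injuries, partner followed long
        pid += 1
        add(f"P{pid}", "left", 20 + 3 * i, 1, None)
        add(f"P{pid}", "right", 63.5, 0, "end_of_followup")
    for i in range(14):         # dead before the window
        pid += 1
        for side in ("left", "right"):
            add(f"P{pid}", side, 30.0, 0, "death")
    for i in range(7):          # re-irradiated before the window
        pid += 1
        for side in ("left", "right"):
            add(f"P{pid}", side, 24.0, 0, "repeat_rt")
    while pid < 132:            # uninjured, adequately followed
        pid += 1
        for side in ("left", "right"):
            add(f"P{pid}", side, 63.5, 0, "end_of_followup")
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def eligibility_cohort():
    return bilateral_fixture_cohort()
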