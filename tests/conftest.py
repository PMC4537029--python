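import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import combsynergy as cs

settings.register_profile(
    "suite",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def grid_design():
    """The standard 2x2 PDT x inhibitor factorial design."""
    return cs.grid_design()


@pytest.fixture
def noiseless_sf():
    """SF records from a noiseless simulated plate (true DL = 0.3 everywhere)."""
    spec = cs.ViabilitySimSpec(noise_sd_log=0.0, seed=11)
    design, ms = cs.simulate_viability_experiment(spec)
    corrected = cs.background_correct(ms, design)
    return design, cs.survival_fraction(corrected, design), spec


def product_limit(times, events, t):
    """Brute-force Kaplan-Meier oracle: direct product over event times <= t,
    risk set counted from scratch at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        n_risk = int(np.sum(times >= u))
        d = int(np.sum((times == u) & (events == 1)))
        s *= 1.0 - d / n_risk
    return s


@pytest.fixture
def km_oracle():
    return product_limit


def make_measurements(rows):
    return cs.MeasurementSet(
        pd.DataFrame(rows, columns=["condition_id", "experiment", "replicate", "signal"])
    )


@pytest.fixture
def tiny_design():
    return cs.Design(
        [
            cs.TreatmentCondition("blank", "blank"),
            cs.TreatmentCondition("control", "untreated_control"),
            cs.TreatmentCondition("treated", "pdt", photosensitizer_dose=50.0,
                                  light_dose=1.0),
        ]
    )
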