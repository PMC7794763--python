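import numpy as np
import pandas as pd
import pytest

from ergkit.simulate import SimParams, simulate_cohort
from ergkit.simulate import EffectSpec, CellEffect


@pytest.fixture
def params():
    return SimParams()


@pytest.fixture
def quiet_params():
    return SimParams(noise_sd_uV=0.0)


@pytest.fixture
def tiny_design():
    return {("control", "vehicle"): 2, ("diabetic", "vehicle"): 2}


def make_sweep_frame(n_trials=3, dt=0.5, pre=5.0, post=20.0, animal="m1", eye="left",
                     lum=1.4, voltage_fn=None):
    """Small well-formed sweep table for I/O tests."""
    t = np.arange(-round(pre / dt), round(post / dt) + 1) * dt
    rows = []
    for trial in range(1, n_trials + 1):
        v = np.zeros_like(t) if voltage_fn is None else voltage_fn(t, trial)
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "eye": eye,
                    "luminance_log": lum,
                    "trial": trial,
                    "time_ms": t,
                    "voltage_uV": v,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture
def sweep_frame():
    return make_sweep_frame()
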