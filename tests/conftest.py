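import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from acinarloop import (
    InputSchedule,
    ModelParameters,
    Trajectory,
    get_preset,
    simulate,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def canine() -> ModelParameters:
    return get_preset("canine-default")


@pytest.fixture(scope="session")
def constant_drive_traj(canine) -> Trajectory:
    """Canine-default loop under a constant drive of 100 ACh-units/min."""
    return simulate(canine, InputSchedule.constant(100.0, 0.0, 500.0), (), (0.0, 500.0))


def make_synthetic_trajectory(
    params: ModelParameters,
    t: np.ndarray,
    S: np.ndarray,
    N: np.ndarray | None = None,
    B: np.ndarray | None = None,
    schedule: InputSchedule | None = None,
) -> Trajectory:
    """Hand-built trajectory with consistent derived columns, for exercising
    the assessment layer on exactly known series."""
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    N = np.zeros_like(t) if N is None else np.asarray(N, dtype=float)
    B = np.zeros_like(t) if B is None else np.asarray(B, dtype=float)
    frame = pd.DataFrame(
        {
            "t": t,
            "N": N,
            "B": B,
            "P": np.zeros_like(t),
            "S": S,
            "input_rate": np.zeros_like(t),
            "input_cum": np.zeros_like(t),
            "hydrolysis_rate": np.zeros_like(t),
            "hydrolyzed_cum": np.zeros_like(t),
            "bche_export_rate": params.F * S,
            "duct_export_rate": np.minimum(S, params.S_max),
            "overflow_rate": np.maximum(S - params.S_max, 0.0),
            "overflow_cum": np.zeros_like(t),
            "N_max_eff": np.full_like(t, params.N_max),
            "G_eff": np.full_like(t, params.G),
        }
    )
    return Trajectory(
        frame=frame,
        params=params,
        schedule=schedule if schedule is not None else InputSchedule.zero(),
    )
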