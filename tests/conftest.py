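import numpy as np
import pandas as pd
import pytest

from cloverpheno.design import Geometry, build_design
from cloverpheno.simulate import SimulationParams, simulate_trial
from cloverpheno.timeline import YEAR1_TIMELINE

# small trial: 20 accessions, (19 x 2) + 7 = 45 = 3 x 3 x 5 plots per field
SMALL_PANEL = 20
SMALL_GEOMETRY = Geometry(3, 3, 5)


def small_panel_ids():
    return ["Lemmon"] + [f"ACC{i:04d}" for i in range(1, SMALL_PANEL)]


@pytest.fixture(scope="session")
def small_design():
    return build_design(small_panel_ids(), SMALL_GEOMETRY, reps=2, control_reps=7, seed=42)


def small_params(seed=42, **overrides):
    defaults = dict(
        panel_size=SMALL_PANEL,
        geometry=(3, 3, 5),
        obs_doys={"CC": (165, 178, 256), "CH": (165, 178, 256), "CH_rpm": (166,), "CWSI": (206,)},
        fault_rate=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def small_trial(small_design):
    return simulate_trial(small_design, small_params(), YEAR1_TIMELINE)


@pytest.fixture(scope="session")
def small_table(small_trial):
    return small_trial.phenotypes
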