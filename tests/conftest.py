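import numpy as np
import pandas as pd
import pytest

from dielfit import (
    ConditionSpec,
    OccupancySimSpec,
    SimulationConfig,
    generate_expression,
    generate_occupancy,
)

UNIFORM_PHASES = [(z, 1 / 6) for z in (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)]


@pytest.fixture(scope="session")
def balanced_times():
    """6 ZT x 2 days x 3 replicates = 36 sample times (ZT mod 24)."""
    return np.tile(np.repeat([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 3), 2)


@pytest.fixture(scope="session")
def noiseless_tc():
    cfg = SimulationConfig(
        n_features=3,
        conditions=[ConditionSpec("control", 1.0, (0.5, 1.5),
                                  UNIFORM_PHASES)],
        noise_sd=0.0,
        seed=11,
    )
    return generate_expression(cfg)


@pytest.fixture(scope="session")
def noisy_tc():
    cfg = SimulationConfig(
        n_features=50,
        conditions=[ConditionSpec("control", 0.5, (0.5, 1.0), UNIFORM_PHASES)],
        noise_sd=0.2,
        seed=7,
    )
    return generate_expression(cfg)


@pytest.fixture(scope="session")
def null_occupancy():
    cfg = SimulationConfig(n_features=0, conditions=[ConditionSpec("wt")],
                           replicates_per_timepoint=1, n_days=2)
    spec = OccupancySimSpec(n_loci=400, noise_sd=0.2, seed=23, name="wt")
    return generate_occupancy(spec, cfg)


def occupancy_design(**kwargs):
    """Canonical ChIP design: 6 ZT x 2 days x 1 replicate = 12 samples."""
    defaults = dict(n_features=0, conditions=[ConditionSpec("occ")],
                    replicates_per_timepoint=1, n_days=2)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)
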