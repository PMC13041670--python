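import numpy as np
import pytest

from traffickit.simulate import (
    FlowSimConfig,
    PlantedEffect,
    ScreenSimConfig,
    simulate_flow_experiment,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """Two-plate screen with one strong planted hit and one toxic compound."""
    cfg = ScreenSimConfig(
        n_plates=2,
        seed=11,
        planted_hits=(PlantedEffect("C001-A3", "surface", mad_units=10.0),),
        toxic_compounds={"C001-A4": 0.1},
    )
    cells, plate_map, truth = simulate_screen(cfg)
    return cfg, cells, plate_map, truth


@pytest.fixture(scope="session")
def flow_experiment():
    """Default treated/vehicle flow experiment (compound effect preset)."""
    cfg = FlowSimConfig(seed=7)
    return cfg, simulate_flow_experiment(cfg)


@pytest.fixture(scope="session")
def clean_flow_config():
    """Noise-free flow config: identity spillover, no background, no spread."""
    return FlowSimConfig(
        n_events=50,
        n_replicates=1,
        event_cv=0.0,
        spillover=((1.0, 0.0), (0.0, 1.0)),
        autofluor_surface=0.0,
        autofluor_internal=0.0,
        background_surface=0.0,
        background_internal=0.0,
        background_cv=0.0,
        replicate_batch_cv=0.0,
        reporter_pos_fraction=1.0,
        reporter_cv=0.0,
        effect_preset="null",
        seed=3,
    )


def brute_force_robust_z(values, x):
    """Sort-based median / explicit MAD oracle for the robust z-score."""
    v = sorted(float(u) for u in values)
    n = len(v)
    med = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
    dev = sorted(abs(u - med) for u in v)
    mad = dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2])
    return (x - med) / (1.4826 * mad)


@pytest.fixture(scope="session")
def robust_z_oracle():
    return brute_force_robust_z
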