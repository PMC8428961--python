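import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from eelvkit.simkit import (
    LungConfig,
    PhantomConfig,
    default_fio2_schedule,
    generate_phantom,
    simulate_maneuver,
)


def maneuver_config(**overrides) -> LungConfig:
    """Noise-free default maneuver with plateaus long enough for steady state."""
    params = dict(
        eelv_ml=500.0,
        vt_ml=180.0,
        vd_airway_ml=30.0,
        rr_min=25.0,
        fio2_schedule=default_fio2_schedule(t_baseline_s=60.0, t_hold_s=150.0),
    )
    params.update(overrides)
    return LungConfig(**params)


def hold_for(config: LungConfig, n_time_constants: float = 12.0) -> list:
    """FiO2 schedule whose holds span ``n_time_constants`` of the washout."""
    vd = config.vd_airway_ml + config.vd_instr_ml
    tau_breaths = config.mixing_volume_ml / max(config.vt_ml - vd, 1.0)
    t_hold = max(120.0, n_time_constants * tau_breaths * 60.0 / config.rr_min)
    return default_fio2_schedule(t_baseline_s=60.0, t_hold_s=t_hold)


@pytest.fixture(scope="session")
def default_run():
    """One simulated maneuver shared by read-only tests."""
    cfg = maneuver_config()
    waveform, truth = simulate_maneuver(cfg)
    return cfg, waveform, truth


@pytest.fixture(scope="session")
def four_compartment_phantom():
    cfg = PhantomConfig(
        shape=(40, 30, 30),
        voxel_dims_mm=(2.0, 2.0, 2.0),
        regions=[(-950.0, 20.0), (-700.0, 100.0), (-300.0, 50.0), (0.0, 30.0)],
    )
    img, truth = generate_phantom(cfg)
    return cfg, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
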