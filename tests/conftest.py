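import numpy as np
import pytest

from skinrems.config import CohortConfig, KernelParams, PatchLayout


def tiny_layout() -> PatchLayout:
    return PatchLayout(frame_shape=(120, 160), patch_size=16, control_size=24)


def tiny_config(**overrides) -> CohortConfig:
    """Fast cohort: two groups, low resolution, kernel peaking on a frame time."""
    defaults = dict(
        group_sizes={"FEP": 4, "BD": 0, "SA": 0, "CS": 0, "HC": 4},
        layout=tiny_layout(),
        kernel=KernelParams(peak_time=270.0),  # = frame index 5 (4.5 min)
        seed=7,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def uniform_amplitudes(triple, groups=("FEP", "BD", "SA", "CS", "HC"), concentrations=(0.1, 0.01, 0.001)):
    """Same amplitude for every group and concentration (e.g. all-zero)."""
    return {g: {c: tuple(triple) for c in concentrations} for g in groups}


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def tiny_cohort():
    from skinrems.synthetic import generate_cohort

    cfg = tiny_config()
    return cfg, generate_cohort(cfg)
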