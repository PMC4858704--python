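import numpy as np
import pytest

from silkcoat.io_core import CoatingCondition
from silkcoat.oxygen import ChamberGeometry
from silkcoat.synthetic import ScenarioSpec


@pytest.fixture
def geometry() -> ChamberGeometry:
    """Default two-chamber rig: 2.75 cm^2 opening, 75 um film, 100 cm^3."""
    return ChamberGeometry(A_M_cm2=2.75, l_cm=0.0075, V_R_cm3=100.0)


@pytest.fixture
def condition() -> CoatingCondition:
    return CoatingCondition(dip_steps=4, annealing_hours=0, beta_sheet_pct=23.0, thickness_um=75.0)


def make_spec(condition, *, D=1e-6, D_B=0.02, seed=0, noiseless=False, **kw) -> ScenarioSpec:
    params = dict(
        condition=condition,
        true_D_eM_cm2_s=D,
        true_D_B_cm3_min=D_B,
        true_wvtr_g_m2_s=1e-3,
        true_beta_fraction=0.36,
        respiration_ml_kg_h=18.0,
        dehydration_k_per_day=0.1,
        seed=seed,
    )
    if noiseless:
        params.update(
            oxygen_noise_sd=0.0,
            cup_noise_sd_g=0.0,
            spectrum_noise_sd=0.0,
            headspace_noise_sd_pct=0.0,
            weight_noise_sd_g=0.0,
            force_noise_sd_n=0.0,
        )
    params.update(kw)
    return ScenarioSpec(**params)


@pytest.fixture
def noiseless_spec(condition) -> ScenarioSpec:
    return make_spec(condition, noiseless=True)
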