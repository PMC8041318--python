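import numpy as np
import pytest

from folatekin import mechanism as mech


@pytest.fixture
def mixed_params() -> mech.MechanismParams:
    """Mixed-type truth: apparent Ki = 40 uM, Ki' = 44 uM at d = 140 uM."""
    return mech.MechanismParams.from_apparent(
        km_app=20.0, vmax=1.0, ki=40.0, ki_prime=44.0, interface_share=0.4
    )


@pytest.fixture
def competitive_params() -> mech.MechanismParams:
    """Competitive truth (interface binding only): apparent Ki = 90 uM."""
    return mech.MechanismParams.from_apparent(
        km_app=20.0, vmax=1.0, ki=90.0, interface_share=1.0 - 1e-12
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260917)


def random_params(rng: np.random.Generator) -> mech.MechanismParams:
    """Random positive mechanism parameters over a broad log range."""

    def draw(lo=-1.0, hi=3.0):
        return float(10.0 ** rng.uniform(lo, hi))

    return mech.MechanismParams(
        K1=draw(), K2=draw(), K3=draw(), K4=draw(), K5=draw(), K6=draw(),
        Vmax=float(10.0 ** rng.uniform(-1, 1)),
    )


def random_condition(rng: np.random.Generator) -> mech.AssayCondition:
    return mech.AssayCondition(
        s=float(10.0 ** rng.uniform(-1, 2.5)),
        d=float(10.0 ** rng.uniform(0.5, 2.5)),
        i=float(10.0 ** rng.uniform(-1, 2.5)),
    )
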