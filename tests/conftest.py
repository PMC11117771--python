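import numpy as np
import pytest

from acanet.neuron import ACANParams, preset_params


@pytest.fixture
def type_a_64() -> ACANParams:
    return preset_params("a", 64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_params(rng: np.random.Generator) -> ACANParams:
    """Random but valid parameter set for fuzzing (not necessarily a preset)."""
    R = int(rng.choice([4, 8, 16, 32, 64]))
    return ACANParams(
        gamma1=float(rng.uniform(-8, 8)),
        gamma2=float(rng.uniform(-1, 1)),
        gamma3=float(rng.uniform(-1, 1)),
        gamma4=float(rng.uniform(-6, 6)),
        gamma5=float(rng.uniform(-0.5, 0.5)),
        lam=float(rng.choice([1.0, R / 2, R])),
        mu=float(rng.uniform(-4, 4)),
        rho1=float(rng.uniform(0, 0.99)),
        rho2=float(rng.uniform(-0.5, 0.5)),
        N=R, M=R, K=R, J=R,
        ticks_per_step=int(rng.integers(1, R + 1)),
    )
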