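import numpy as np
import pytest

from legatos.kinetics import KineticParams, VascularInputFunction
from legatos.phantom import PhantomConfig, build_phantom
from legatos.simulation import NoiseSpec, PopulationVIFModel


@pytest.fixture(scope="session")
def population_vif() -> VascularInputFunction:
    """Population plasma input sampled on a 1.46 s grid over 751 s."""
    model = PopulationVIFModel()
    times = np.arange(0.0, 751.0, 1.46)
    return model.as_vif(times)


@pytest.fixture(scope="session")
def vs_truth() -> KineticParams:
    """Reference vestibular-schwannoma kinetics used throughout."""
    return KineticParams(ktrans=0.26, vp=0.07, ve=0.5)


def small_phantom_config(noiseless: bool, seed: int = 1) -> PhantomConfig:
    if noiseless:
        nz_ht = NoiseSpec(nl=0.0, baseline_mean=371.1)
        nz_hs = NoiseSpec(nl=0.0, baseline_mean=84.4)
        return PhantomConfig(scale=0.12, seed=seed, noise_ht=nz_ht, noise_hs=nz_hs)
    return PhantomConfig(scale=0.12, seed=seed)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return build_phantom(small_phantom_config(noiseless=True))


@pytest.fixture(scope="session")
def noisy_phantom():
    return build_phantom(small_phantom_config(noiseless=False))
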