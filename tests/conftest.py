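import numpy as np
import pytest

from asgard_ogt import FluorescenceProfile, PeakParams, SimulationConfig, simulate_binding_profile


@pytest.fixture
def typical_params() -> PeakParams:
    return PeakParams(f0=100.0, f_star=500.0, t_star=50.0, s_l=10.0, s_r=20.0, w=5.0)


@pytest.fixture
def noiseless_profile(typical_params) -> FluorescenceProfile:
    cfg = SimulationConfig(noise_sd=0.0, true_params=typical_params, seed=0)
    profile, _ = simulate_binding_profile(cfg, protein_id="noiseless")
    return profile


@pytest.fixture
def noisy_profile() -> FluorescenceProfile:
    cfg = SimulationConfig(
        noise_sd=0.02,
        true_params=PeakParams(f0=100.0, f_star=1000.0, t_star=52.9, s_l=8.0, s_r=12.0, w=5.0),
        seed=42,
    )
    profile, _ = simulate_binding_profile(cfg, protein_id="noisy")
    return profile


@pytest.fixture
def flat_profile() -> FluorescenceProfile:
    temps = np.arange(0.0, 101.0, 10.0)
    return FluorescenceProfile(
        protein_id="flat",
        temperatures=temps,
        fluorescence=np.full((3, temps.size), 250.0),
        assay_kind="binding",
    )
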