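import numpy as np
import pytest

from hcmecg.synthetic_data import make_archetype_library


@pytest.fixture(scope="session")
def archetypes():
    """Name -> archetype map of the four built-in phenotypes."""
    return {a.name: a for a in make_archetype_library()}


@pytest.fixture(scope="session")
def small_cohort():
    """Small noiseless-ish cohort shared across tests (8 per group)."""
    from hcmecg.synthetic_data import synthesize_cohort
    return synthesize_cohort({"1A": 8, "1B": 8, "2": 8, "3": 8},
                             variability=0.05, noise_sd=0.02, seed=11)


@pytest.fixture(scope="session")
def baseline_cable():
    """Uniform-cable simulation reused by several conduction tests."""
    from hcmecg.simulation import TissueConfig, simulate_cable
    cfg = TissueConfig(diffusion_mm2_per_ms=0.3)
    return simulate_cable(cfg, duration_ms=250.0)


@pytest.fixture(scope="session")
def scenario_results():
    """All five mechanism scenarios, run once per session."""
    from hcmecg.simulation import SCENARIOS, run_scenario
    out = {}
    for name in SCENARIOS:
        out[name] = run_scenario(name)
    return out


def rng(seed=0):
    return np.random.default_rng(seed)
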