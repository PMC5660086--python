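import warnings

import pytest

from sumoremnant.conjugates import ModifierProtein
from sumoremnant.simulate import SimConfig, plant_sites, simulate_proteome, simulate_psms

# pyteomics warns about proton-containing compositions on import-time constants
warnings.filterwarnings("ignore", message="Charge is not specified")


@pytest.fixture(scope="session")
def toy_sumo():
    """SUMO-like modifier: trypsin leaves TGG, WaLP leaves GG."""
    return ModifierProtein("toySUMO", "MQKARTGG")


@pytest.fixture(scope="session")
def toy_ub():
    """Ub-like modifier: trypsin leaves GG."""
    return ModifierProtein("toyUb", "MRGG")


@pytest.fixture(scope="session")
def sim_experiment():
    """One seeded synthetic experiment shared across tests (read-only)."""
    cfg = SimConfig(seed=11, n_proteins=40, n_sites=60)
    proteome = simulate_proteome(cfg)
    proteome, truth = plant_sites(proteome, cfg)
    sim = simulate_psms(proteome, truth, cfg)
    return cfg, proteome, truth, sim
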