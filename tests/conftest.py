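import numpy as np
import pytest

from rhpkit import SimulationConfig, default_system, simulate_batch


@pytest.fixture(scope="session")
def system4():
    """4-monomer methacrylate reference system, 50:25:20:5, all r = 1."""
    return default_system()


@pytest.fixture(scope="session")
def default_batch(system4):
    """The standard production batch: NC 15000, DP 100, conversion 0.5, PDI 1.2."""
    cfg = SimulationConfig(system=system4, nc=15000, dp_target=100.0,
                           conversion_target=0.5, pdi_target=1.2, seed=1234)
    return simulate_batch(cfg)


@pytest.fixture(scope="session")
def monodisperse_batch(system4):
    """Ideal-statistics batch with every chain exactly DP 100 (binomial compositions)."""
    cfg = SimulationConfig(system=system4, nc=3000, dp_target=100.0,
                           conversion_target=0.5, pdi_target=1.0, seed=77)
    return simulate_batch(cfg)


@pytest.fixture(scope="session")
def small_batch(system4):
    cfg = SimulationConfig(system=system4, nc=200, dp_target=60.0,
                           conversion_target=0.5, pdi_target=1.15, seed=5)
    return simulate_batch(cfg)
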