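import numpy as np
import pytest

import decoysim as ds


@pytest.fixture(scope="session")
def geometric20():
    """Geometric burst distribution with mean 20 (the standard figure setting)."""
    return ds.make_geometric_burst(20.0)


@pytest.fixture(scope="session")
def fig2_model(geometric20):
    """Bursty TF without decoys: k_x=10/hr, <B>=20, gamma_f=1/hr (mean 200)."""
    return ds.TFDecoyModel(k_x=10.0, burst=geometric20, gamma_f=1.0, gamma_b=0.0)


@pytest.fixture(scope="session")
def tiny_decoy_model():
    """Non-bursty TF with two decoy sites, small enough for the CME oracle."""
    return ds.TFDecoyModel(
        k_x=1.0, burst=ds.BurstDistribution.degenerate(1),
        gamma_f=1.0, gamma_b=1.0,
        decoys=(ds.DecoySpecies(N=2, k_b=10.0, k_u=10.0),))
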