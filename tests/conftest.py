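import numpy as np
import pytest

from bilayerlab.types import DepthDistribution, DepthGroup, LamellarModelParams


@pytest.fixture
def depth_c2c3():
    """Depth distribution with a ligand centered between C2 and C3."""
    return DepthDistribution([
        DepthGroup("CH3", 0.00, 0.30, 6, 15.0),
        DepthGroup("(CH2)n", 0.60, 0.35, 24, 14.0),
        DepthGroup("CH2C=", 0.95, 0.30, 4, 14.0),
        DepthGroup("C3", 1.25, 0.25, 4, 14.0),
        DepthGroup("C2", 1.35, 0.25, 4, 14.0),
        DepthGroup("G1", 1.55, 0.25, 2, 14.0),
        DepthGroup("gamma", 2.00, 0.25, 9, 15.0),
        DepthGroup("III", 1.28, 0.30, 4, 13.0),
        DepthGroup("IV", 1.32, 0.30, 4, 13.0),
    ])


@pytest.fixture
def dmpc_gel_params():
    """Electron-density model parameters styled after gel-phase DMPC."""
    return LamellarModelParams(d=64.0, zH=19.5, sigmaH=3.0, sigmaC=5.4,
                               rho_ratio=-1.0, n_lamellae=25, eta=0.0)


@pytest.fixture
def saxd_grid():
    return np.linspace(0.0075, 0.07, 640)
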