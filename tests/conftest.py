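import numpy as np
import pytest

from specbind import GroundTruth

#: amplitude-weighted averages of the three published decay rows, computed
#: from their printed components (frozen oracle values)
TABLE2_ROWS = [
    ((0.362, 0.062, 0.576), (3.102, 0.604, 6.796), 5.073),
    ((0.403, 0.050, 0.547), (2.926, 0.440, 6.662), 4.846),
    ((0.426, 0.059, 0.515), (2.962, 0.544, 6.648), 4.717),
]

#: published Stern-Volmer constants (M^-1) and binding constants by T (K)
KSV_BY_T = {298.0: 6.702e4, 304.0: 5.981e4, 310.0: 5.664e4}
K_BY_T = {298.0: 6.826e4, 304.0: 3.618e4, 310.0: 2.334e4}


@pytest.fixture
def noiseless_truth():
    return GroundTruth(noise_sigma=0.0, seed=0)


@pytest.fixture
def noisy_truth():
    return GroundTruth(noise_sigma=0.01, seed=42)


@pytest.fixture
def conc_grid_uM():
    return np.arange(10) * 1e-6
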