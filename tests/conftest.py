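import numpy as np
import pytest

from gestaltmask.em_mask import EMConfig, run_em
from gestaltmask.synthetic import feature_maps_from_field


@pytest.fixture(scope="session")
def random_field_traces():
    """200 EM runs on seeded isotropic orientation fields (shared by the
    descent and bounds checks)."""
    out = []
    rng = np.random.default_rng(20240915)
    for _ in range(200):
        theta = rng.uniform(-90.0, 90.0, size=(41, 41))
        maps = feature_maps_from_field(theta)
        target = (int(rng.integers(10, 31)), int(rng.integers(10, 31)))
        out.append(run_em(target, maps, EMConfig()))
    return out
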