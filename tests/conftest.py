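import warnings

import numpy as np
import pytest

import hsunmix as h


@pytest.fixture(autouse=True)
def _quiet_clip_warnings():
    # the 30 dB generator clips ~3% of entries at zero by design; the
    # warning is informative in interactive use but noise in the suite
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="gaussian noise clipped")
        yield


@pytest.fixture(scope="session")
def default_gt():
    """Ground truth under the frozen default conditions, seed 0."""
    return h.default_ground_truth(seed=0)


@pytest.fixture(scope="session")
def default_cube(default_gt):
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="gaussian noise clipped")
        return h.make_cube(default_gt)


@pytest.fixture(scope="session")
def default_dm(default_cube):
    return h.cube_to_matrix(default_cube)


@pytest.fixture(scope="session")
def default_model(default_dm):
    """A converged HALS fit of the default cube at the true rank."""
    cfg = h.UnmixingConfig(k=3, seed=0, solver="hals", init="nndsvd", tol=1e-9, max_iter=500)
    return h.nmf(default_dm, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
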