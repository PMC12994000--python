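import numpy as np
import pytest

from dqnencode.design import AcquisitionSpec, DesignMatrix, assemble_design
from dqnencode.encoding import EncodingConfig
from dqnencode.synth import synth_layer_features


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_acq():
    return AcquisitionSpec(n_volumes=150)


def make_session_designs(
    n_sessions=5, n_predictors=10, n_volumes=200, seed=0, iid=False
):
    """Per-session standardized designs: iid Gaussian or pipeline-built."""
    rng = np.random.default_rng(seed)
    designs = []
    if iid:
        for _ in range(n_sessions):
            x = rng.standard_normal((n_predictors, n_volumes))
            x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
            designs.append(DesignMatrix(x, ["conv1"] * n_predictors, True))
        return designs
    acq = AcquisitionSpec(n_volumes=n_volumes)
    n_stim = int(np.ceil(acq.n_volumes * acq.tr_seconds * 45)) + 45
    sessions = [
        synth_layer_features(n_stim, n_predictors, seed=int(rng.integers(2 ** 31)),
                             layers=("conv1",))
        for _ in range(n_sessions)
    ]
    return [
        assemble_design(f, "conv1", acq, extra_sessions=[g for g in sessions if g is not f])
        for f in sessions
    ]


@pytest.fixture(scope="session")
def iid_designs():
    return make_session_designs(iid=True, seed=11)


@pytest.fixture(scope="session")
def fast_cfg():
    return EncodingConfig()
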