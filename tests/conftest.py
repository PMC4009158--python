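import numpy as np
import pytest

import ricewave as rw


@pytest.fixture(scope="session")
def phantom128():
    return rw.make_phantom(rw.default_phantom_spec((128, 128)))


@pytest.fixture(scope="session")
def phantom64():
    return rw.make_phantom(rw.default_phantom_spec((64, 64)))


@pytest.fixture(scope="session")
def fitted_params():
    """Bias-inverse constants fitted on the standard grid (shared: the fit
    takes a couple of seconds)."""
    return rw.fit_inverse_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_tissue_map(phantom64):
    """Two-compartment tissue map on the 64x64 phantom: outer ring decaying
    at 4/s, inner structures at 14/s, baseline 2 inside tissue only (the
    background corner stays zero for noise estimation)."""
    clean = phantom64
    inner = clean >= 66.0
    outer = (clean > 0) & ~inner
    tissue = rw.TissueMap(
        baseline=np.where(clean > 0, 2.0, 0.0),
        components=(
            (np.where(outer, 40.0, 0.0), np.where(outer, 4.0, 0.0)),
            (np.where(inner, 40.0, 0.0), np.where(inner, 14.0, 0.0)),
        ),
    )
    return tissue, {"outer": outer, "inner": inner}, {"outer": 4.0, "inner": 14.0}
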