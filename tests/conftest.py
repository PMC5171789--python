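import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import settings

import pbm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim() -> pbm.SimulationResult:
    """A small planted-state study: 3 subjects x 300 points x 20 ROIs, 4 states."""
    return pbm.simulate(
        pbm.SimulationSpec(
            n_subjects=3, n_rois=20, n_timepoints=300, k_true=4, seed=20_001
        )
    )


@pytest.fixture(scope="session")
def fitted_small(small_sim) -> pbm.PBMResults:
    """The point-based model fitted on the small study (no band-pass: the
    synthetic data carry no drift, and filtering would blur the fast planted
    state switches)."""
    model = pbm.PointBasedModel(
        small_sim.timeseries,
        atlas=small_sim.atlas,
        motion=small_sim.motion,
        k=4,
        band=None,
    )
    return model.fit(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
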