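import numpy as np
import pytest

from rotsaf import (
    BeamModel,
    RotationSequence,
    SliceStack,
    TransducerSpec,
    make_grid,
)


@pytest.fixture(scope="session")
def spec() -> TransducerSpec:
    return TransducerSpec()


@pytest.fixture(scope="session")
def beam(spec) -> BeamModel:
    return BeamModel.from_spec(spec)


@pytest.fixture(scope="session")
def eight_angles() -> RotationSequence:
    return RotationSequence(np.arange(0.0, 180.0, 22.5), 22.5)


def random_envelope_stack(spec, seq, n_axial=1600, seed=0):
    """Random nonnegative slice data on the probe's grid, for oracle tests."""
    grid = make_grid(spec, n_axial)
    rng = np.random.default_rng(seed)
    data = rng.random((len(seq), grid.ni, grid.nj))
    return SliceStack(data, "envelope", grid, seq, spec)
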