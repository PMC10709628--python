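import numpy as np
import pytest

from starchir import synth
from starchir.spectra import WavenumberGrid


@pytest.fixture(scope="session")
def full_grid() -> WavenumberGrid:
    """The default full mid-IR acquisition grid, 800-4000 cm^-1 at 4 cm^-1."""
    return synth.default_grid()


@pytest.fixture(scope="session")
def signatures16():
    """The default 16-class reference roster with frozen variability."""
    return synth.generate_class_signatures(16, seed=101)


@pytest.fixture(scope="session")
def small_library(full_grid):
    """A compact 6-class x 8-replicate library for fast model tests."""
    sigs = synth.generate_class_signatures(16, seed=101)[:6]
    return synth.generate_reference_library(
        sigs, reps_per_class=8, grid=full_grid, seed=202
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
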