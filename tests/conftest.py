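import numpy as np
import pytest

from protflux import FluxDesign, FluxSimParams, OPLSimParams, gen_flux_table, normalize_lanes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design(rng):
    """A random 2-per-group flux design (small enough to enumerate)."""
    vals = rng.lognormal(0.0, 0.3, 8)
    return FluxDesign(
        treated_plus=vals[0:2] * 2.0,
        treated_minus=vals[2:4],
        control_plus=vals[4:6] * 3.0,
        control_minus=vals[6:8],
    )


@pytest.fixture
def small_opl_params():
    """A quick, low-density photoconversion simulation."""
    return OPLSimParams(n_cells=10, field_shape=(256, 256), seed=42)
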