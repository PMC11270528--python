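import numpy as np
import pytest

from jressr.core_io import Axis, Spectrum2D, default_f1_axis, default_f2_axis
from jressr.simulate import (
    Metabolite,
    Multiplet,
    default_library,
    render_metabolite,
    scaled_linewidths,
)


@pytest.fixture(scope="session")
def demo_axes():
    """Reduced 64 x 1024 grid spanning the reference physical ranges."""
    return default_f1_axis(64), default_f2_axis(1024)


@pytest.fixture(scope="session")
def demo_library():
    lw1, lw2 = scaled_linewidths(64, 1024)
    return default_library(40, lw_f1=lw1, lw_f2=lw2)


@pytest.fixture(scope="session")
def doublet_metabolite():
    """Single 7 Hz doublet, linewidths suitable for the 64 x 1024 grid."""
    lw1, lw2 = scaled_linewidths(64, 1024)
    return Metabolite(
        "doublet7",
        (Multiplet(delta=4.0, couplings=(7.0,), proton_weight=2.0,
                   lw_f1=lw1, lw_f2=lw2),),
    )


@pytest.fixture(scope="session")
def rendered_doublet(doublet_metabolite, demo_axes):
    return render_metabolite(doublet_metabolite, *demo_axes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_spectrum(rng):
    """Small random non-negative spectrum on a 8 x 16 grid."""
    f1 = Axis(8, -4.0, 4.0, "Hz")
    f2 = Axis(16, 0.0, 8.0, "ppm")
    return Spectrum2D(np.abs(rng.normal(1.0, 0.5, size=(8, 16))), f1, f2)
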