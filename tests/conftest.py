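"""Shared fixtures: geometry, detector models, response matrices, streams.

Expensive simulated objects are session-scoped and shared between test
modules; every random source is seeded for reproducibility.
"""

import numpy as np
import pytest

from cztpet.detector import DetectorModel
from cztpet.geometry import SystemGeometry
from cztpet.phantoms import PhantomSpec, make_phantom
from cztpet.rejection import CAT_COMPTON_BOTH, CAT_COMPTON_ONE, classify_events
from cztpet.response import build_response_matrix
from cztpet.simulate import (
    concatenate_listmode,
    random_coincidence_stream,
    simulate_coincidences,
)


@pytest.fixture(scope="session")
def geometry():
    return SystemGeometry.nominal()


@pytest.fixture(scope="session")
def detector():
    return DetectorModel()


@pytest.fixture(scope="session")
def response_F():
    """Default-blur, Doppler-on response matrix, coarsened test binning.

    Bins are widened (2 keV / 2 deg / 1 mm) so the desk-scale event count
    fills the matrix densely enough for stable slice statistics.
    """
    rng = np.random.default_rng(101)
    return build_response_matrix(0, rng=rng, target_events=250_000,
                                 de=2.0, dtheta=2.0, dd2=1.0)


@pytest.fixture(scope="session")
def response_ideal():
    """Blur-free, Doppler-free response matrix (exact kinematics)."""
    rng = np.random.default_rng(102)
    return build_response_matrix(0, rng=rng, target_events=150_000,
                                 model=DetectorModel.ideal(), doppler=False,
                                 dd2=2.0)


@pytest.fixture(scope="session")
def hotrod_phantom():
    return make_phantom(PhantomSpec("hot-rod"), 0.175)


@pytest.fixture(scope="session")
def mixed_stream(geometry, hotrod_phantom):
    """True + random coincidences from the hot-rod phantom (labelled)."""
    rng = np.random.default_rng(103)
    trues = simulate_coincidences(hotrod_phantom, geometry, duration=0.35,
                                  rng=rng)
    trues = trues.select(~trues.truth["is_random"])
    randoms = random_coincidence_stream(hotrod_phantom, geometry, 6000, rng)
    return concatenate_listmode([trues, randoms])


@pytest.fixture(scope="session")
def compton_stream(mixed_stream):
    """The in-window Compton-containing substream of the mixed stream."""
    cat, in_win = classify_events(mixed_stream)
    keep = np.isin(cat, (CAT_COMPTON_ONE, CAT_COMPTON_BOTH)) & in_win
    return mixed_stream.select(keep)
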