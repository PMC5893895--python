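import numpy as np
import pytest

from tonerec import (
    GlissandoSpec,
    RQEConfig,
    detect_peaks,
    rqe_scan,
    synth_glissando_mix,
)

#: 10-value example series used throughout the recurrence unit tests.
WORKED_SERIES = [7, 8, 10, 15, 6, 7, 9, 11, 10, 8]

#: Reference Euclidean distances between the 8 epochs of WORKED_SERIES
#: embedded with m=3, L=1; keys are 1-based (row, col), row > col.
WORKED_DISTANCES = {
    (2, 1): 5.477226,
    (3, 1): 8.602325, (3, 2): 10.48809,
    (4, 1): 8.774964, (4, 2): 11.35782, (4, 3): 10.34408,
    (5, 1): 1.732051, (5, 2): 7.0, (5, 3): 9.433981, (5, 4): 9.273618,
    (6, 1): 1.41421, (6, 2): 4.242641, (6, 3): 8.3666, (6, 4): 9.433981,
    (6, 5): 3.0,
    (7, 1): 3.605551, (7, 2): 5.196152, (7, 3): 5.744563, (7, 4): 8.3666,
    (7, 5): 5.09902, (7, 6): 3.0,
    (8, 1): 4.898979, (8, 2): 7.615773, (8, 3): 5.477226, (8, 4): 5.744563,
    (8, 5): 5.91608, (8, 6): 5.09902, (8, 7): 3.0,
}


@pytest.fixture
def worked_series():
    return list(WORKED_SERIES)


@pytest.fixture
def worked_distances():
    return dict(WORKED_DISTANCES)


@pytest.fixture(scope="session")
def glissando_signal():
    return synth_glissando_mix(GlissandoSpec())


@pytest.fixture(scope="session")
def default_profile(glissando_signal):
    return rqe_scan(glissando_signal, RQEConfig())


@pytest.fixture(scope="session")
def default_peaks(default_profile):
    return detect_peaks(default_profile)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180404)
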