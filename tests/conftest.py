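import numpy as np
import pytest

from protoendo.shapes import (
    AxisymShape,
    cap_inverted_sphere,
    sphere_shape,
    spheroid_shape,
)


@pytest.fixture(scope="session")
def unit_sphere():
    return sphere_shape(1.0, 256)


@pytest.fixture(scope="session")
def prolate_211():
    """Prolate spheroid, polar semi-axis 2 um, equatorial 1 um."""
    return spheroid_shape(2.0, 1.0, 256)


@pytest.fixture(scope="session")
def oblate_112():
    """Oblate spheroid, polar semi-axis 1 um, equatorial 2 um."""
    return spheroid_shape(1.0, 2.0, 256)


@pytest.fixture(scope="session")
def stomatocyte_fixture():
    """Unit sphere with a 0.6R spherical-cap inversion at one pole."""
    return cap_inverted_sphere(1.0, 0.6, 256)


def spheroid_closed_forms(c, a):
    """Closed-form (area, volume) of a spheroid with polar semi-axis c
    and equatorial semi-axis a (the independent oracle)."""
    V = 4.0 / 3.0 * np.pi * a ** 2 * c
    if np.isclose(a, c):
        return 4 * np.pi * a ** 2, V
    if c > a:  # prolate
        e = np.sqrt(1 - (a / c) ** 2)
        A = 2 * np.pi * a ** 2 * (1 + (c / a) / e * np.arcsin(e))
    else:  # oblate
        e = np.sqrt(1 - (c / a) ** 2)
        A = 2 * np.pi * a ** 2 * (1 + (1 - e ** 2) / e * np.arctanh(e))
    return A, V


@pytest.fixture(scope="session")
def count_table():
    from protoendo.synth import CountGeneratorParams, gen_counts

    return gen_counts(CountGeneratorParams(
        replicates=5, vesicles_per_replicate=200, seed=11))
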