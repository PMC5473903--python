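"""Shared fixtures: probe geometry, Golay codec objects, and the
(expensive) full-resolution time-of-flight grid."""

import numpy as np
import pytest

from needletrack import (
    ProbeGeometry,
    encode,
    generate_golay_pair,
    make_base_pulse,
    precompute_tof_grid,
)


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def pair():
    return generate_golay_pair(32)


@pytest.fixture(scope="session")
def base_pulse():
    return make_base_pulse()


@pytest.fixture(scope="session")
def excitations(pair, base_pulse):
    return (
        encode(pair.code_a, base_pulse, kind="golay_a"),
        encode(pair.code_b, base_pulse, kind="golay_b"),
    )


@pytest.fixture(scope="session")
def grid(geometry):
    """Full 0.025 mm TOF grid (X −20..20, Z 0..80), shared across tests."""
    return precompute_tof_grid(geometry)


def _snr_test_images(geometry, peak=10.0, region_sd=1.0, n_samples=4000):
    """Images with a known peak and a ±1 checkerboard (sd exactly 1,
    scaled) inside the default SNR noise rectangle."""
    from needletrack import TrackingImage

    fs, c = 1.0e8, 1540.0
    images = []
    v = np.arange(n_samples) / fs * c * 1e3
    region_rows = np.flatnonzero(np.abs(v - 10.0) <= 10.0)
    y = geometry.row_lateral_positions("side1")
    region_cols = np.flatnonzero(np.abs(y - 9.5) <= 9.5)
    for k in range(4):
        amp = np.zeros((n_samples, 32))
        patch = np.indices((region_rows.size, region_cols.size)).sum(axis=0) % 2
        amp[np.ix_(region_rows, region_cols)] = (2 * patch - 1) * region_sd
        amp[3000, 5] = peak
        images.append(TrackingImage(k + 1, amp, fs, c))
    return images


@pytest.fixture(scope="session")
def snr_image_factory(geometry):
    def factory(**kwargs):
        return _snr_test_images(geometry, **kwargs)

    return factory


@pytest.fixture(scope="session")
def small_grid(geometry):
    """Reduced grid for search-equivalence and fast localiser tests."""
    return precompute_tof_grid(
        geometry, x_range=(-10.0, 10.0), z_range=(10.0, 50.0), spacing=0.5
    )
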