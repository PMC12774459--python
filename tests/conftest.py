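import numpy as np
import pytest

from ermquant import ScanGeometry


@pytest.fixture
def geometry():
    """Default device geometry: 768x496 B-scans, 496x496 en face, 25 scans."""
    return ScanGeometry()


@pytest.fixture
def small_geometry():
    """Tiny geometry for brute-force comparisons."""
    return ScanGeometry(
        bscan_width=48,
        bscan_height=24,
        enface_width=16,
        enface_height=16,
        n_scans_per_orientation=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_small_geometry(rng):
    size = int(rng.integers(8, 33))
    return ScanGeometry(
        bscan_width=int(rng.integers(size, 3 * size + 1)),
        bscan_height=int(rng.integers(8, 64)),
        enface_width=size,
        enface_height=size,
        n_scans_per_orientation=int(rng.integers(1, 5)),
    )
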