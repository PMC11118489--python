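import numpy as np
import pytest

from langlat import build_atlas
from langlat.synth import GroupSpec, make_block_design, planted_amplitudes, simulate_localizer_run


@pytest.fixture(scope="session")
def small_atlas():
    """24x28x24 grid, 60-voxel parcels — the workhorse test atlas."""
    return build_atlas((24, 28, 24), 60, seed=1)


@pytest.fixture(scope="session")
def tiny_atlas():
    """20x24x20 grid, 50-voxel parcels — for replicate-heavy simulations."""
    return build_atlas((20, 24, 20), 50, seed=2)


@pytest.fixture(scope="session")
def events4():
    """Four blocks per condition, 18 s blocks, TR 2 s (84 volumes)."""
    return make_block_design(4, tr_seconds=2.0)


@pytest.fixture(scope="session")
def events3():
    """Three blocks per condition (66 volumes at TR 2 s)."""
    return make_block_design(3, tr_seconds=2.0)


@pytest.fixture(scope="session")
def noiseless_symmetric_runs(small_atlas, events4):
    """Two noiseless runs of a perfectly hemispherically symmetric subject."""
    group = GroupSpec(
        "adult", 1, psc_language=1.2, psc_control=0.4, lateral_bias=1.0, noise_sd=0.0, outlier_rate=0.0
    )
    rng = np.random.default_rng(5)
    amps = planted_amplitudes(group, small_atlas, rng)
    return [
        simulate_localizer_run(group, small_atlas, events4, rng, amplitudes=amps) for _ in range(2)
    ]
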