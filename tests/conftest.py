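import numpy as np
import pytest

from radsurv.volume_io import DiscreteVOI, SegmentationMask, VolumeGrid


@pytest.fixture
def small_phantom():
    """Deterministic GRF-textured ellipsoid phantom on a 32-cube grid."""
    from radsurv.synthetic_data import PhantomSpec, generate_phantom

    spec = PhantomSpec(
        shape=(32, 32, 32), semi_axes=(10.0, 8.0, 6.0), texture="grf", seed=7
    )
    return generate_phantom(spec)


@pytest.fixture
def cube_volume():
    """8x8x8 volume of iid intensities with a centered 4-cube mask."""
    rng = np.random.default_rng(11)
    vals = rng.uniform(0, 100, (8, 8, 8))
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[2:6, 2:6, 2:6] = True
    return VolumeGrid(vals), SegmentationMask(mask)


def random_dvoi(seed: int, shape=(5, 5, 5), n_bins=32, mask_p=0.85) -> DiscreteVOI:
    """Random discrete VOI with an irregular mask (utility, not a fixture)."""
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_bins + 1, size=shape).astype(np.int32)
    inside = rng.random(shape) < mask_p
    if not inside.any():
        inside[tuple(s // 2 for s in shape)] = True
    levels = np.where(inside, levels, 0).astype(np.int32)
    return DiscreteVOI(levels, inside, n_bins, (0.0, 1.0))
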