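import numpy as np
import pytest

from ptxshim.fieldsim import (
    ChannelFieldSlice,
    CoilArraySpec,
    PhantomSpec,
    RegionMask,
    simulate_channel_fields,
)
from ptxshim.shimcore import TargetMap


@pytest.fixture(scope="session")
def small_volume():
    """A deterministic 8-channel 48x48 volume with 3 slices."""
    coils = CoilArraySpec.for_grid((48, 48))
    phantom = PhantomSpec.for_grid((48, 48), noise_level=0.05)
    return simulate_channel_fields(coils, phantom, n_slices=3, seed=11)


@pytest.fixture(scope="session")
def small_slice(small_volume):
    """(fields, mask, uniform target) for the central slice."""
    fields = small_volume.slices[1]
    mask = small_volume.masks[1]
    return fields, mask, TargetMap.uniform(fields.grid_shape)


def random_system(rng: np.random.Generator, n_voxels: int, n_channels: int):
    """A random tiny shimming problem as (fields, mask, target)."""
    A = rng.standard_normal((n_voxels, n_channels)) + 1j * rng.standard_normal(
        (n_voxels, n_channels)
    )
    fields = ChannelFieldSlice(np.ascontiguousarray(A.T.reshape(n_channels, 1, n_voxels)))
    mask = RegionMask(np.ones((1, n_voxels), dtype=bool))
    target = TargetMap.uniform((1, n_voxels))
    return fields, mask, target
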