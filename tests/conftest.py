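import numpy as np
import pytest

from chromadist import DEFAULT_VOXEL_SIZE_NM, SpotCandidate, render_spots


@pytest.fixture
def voxel_size():
    return DEFAULT_VOXEL_SIZE_NM


@pytest.fixture
def spot_stack_factory(voxel_size):
    """Render a stack with spots at the given physical positions."""

    def _make(
        positions_nm,
        shape=(16, 64, 64),
        sigma_xy_nm=130.0,
        sigma_z_nm=300.0,
        amplitude=1000.0,
        background=100.0,
        noise_model="none",
        seed=0,
    ):
        return render_spots(
            np.asarray(positions_nm, dtype=float),
            shape=shape,
            voxel_size_nm=voxel_size,
            sigma_xy_nm=sigma_xy_nm,
            sigma_z_nm=sigma_z_nm,
            amplitude=amplitude,
            background=background,
            noise_model=noise_model,
            seed=seed,
        )

    return _make


@pytest.fixture
def candidate_at():
    def _make(iz, iy, ix, response=1.0, raw=1000.0):
        return SpotCandidate(index=(iz, iy, ix), response=response, raw_intensity=raw)

    return _make
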