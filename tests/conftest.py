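import numpy as np
import pytest

from zshim import AcquisitionParams, ZShimGrid
from zshim import sim


@pytest.fixture
def grid21() -> ZShimGrid:
    return ZShimGrid(n_steps=21, g_max=0.21)


@pytest.fixture
def params() -> AcquisitionParams:
    return AcquisitionParams(te=40.0, slice_thickness=5.0, n_slices=24,
                             slice_spacing_fm=1.0)


@pytest.fixture
def phantom_spec() -> sim.PhantomSpec:
    return sim.PhantomSpec()


@pytest.fixture
def ongrid_scenario(grid21, params):
    """Noiseless table-mode scenario whose per-slice gradients lie exactly
    on the grid, with the ground-truth indices."""
    indices = sim.demo_per_slice_indices(grid21, params.n_slices)
    gz = tuple(grid21.gradient_for_index(indices))
    field = sim.FieldSpec(mode="per_slice_table", per_slice_gz=gz)
    return {"field": field, "indices": indices, "gz": np.asarray(gz)}


@pytest.fixture
def fm_grid(phantom_spec, params):
    """Field-map sampling grid covering the phantom: (shape, voxel_size, z0)."""
    return sim.fieldmap_grid(phantom_spec, params)
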