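"""Shared fixtures: tiny phantoms with analytically known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from tractterm.phantom import (generate_phantom, PhantomSpec, TractGeometry,
                               three_tract_cohort_spec)


def corridor_spec(grid_shape=(41, 5, 5), voxel_size=0.8,
                  half_extent=(4.8, 0.3, 0.3), **kw) -> PhantomSpec:
    """A single straight WM corridor along +x (background orientation), one
    voxel wide, with no tracts.  With the default geometry the corridor spans
    13 voxels of 0.8 mm, i.e. exactly 10 mm of white matter ahead of a seed
    placed at the -x end voxel centre."""
    defaults = dict(grid_shape=grid_shape, voxel_size=voxel_size,
                    wm_half_extent_mm=half_extent, gm_thickness_vox=1,
                    dispersion_deg=0.0, n_subjects=1, subject_jitter_mm=0.0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def corridor_phantom():
    return generate_phantom(corridor_spec())


def single_tract_spec(dispersion_deg=0.0, **kw) -> PhantomSpec:
    """One straight tract along +x ending on the +x WM face."""
    tract = TractGeometry(
        name="t", control_points=np.array([[-14.0, 0.0, 0.0], [21.0, 0.0, 0.0]]),
        corridor_radius_mm=6.0, patch_radius_mm=6.0)
    defaults = dict(grid_shape=(40, 24, 24), voxel_size=2.0,
                    wm_half_extent_mm=(21.0, 12.0, 12.0),
                    tracts=(tract,), dispersion_deg=dispersion_deg,
                    n_subjects=1, subject_jitter_mm=0.0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def single_tract_phantom():
    return generate_phantom(single_tract_spec())


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Scaled-down three-tract cohort used by fast end-to-end checks."""
    return three_tract_cohort_spec(n_subjects=3, rng_seed=11)
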