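"""Shared fixtures: a small desk-scale phantom and its derived products.

The small phantom keeps the default's texture-wavelength-to-spacing ratio
(3 voxels) and wall sampling (~12 voxels transmurally) at a quarter of the
default voxel count, so orientation tests run in seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from myoarch import geometry, orientation, phantom


SMALL_KW = dict(
    outer_radii=(1400.0, 750.0, 750.0),
    wall_thickness=400.0,
    voxel_spacing=20.0,
    texture_wavelength=60.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(**SMALL_KW)


@pytest.fixture(scope="session")
def small_phantom(small_spec) -> phantom.PhantomOutput:
    return phantom.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_frames(small_phantom):
    axis = geometry.fit_heart_axis(small_phantom.mask)
    return geometry.local_cardiac_frames(small_phantom.mask, axis)


@pytest.fixture(scope="session")
def small_depth(small_phantom, small_frames):
    return geometry.normalized_wall_depth(small_phantom.mask, small_frames)


@pytest.fixture(scope="session")
def small_segments(small_phantom, small_frames):
    return geometry.assign_segments(small_phantom.mask, small_frames)


@pytest.fixture(scope="session")
def small_orientation(small_phantom):
    myo = small_phantom.mask.myocardium
    return orientation.estimate_orientation(small_phantom.volume, roi=myo, mask=myo)


def annulus_mask(
    inner_vox: float = 12.0,
    outer_vox: float = 20.0,
    height: int = 24,
    spacing: float = 10.0,
) -> "geometry.LVMask":
    """Hollow digital cylinder along z: cavity inside, myocardium in the shell."""
    from myoarch.volio import LVMask

    half = int(outer_vox) + 3
    n = 2 * half + 1
    yy, xx = np.meshgrid(np.arange(n) - half, np.arange(n) - half, indexing="ij")
    r = np.hypot(yy, xx)
    plane = np.zeros((n, n), dtype=np.uint8)
    plane[r < inner_vox] = 2
    plane[(r >= inner_vox) & (r <= outer_vox)] = 1
    labels = np.broadcast_to(plane, (height, n, n)).copy()
    return LVMask(labels, (spacing, spacing, spacing))


@pytest.fixture()
def annulus():
    return annulus_mask()
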