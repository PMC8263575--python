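"""Structure tensor, eigen-system, helical angles, and transmural fits."""

import numpy as np
import pytest

from myoarch import geometry, orientation
from myoarch.geometry import CardiacFrame, SegmentModel
from myoarch.volio import Volume3D


def _iso(data, s=10.0):
    return Volume3D(np.asarray(data, dtype=np.float32), (s, s, s))


# ---------------------------------------------------------------------------
# Structure tensor
# ---------------------------------------------------------------------------

def test_constant_volume_gives_zero_tensor():
    st = orientation.compute_structure_tensor(_iso(np.full((16, 16, 16), 2.5)))
    assert np.allclose(st.components, 0.0, atol=1e-10)


def test_sine_along_x_dominant_eigenvector_is_x():
    z, y, x = np.meshgrid(*(np.arange(24),) * 3, indexing="ij")
    vol = _iso(np.sin(2 * np.pi * x / 8))
    st = orientation.compute_structure_tensor(vol, sigma_gradient=0.0, sigma_window=2.0)
    mats = st.as_matrices()
    w, v = np.linalg.eigh(mats)
    interior = np.zeros((24, 24, 24), dtype=bool)
    interior[4:-4, 4:-4, 4:-4] = True
    v1 = v[interior.ravel(), :, 2]  # eigenvector of the largest eigenvalue
    # dominant gradient direction is x (last component in (z, y, x))
    assert np.median(np.abs(v1[:, 2])) > 0.999
    lam = w[interior.ravel()]
    assert np.median(lam[:, 1] / lam[:, 2]) < 0.01  # l2, l3 ~ 0 vs l1


def test_structure_tensor_psd_on_noise():
    rng = np.random.default_rng(0)
    st = orientation.compute_structure_tensor(_iso(rng.standard_normal((16, 16, 16))))
    w = np.linalg.eigvalsh(st.as_matrices())
    assert w.min() >= -1e-9


def _analytic_sym3_eigvals(m):
    """Closed-form (trigonometric) eigenvalues of a symmetric 3x3 matrix."""
    p1 = m[0, 1] ** 2 + m[0, 2] ** 2 + m[1, 2] ** 2
    q = np.trace(m) / 3
    p2 = (m[0, 0] - q) ** 2 + (m[1, 1] - q) ** 2 + (m[2, 2] - q) ** 2 + 2 * p1
    p = np.sqrt(p2 / 6)
    if p < 1e-30:
        return np.array([q, q, q])
    b = (m - q * np.eye(3)) / p
    r = np.clip(np.linalg.det(b) / 2, -1, 1)
    phi = np.arccos(r) / 3
    e1 = q + 2 * p * np.cos(phi)
    e3 = q + 2 * p * np.cos(phi + 2 * np.pi / 3)
    return np.array([e1, 3 * q - e1 - e3, e3])


def test_eigendecomposition_matches_closed_form_on_random_psd():
    rng = np.random.default_rng(42)
    a = rng.standard_normal((1000, 3, 3))
    psd = a @ np.transpose(a, (0, 2, 1))
    w = np.sort(np.linalg.eigvalsh(psd), axis=1)[:, ::-1]
    for i in range(1000):
        expect = _analytic_sym3_eigvals(psd[i])
        np.testing.assert_allclose(w[i], expect, atol=1e-8 * max(1.0, abs(expect[0])))


# ---------------------------------------------------------------------------
# Principal orientations
# ---------------------------------------------------------------------------

def test_zero_tensor_invalid_with_zero_coherence():
    comp = np.zeros((8, 8, 8, 6), dtype=np.float32)
    st = orientation.StructureTensorField(comp, 1.0, 2.0, (1, 1, 1))
    out = orientation.principal_orientations(st)
    assert not out.valid.any()
    assert np.all(out.coherence == 0)


def test_eigensystem_sorted_and_unit_v3(small_orientation, small_phantom):
    myo = small_phantom.mask.myocardium
    lam = small_orientation.eigenvalues[myo]
    assert np.all(np.diff(lam, axis=1) <= 1e-5)  # descending
    norms = np.linalg.norm(small_orientation.v3[myo], axis=1)
    valid = small_orientation.valid[myo]
    assert np.allclose(norms[valid], 1.0, atol=1e-6)


def test_lic_texture_recovers_direction(small_phantom, small_orientation):
    """Tertiary eigenvector of the LIC texture aligns with the construction
    field (full 3D angle, including the radial error component the helical
    angle discards)."""
    truth = small_phantom.truth_orientation
    sel = small_orientation.valid & small_phantom.mask.myocardium
    dots = np.abs(np.sum(small_orientation.v3[sel] * truth[sel], axis=1))
    ang = np.degrees(np.arccos(np.clip(dots, 0, 1)))
    assert np.median(ang) <= 10.0


# ---------------------------------------------------------------------------
# Helical angles
# ---------------------------------------------------------------------------

def _unit_frame(shape=(4, 4, 4)):
    """Constant frame: l=+z, r=+x, c=+y (axis through the corner)."""
    frame = CardiacFrame(
        origin_um=np.zeros(3), axis=np.array([1.0, 0.0, 0.0]), spacing=(1, 1, 1)
    )
    frame.r_hat = np.broadcast_to(
        np.array([0, 0, 1], dtype=np.float32), shape + (3,)
    ).copy()
    frame.c_hat = np.broadcast_to(
        np.array([0, 1, 0], dtype=np.float32), shape + (3,)
    ).copy()
    frame.valid = np.ones(shape, dtype=bool)
    return frame


def _orient_with_v3(v3_vec, shape=(4, 4, 4)):
    v3 = np.broadcast_to(np.asarray(v3_vec, dtype=np.float32), shape + (3,)).copy()
    lam = np.broadcast_to(np.array([1.0, 1.0, 0.0], np.float32), shape + (3,)).copy()
    return orientation.OrientationField(
        eigenvalues=lam, v3=v3, coherence=np.ones(shape, np.float32),
        valid=np.ones(shape, bool), spacing=(1, 1, 1),
    )


@pytest.mark.parametrize(
    "v3,expected",
    [
        ([0, 1, 0], 0.0),  # circumferential -> 0 deg
        ([1, 0, 0], 90.0),  # longitudinal -> +90
        ([-1, 0, 0], 90.0),  # axial data: -l is the same orientation -> +90
        ([np.sin(np.radians(30)), np.cos(np.radians(30)), 0], 30.0),
        ([-np.sin(np.radians(30)), -np.cos(np.radians(30)), 0], 30.0),
    ],
)
def test_helical_angle_definition(v3, expected):
    ha = orientation.helical_angle_map(_orient_with_v3(v3), _unit_frame())
    assert ha.valid.all()
    np.testing.assert_allclose(ha.ha_deg, expected, atol=1e-4)


def test_near_radial_vectors_flagged_invalid():
    ha = orientation.helical_angle_map(_orient_with_v3([0.1, 0.1, 0.99]), _unit_frame())
    assert not ha.valid.any()
    assert np.all(np.isnan(ha.ha_deg))


def test_antipodal_invariance_of_ha(small_orientation, small_frames):
    ha1 = orientation.helical_angle_map(small_orientation, small_frames)
    flipped = orientation.OrientationField(
        eigenvalues=small_orientation.eigenvalues,
        v3=-small_orientation.v3,
        coherence=small_orientation.coherence,
        valid=small_orientation.valid,
        spacing=small_orientation.spacing,
    )
    ha2 = orientation.helical_angle_map(flipped, small_frames)
    np.testing.assert_array_equal(ha1.valid, ha2.valid)
    np.testing.assert_allclose(ha1.ha_deg[ha1.valid], ha2.ha_deg[ha2.valid], atol=1e-4)


def test_phantom_endo_positive_epi_negative(small_phantom, small_orientation,
                                            small_frames, small_depth):
    ha = orientation.helical_angle_map(small_orientation, small_frames)
    sel = ha.valid & np.isfinite(small_depth.depth)
    d = small_depth.depth[sel]
    vals = ha.ha_deg[sel]
    assert np.median(vals[d < 0.2]) > 0
    assert np.median(vals[d > 0.8]) < 0


def test_rotation_equivariance_quarter_turn(small_phantom):
    """Rotating volume and mask 90 deg about the axis leaves the HA distribution
    unchanged within discretization tolerance."""
    ph = small_phantom
    vol_r = Volume3D(np.rot90(ph.volume.data, axes=(1, 2)).copy(), ph.volume.spacing)
    from myoarch.volio import LVMask

    mask_r = LVMask(np.rot90(ph.mask.labels, axes=(1, 2)).copy(), ph.mask.spacing)
    axis_r = geometry.fit_heart_axis(mask_r)
    frames_r = geometry.local_cardiac_frames(mask_r, axis_r)
    orient_r = orientation.estimate_orientation(
        vol_r, roi=mask_r.myocardium, mask=mask_r.myocardium
    )
    ha_r = orientation.helical_angle_map(orient_r, frames_r)

    axis0 = geometry.fit_heart_axis(ph.mask)
    frames0 = geometry.local_cardiac_frames(ph.mask, axis0)
    orient0 = orientation.estimate_orientation(
        ph.volume, roi=ph.mask.myocardium, mask=ph.mask.myocardium
    )
    ha0 = orientation.helical_angle_map(orient0, frames0)
    q0 = np.percentile(ha0.ha_deg[ha0.valid], [10, 25, 50, 75, 90])
    q1 = np.percentile(ha_r.ha_deg[ha_r.valid], [10, 25, 50, 75, 90])
    np.testing.assert_allclose(q0, q1, atol=2.0)


# ---------------------------------------------------------------------------
# Transmural fits
# ---------------------------------------------------------------------------

def _fit_inputs(x, y):
    n = len(x)
    shape = (n, 1, 1)
    ha = orientation.HAMap(
        np.asarray(y, np.float32).reshape(shape), np.ones(shape, bool), (1, 1, 1)
    )
    depth = geometry.DepthMap(np.asarray(x, np.float32).reshape(shape), (1, 1, 1))
    segs = SegmentModel(np.ones(shape, np.int16), 1, 1)
    return ha, depth, segs


def test_exact_line_recovered():
    x = np.linspace(0, 1, 20)
    ha, depth, segs = _fit_inputs(x, 60 - 120 * x)
    fit = orientation.fit_transmural_profile(ha, depth, segs, 1)
    assert fit.ok
    assert fit.beta0 == pytest.approx(60, abs=1e-6)
    assert fit.beta1 == pytest.approx(-120, abs=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)
    assert fit.n == 20


def test_symmetric_noise_gives_flat_slope():
    # OLS closed form: symmetric +-e noise at mirrored x cancels the slope exactly
    x = np.array([0.1, 0.9, 0.2, 0.8, 0.3, 0.7, 0.4, 0.6, 0.45, 0.55])
    e = np.array([1, 1, -1, -1, 2, 2, -2, -2, 0.5, 0.5])
    ha, depth, segs = _fit_inputs(x, 10 + e)
    fit = orientation.fit_transmural_profile(ha, depth, segs, 1)
    assert fit.beta1 == pytest.approx(0.0, abs=1e-5)  # float32 map storage
    assert fit.beta0 == pytest.approx(10.0, abs=1.0)


def test_too_few_points_is_missing_record_not_error():
    ha, depth, segs = _fit_inputs([0.5] * 5, [1.0] * 5)
    fit = orientation.fit_transmural_profile(ha, depth, segs, 1, min_points=10)
    assert not fit.ok and "valid points" in fit.reason


def test_zero_depth_variance_rejected_with_diagnostic():
    ha, depth, segs = _fit_inputs([0.5] * 12, list(range(12)))
    fit = orientation.fit_transmural_profile(ha, depth, segs, 1)
    assert not fit.ok and "variance" in fit.reason


def test_phantom_transmural_slope_recovery(small_phantom, small_frames,
                                           small_depth, small_segments, small_orientation):
    ha = orientation.helical_angle_map(small_orientation, small_frames)
    fits = orientation.fit_all_segments(ha, small_depth, small_segments)
    assert fits.ok.all()
    good = (fits.beta1 >= -130) & (fits.beta1 <= -110) & (fits.r2 >= 0.9)
    # the small phantom has only ~12 voxels across the wall; require the bulk
    assert good.mean() >= 0.8
    assert fits.r2.median() >= 0.9
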