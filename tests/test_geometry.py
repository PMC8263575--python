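"""Geometry oracles: contour interpolation, volumes/mass, EDT thickness and
depth on digital annuli, axis fitting, local frames, and the segment model."""

import numpy as np
import pytest

from myoarch import geometry
from myoarch.volio import LVMask


# ---------------------------------------------------------------------------
# Contours -> mask
# ---------------------------------------------------------------------------

def _circle(cy, cx, r, n=72):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([cy + r * np.sin(th), cx + r * np.cos(th)], axis=1)


def _contours(endo_r, epi_r, slices, shape=(11, 64, 64)):
    endo = {z: _circle(32, 32, endo_r[z]) for z in slices}
    epi = {z: _circle(32, 32, epi_r[z]) for z in slices}
    return geometry.ContourSet(endo, epi, (10.0, 10.0, 10.0)), shape


def test_full_delineation_equals_rasterization():
    cs, shape = _contours({z: 8 for z in range(11)}, {z: 16 for z in range(11)}, range(11))
    mask = geometry.interpolate_mask_from_contours(cs, shape)
    from skimage.draw import polygon2mask

    inside_epi = polygon2mask(shape[1:], _circle(32, 32, 16))
    inside_endo = polygon2mask(shape[1:], _circle(32, 32, 8))
    expect = np.zeros(shape[1:], dtype=np.uint8)
    expect[inside_epi] = 1
    expect[inside_endo] = 2
    for z in range(11):
        np.testing.assert_array_equal(mask.labels[z], expect)


def test_identical_circles_interpolate_to_same_circle():
    cs, shape = _contours({0: 8, 10: 8}, {0: 16, 10: 16}, [0, 10])
    mask = geometry.interpolate_mask_from_contours(cs, shape)
    for z in range(1, 10):
        np.testing.assert_array_equal(mask.labels[z], mask.labels[0])


def test_cone_interpolation_radius_midway():
    # epi radius 10 at slice 0, 20 at slice 10 -> ~15 at slice 5 (analytic cone)
    cs, shape = _contours({0: 4, 10: 8}, {0: 10, 10: 20}, [0, 10])
    mask = geometry.interpolate_mask_from_contours(cs, shape)
    area = np.count_nonzero(mask.labels[5] > 0)
    r_eff = np.sqrt(area / np.pi)
    assert abs(r_eff - 15.0) <= 1.0


def test_crossing_surfaces_rejected_with_slice_diagnostics():
    cs, shape = _contours({0: 8, 10: 18}, {0: 16, 10: 16}, [0, 10])
    with pytest.raises(ValueError, match="slices"):
        geometry.interpolate_mask_from_contours(cs, shape)


def test_contourset_json_roundtrip(tmp_path):
    cs, _ = _contours({0: 8, 10: 8}, {0: 16, 10: 16}, [0, 10])
    path = tmp_path / "contours.json"
    cs.to_json(path)
    back = geometry.ContourSet.from_json(path)
    np.testing.assert_allclose(back.endo[0], cs.endo[0])
    assert back.spacing == cs.spacing


# ---------------------------------------------------------------------------
# Volumes and mass
# ---------------------------------------------------------------------------

def test_volume_arithmetic_cube():
    labels = np.zeros((12, 12, 12), dtype=np.uint8)
    labels[1:11, 1:11, 1:11] = 1  # 1000 voxels
    mask = LVMask(labels, (5.8, 5.8, 5.8))
    rep = geometry.compute_volumes_and_mass(mask, density=1.0)
    assert rep.myocardial_ml == pytest.approx(1000 * 5.8**3 / 1e12, rel=1e-12)
    assert rep.myocardial_ml == pytest.approx(1.95112e-7, rel=1e-5)
    assert rep.cavity_ml == 0.0  # empty cavity label: volume 0, no error


def test_mass_density_convention_control_heart():
    # a myocardial volume of 0.58 ml at 1.05 g/ml gives 0.61 g at 2 decimals
    labels = np.zeros((10, 10, 10), dtype=np.uint8)
    labels.flat[:580] = 1
    mask = LVMask(labels, (1000.0, 1000.0, 1000.0))  # 1 mm voxels -> 1e9 µm³ each
    rep = geometry.compute_volumes_and_mass(mask)
    assert rep.myocardial_ml == pytest.approx(0.58)
    assert rep.mass_g == pytest.approx(0.58 * 1.05)
    from myoarch.stats_report import round_half_up

    assert round_half_up(rep.mass_g, 2) == 0.61
    assert rep.mass_g == pytest.approx(rep.myocardial_ml * rep.density_g_per_ml, rel=1e-15)


def test_volumes_empty_myocardium_rejected():
    mask = LVMask(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
    with pytest.raises(ValueError, match="myocardial"):
        geometry.compute_volumes_and_mass(mask)


# ---------------------------------------------------------------------------
# Thickness and depth on digital annuli
# ---------------------------------------------------------------------------

def test_annulus_thickness_within_one_voxel(annulus):
    spacing = annulus.spacing[0]
    tm = geometry.compute_wall_thickness(annulus)
    myo = annulus.myocardium
    expected = (20.0 - 12.0) * spacing
    vals = tm.thickness_um[myo]
    assert np.all(vals > 0)
    # interior slices only (top/bottom faces see the cap, like a cut ventricle)
    mid = tm.thickness_um[10][annulus.myocardium[10]]
    assert np.abs(np.median(mid) - expected) <= spacing
    assert np.percentile(np.abs(mid - expected), 95) <= 1.5 * spacing


def test_annulus_depth_linear_in_radius(annulus):
    spacing = annulus.spacing[0]
    dm = geometry.normalized_wall_depth(annulus)
    n = annulus.shape[1]
    half = n // 2
    yy, xx = np.meshgrid(np.arange(n) - half, np.arange(n) - half, indexing="ij")
    r = np.hypot(yy, xx)
    myo_mid = annulus.myocardium[10]
    expect = (r[myo_mid] - 12.0) / (20.0 - 12.0)
    got = dm.depth[10][myo_mid]
    # ±1 voxel tolerance expressed in depth units
    assert np.percentile(np.abs(got - expect), 95) <= 1.0 / (20.0 - 12.0)
    assert np.all((got >= 0) & (got <= 1))


def test_depth_boundary_bands(annulus):
    dm = geometry.normalized_wall_depth(annulus)
    tm = geometry.compute_wall_thickness(annulus)
    myo = annulus.myocardium
    d_endo_frac = dm.depth[myo]
    near_endo = tm.thickness_um[myo] * d_endo_frac <= annulus.spacing[0]
    assert np.all(d_endo_frac[near_endo] <= 0.2)


def test_thickness_requires_cavity():
    labels = np.zeros((6, 6, 6), dtype=np.uint8)
    labels[2:4, 2:4, 2:4] = 1
    with pytest.raises(ValueError, match="cavity"):
        geometry.compute_wall_thickness(LVMask(labels, (1, 1, 1)))


def test_phantom_depth_matches_truth(small_phantom, small_frames):
    dm = geometry.normalized_wall_depth(small_phantom.mask, small_frames)
    myo = small_phantom.mask.myocardium
    err = dm.depth[myo] - small_phantom.truth_depth[myo]
    assert np.sqrt(np.mean(err**2)) <= 0.05


# ---------------------------------------------------------------------------
# Axis fitting and local frames
# ---------------------------------------------------------------------------

def _ellipsoid_shell_mask(radii, wall, spacing, rot=None, trunc=0.25):
    """Truncated ellipsoidal shell, optionally rotated about the y axis."""
    cz, by, ax = radii
    pad = 4 * spacing
    half = max(radii) + pad
    n = int(2 * half / spacing) + 1
    g = (np.arange(n) - n // 2) * spacing
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
    if rot is not None:
        c, s = np.cos(rot), np.sin(rot)
        zz, xx = c * zz - s * xx, s * zz + c * xx
    m_out = np.sqrt((zz / cz) ** 2 + (yy / by) ** 2 + (xx / ax) ** 2)
    inner = np.array([cz, by, ax]) - wall
    m_in = np.sqrt((zz / inner[0]) ** 2 + (yy / inner[1]) ** 2 + (xx / inner[2]) ** 2)
    below = zz <= cz * (1 - 2 * trunc)
    labels = np.zeros((n, n, n), dtype=np.uint8)
    labels[(m_out <= 1) & (m_in >= 1) & below] = 1
    labels[(m_in < 1) & below] = 2
    return LVMask(labels, (spacing, spacing, spacing))


def test_axis_recovered_along_z():
    mask = _ellipsoid_shell_mask((1200, 600, 600), 250, 25)
    frame = geometry.fit_heart_axis(mask)
    angle = np.degrees(np.arccos(abs(frame.axis[0])))
    assert angle <= 2.0
    assert frame.axis[0] > 0  # apex at -z, base (open cavity) at +z


def test_axis_recovered_after_rotation():
    rot = np.radians(30)
    mask = _ellipsoid_shell_mask((1200, 600, 600), 250, 25, rot=rot)
    frame = geometry.fit_heart_axis(mask)
    # the voxelized shape occupies R^-1 of the ellipsoid: long axis (cos, 0, -sin)
    expected = np.array([np.cos(rot), 0.0, -np.sin(rot)])
    angle = np.degrees(np.arccos(np.clip(abs(frame.axis @ expected), 0, 1)))
    assert angle <= 2.0


def test_axis_empty_and_degenerate_masks_rejected():
    with pytest.raises(ValueError, match="empty"):
        geometry.fit_heart_axis(LVMask(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1)))
    sphere = _ellipsoid_shell_mask((600, 600, 600), 200, 25, trunc=0.04)
    with pytest.raises(ValueError, match="dominant"):
        geometry.fit_heart_axis(sphere)


def test_local_frames_orthonormal_and_oriented(annulus):
    frame = geometry.CardiacFrame(
        origin_um=np.array([120.0, 230.0, 230.0]),
        axis=np.array([1.0, 0.0, 0.0]),
        spacing=annulus.spacing,
    )
    frames = geometry.local_cardiac_frames(annulus, frame)
    myo = frames.valid
    r, c = frames.r_hat[myo], frames.c_hat[myo]
    l = frames.l_hat
    assert np.allclose(np.linalg.norm(r, axis=1), 1, atol=1e-6)
    assert np.allclose(np.linalg.norm(c, axis=1), 1, atol=1e-6)
    assert np.allclose(np.sum(r * c, axis=1), 0, atol=1e-6)
    assert np.allclose(r @ l, 0, atol=1e-6)
    # right-handed: c = l x r
    np.testing.assert_allclose(geometry.cross_zyx(np.broadcast_to(l, r.shape), r), c, atol=1e-6)
    # +x side voxel: r ~ +x, c ~ +y
    iz, iy, ix = 12, 23, 40
    assert annulus.myocardium[iz, iy, ix]
    np.testing.assert_allclose(frames.r_hat[iz, iy, ix], [0, 0, 1], atol=0.05)
    np.testing.assert_allclose(frames.c_hat[iz, iy, ix], [0, 1, 0], atol=0.05)


def test_frames_invariant_under_spacing_rescale(annulus):
    f1 = geometry.CardiacFrame(
        origin_um=np.array([120.0, 230.0, 230.0]), axis=np.array([1.0, 0.0, 0.0]),
        spacing=annulus.spacing,
    )
    frames1 = geometry.local_cardiac_frames(annulus, f1)
    scaled = LVMask(annulus.labels, tuple(2 * s for s in annulus.spacing))
    f2 = geometry.CardiacFrame(
        origin_um=2 * f1.origin_um, axis=f1.axis, spacing=scaled.spacing
    )
    frames2 = geometry.local_cardiac_frames(scaled, f2)
    sel = frames1.valid & frames2.valid
    np.testing.assert_allclose(frames1.r_hat[sel], frames2.r_hat[sel], atol=1e-5)


# ---------------------------------------------------------------------------
# Segment model
# ---------------------------------------------------------------------------

def test_phantom_segments_partition_and_count(small_phantom, small_frames, small_segments):
    segs = small_segments
    assert len(segs.ids_present()) == 45
    myo = small_phantom.mask.myocardium
    assert np.all(segs.segment_ids[myo] > 0)
    assert np.all(segs.segment_ids[~myo] == 0)


def test_reference_angle_shift_permutes_sectors(small_phantom, small_frames):
    width = 360.0 / 9
    a = geometry.assign_segments(small_phantom.mask, small_frames)
    b = geometry.assign_segments(small_phantom.mask, small_frames, reference_angle_deg=width)
    myo = small_phantom.mask.myocardium
    sec_a = (a.segment_ids[myo] - 1) % 9
    sec_b = (b.segment_ids[myo] - 1) % 9
    lev_a = (a.segment_ids[myo] - 1) // 9
    lev_b = (b.segment_ids[myo] - 1) // 9
    agree = (sec_b == (sec_a - 1) % 9) & (lev_a == lev_b)
    assert agree.mean() > 0.99  # up to discretization at bin edges


def test_categories_empty_mi_all_remaining(small_segments):
    model = geometry.derive_segment_categories(small_segments, [])
    assert set(model.categories.values()) == {"remaining"}


def test_categories_single_mi_segment_grid_logic(small_segments):
    # MI at level 3, sector 4 of a 5x9 grid (id 22)
    model = geometry.derive_segment_categories(small_segments, [22])
    cats = model.categories
    assert cats[22] == "MI"
    peri_expected = {12, 13, 14, 21, 23, 30, 31, 32}
    assert {i for i, c in cats.items() if c == "peri-MI"} == peri_expected
    # sector 4 centre +180 deg lands between sectors 8 and 9 -> both contralateral
    assert {i for i, c in cats.items() if c == "contralateral"} == {26, 27}
    assert sum(c == "remaining" for c in cats.values()) == 45 - 1 - 8 - 2


def test_categories_cover_and_disjoint(small_segments):
    model = geometry.derive_segment_categories(small_segments, [1, 22, 45])
    assert set(model.categories) == set(range(1, 46))
    assert all(
        c in {"MI", "peri-MI", "contralateral", "remaining"}
        for c in model.categories.values()
    )


def test_categories_unknown_ids_rejected(small_segments):
    with pytest.raises(ValueError, match="unknown"):
        geometry.derive_segment_categories(small_segments, [99])
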