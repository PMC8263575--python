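"""Synthetic LV phantom generation with known ground truth.

The phantom is a truncated-ellipsoid LV wall (apex closed, base cut open)
whose fiber direction follows a linear endo-to-epi helical-angle law,
HA(depth) = ha_endo + (ha_epi - ha_endo) * depth, defaulting to +60 deg at
the endocardium and -60 deg at the epicardium — the normal pattern of
positive subendocardial and negative subepicardial angles. Image texture is
synthesized by line-integral convolution (LIC) of band-limited noise along
the ground-truth direction field, so the tertiary eigenvector of the
structure tensor has a known answer by construction.

An optional transmural infarct sector adds orientation disarray (random
rotations with Gaussian angle), reduced texture contrast (cardiomyocyte
loss), wall thinning and cavity dilation, and marks the affected segments
MI in the ground-truth segment model.

Scale: the default grid is a desk-scale LV (outer semi-axes 2.0 x 1.1 x
1.1 mm, 400 µm wall, 15 µm isotropic voxels, ~220 x 160 x 160 grid) — a
prolate shape like a rat LV, small enough that the full pipeline runs in
minutes. Spacing is a free parameter, not locked to any scanner.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .geometry import (
    CardiacFrame,
    SegmentModel,
    assign_segments,
    cross_zyx,
    derive_segment_categories,
    local_cardiac_frames,
)
from .volio import LABEL_CAVITY, LABEL_MYOCARDIUM, LVMask, Volume3D, write_mask, write_volume

__all__ = [
    "InfarctSpec",
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "lic_fiber_texture",
    "apply_infarct",
    "save_phantom",
]


@dataclass
class InfarctSpec:
    """Parameters of a transmural infarct sector.

    The region is a circumferential angular interval times a longitudinal
    interval in normalized apex(0)-to-base(1) coordinates. ``jitter_sd``
    controls orientation disarray, ``contrast_scale`` the texture amplitude
    (cardiomyocyte loss), ``thinning_factor`` moves the epicardial surface
    inward, ``cavity_dilation`` >= 1 moves the endocardial surface outward.
    """

    sector_range: tuple[float, float] = (60.0, 150.0)  # degrees
    level_range: tuple[float, float] = (0.25, 0.70)  # normalized apex->base
    jitter_sd: float = 30.0  # degrees
    contrast_scale: float = 0.5
    thinning_factor: float = 0.6
    cavity_dilation: float = 1.0
    seed: int = 0  # jitter stream, independent of the phantom's own streams

    def __post_init__(self) -> None:
        if not self.sector_range[1] > self.sector_range[0]:
            raise ValueError("sector_range width must be > 0")
        if not 0 <= self.level_range[0] < self.level_range[1] <= 1:
            raise ValueError("level_range must be an interval within [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0 <= self.contrast_scale <= 1:
            raise ValueError("contrast_scale must be in [0, 1]")
        if not 0 < self.thinning_factor <= 1:
            raise ValueError("thinning_factor must be in (0, 1]")
        if self.cavity_dilation < 1:
            raise ValueError("cavity_dilation must be >= 1")


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic LV (geometry, HA law, texture)."""

    outer_radii: tuple[float, float, float] = (2000.0, 1100.0, 1100.0)  # µm, (z, y, x)
    wall_thickness: float = 400.0  # µm
    truncation_fraction: float = 0.2  # fraction of the long-axis height cut at the base
    voxel_spacing: float = 15.0  # µm, isotropic
    ha_endo: float = 60.0  # degrees
    ha_epi: float = -60.0
    texture_wavelength: float = 45.0  # µm
    texture_contrast: float = 0.8  # 0..1
    noise_sd: float = 0.05  # intensity units on the [0, 1] scale
    infarct: InfarctSpec | None = None
    seed: int = 0
    pad_voxels: int = 5
    n_levels: int = 5
    n_sectors: int = 9

    def __post_init__(self) -> None:
        if self.wall_thickness >= min(self.outer_radii):
            raise ValueError(
                f"degenerate geometry: wall_thickness {self.wall_thickness} µm must be "
                f"< min(outer_radii) {min(self.outer_radii)} µm"
            )
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be > 0")
        for name, val in (("ha_endo", self.ha_endo), ("ha_epi", self.ha_epi)):
            if not -90 <= val <= 90:
                raise ValueError(f"{name} must be in [-90, 90], got {val}")
        if not 0 < self.truncation_fraction < 0.75:
            raise ValueError("truncation_fraction must be in (0, 0.75)")
        if not 0 <= self.texture_contrast <= 1:
            raise ValueError("texture_contrast must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- JSON round-trip ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        obj = dataclasses.asdict(self)
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PhantomSpec":
        p = Path(source)
        obj = json.loads(p.read_text() if p.exists() else str(source))
        if obj.get("infarct") is not None:
            inf = obj["infarct"]
            inf["sector_range"] = tuple(inf["sector_range"])
            inf["level_range"] = tuple(inf["level_range"])
            obj["infarct"] = InfarctSpec(**inf)
        obj["outer_radii"] = tuple(obj["outer_radii"])
        return cls(**obj)


@dataclass
class PhantomOutput:
    """Phantom volume plus ground truth, all on one voxel grid."""

    volume: Volume3D
    mask: LVMask
    truth_orientation: np.ndarray  # (Z, Y, X, 3) unit vectors on myocardium
    truth_ha: np.ndarray  # degrees, NaN outside myocardium
    truth_segments: SegmentModel
    truth_depth: np.ndarray  # normalized 0..1, NaN outside myocardium
    frame: CardiacFrame  # analytic cylindrical frame (axis = grid z)
    spec: PhantomSpec
    infarct_mask: np.ndarray | None = None  # bool, affected myocardial voxels


# ---------------------------------------------------------------------------
# LIC texture
# ---------------------------------------------------------------------------

def lic_fiber_texture(
    noise_volume: Volume3D, direction_field: np.ndarray, length_um: float
) -> Volume3D:
    """Line-integral convolution of a noise volume along a direction field.

    Each output voxel with a defined direction is the average of the input
    sampled along the streamline through it (total arc length ``length_um``,
    unit steps of one voxel, trilinear sampling, sign-consistent direction
    tracking). Voxels with a zero direction (outside the textured region)
    pass through unchanged. Directions must be unit-norm where defined.
    """
    if length_um < 0:
        raise ValueError("length must be >= 0")
    d = np.asarray(direction_field, dtype=np.float32)
    if d.shape != noise_volume.shape + (3,):
        raise ValueError("direction_field must be (Z, Y, X, 3) matching the volume")
    norms = np.linalg.norm(d, axis=-1)
    textured = norms > 0.5
    if textured.any() and not np.allclose(norms[textured], 1.0, atol=1e-3):
        raise ValueError("direction field must be unit-norm where texture is requested")
    out = noise_volume.data.astype(np.float32).copy()
    h_vox = 1.0  # step, voxels (isotropic spacing assumed by the caller)
    n_steps = int(round((length_um / 2.0) / (noise_volume.spacing[0] * h_vox)))
    if n_steps == 0 or not textured.any():
        return noise_volume.with_data(out, note="lic length=0")

    noise = noise_volume.data.astype(np.float32)
    start = np.argwhere(textured).astype(np.float32)

    def interp(vol: np.ndarray, pts: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(vol, pts.T, order=1, mode="nearest")

    def interp_dir(pts: np.ndarray, ref: np.ndarray) -> np.ndarray:
        vec = np.stack([interp(d[..., k], pts) for k in range(3)], axis=-1)
        n = np.linalg.norm(vec, axis=-1, keepdims=True)
        vec = np.where(n > 1e-6, vec / np.maximum(n, 1e-6), ref)
        flip = np.sum(vec * ref, axis=-1) < 0
        vec[flip] *= -1
        return vec

    acc = noise[textured].astype(np.float64)
    d0 = d[textured]
    for sgn in (1.0, -1.0):
        pos = start.copy()
        prev = sgn * d0
        for _ in range(n_steps):
            step_dir = interp_dir(pos, prev)
            pos = pos + step_dir * h_vox
            prev = step_dir
            acc += interp(noise, pos)
    acc /= 2 * n_steps + 1
    out[textured] = acc.astype(np.float32)
    return noise_volume.with_data(out, note=f"lic length={length_um}µm")


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _level_set(coords: np.ndarray, radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """m(p) = sqrt(sum (p_i / r_i)^2) and |grad m| for an axis-aligned ellipsoid."""
    scaled = coords / radii
    m = np.linalg.norm(scaled, axis=-1)
    grad = scaled / radii
    gnorm = np.linalg.norm(grad, axis=-1) / np.maximum(m, 1e-9)
    return m, gnorm


def _jitter_rotate(vectors: np.ndarray, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate each vector about a uniformly random axis by a N(0, sd) angle."""
    n = vectors.shape[0]
    k = rng.standard_normal((n, 3))
    k /= np.linalg.norm(k, axis=-1, keepdims=True)
    phi = np.radians(rng.standard_normal(n) * sd_deg)
    cosp, sinp = np.cos(phi)[:, None], np.sin(phi)[:, None]
    kxv = cross_zyx(k, vectors)
    kdotv = np.sum(k * vectors, axis=-1, keepdims=True)
    return vectors * cosp + kxv * sinp + k * kdotv * (1 - cosp)


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate the synthetic LV volume with full ground truth.

    Deterministic given ``spec`` (including its seed): the texture-noise and
    Gaussian-noise streams are spawned from the spec seed; infarct jitter
    uses the infarct's own seed so an infarct with neutral parameters leaves
    the phantom bit-identical.
    """
    s = spec.voxel_spacing
    cz, by, ax = spec.outer_radii
    z_cut = cz * (1.0 - 2.0 * spec.truncation_fraction)
    pad = spec.pad_voxels * s
    shape = (
        int(np.ceil((cz + z_cut + 2 * pad) / s)) + 1,
        int(np.ceil((2 * by + 2 * pad) / s)) + 1,
        int(np.ceil((2 * ax + 2 * pad) / s)) + 1,
    )
    center = np.array([cz + pad, by + pad, ax + pad], dtype=np.float64)
    axes = [np.arange(n) * s - c for n, c in zip(shape, center)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(np.float32)

    outer = np.array(spec.outer_radii, dtype=np.float64)
    inner = outer - spec.wall_thickness
    m_out, g_out = _level_set(coords, outer.astype(np.float32))
    m_in, g_in = _level_set(coords, inner.astype(np.float32))
    below_cut = coords[..., 0] <= z_cut
    myo = (m_out <= 1.0) & (m_in >= 1.0) & below_cut
    cavity = (m_in < 1.0) & below_cut
    if not myo.any():
        raise ValueError("degenerate geometry: no myocardial voxels on the grid")

    # approximate normal distances to both surfaces from the level sets
    d_endo = (m_in - 1.0) / np.maximum(g_in, 1e-12)
    d_epi = (1.0 - m_out) / np.maximum(g_out, 1e-12)
    depth = np.full(shape, np.nan, dtype=np.float32)
    depth[myo] = np.clip(d_endo[myo] / np.maximum(d_endo[myo] + d_epi[myo], 1e-9), 0, 1)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[myo] = LABEL_MYOCARDIUM
    labels[cavity] = LABEL_CAVITY
    mask = LVMask(labels, (s, s, s), provenance="phantom")

    # analytic cylindrical frame: axis = +z (apex at -z, truncated base at +z)
    frame = CardiacFrame(
        origin_um=center, axis=np.array([1.0, 0.0, 0.0]), spacing=(s, s, s)
    )
    frame = local_cardiac_frames(mask, frame)
    # on-axis apex voxels: fall back to +x radial so truth stays unit-norm
    on_axis = myo & ~frame.valid
    if on_axis.any():
        frame.r_hat[on_axis] = np.array([0.0, 0.0, 1.0], dtype=np.float32)
        frame.c_hat[on_axis] = np.array([0.0, 1.0, 0.0], dtype=np.float32)

    # normalized apex->base coordinate and circumferential angle for regions
    z_phys = coords[..., 0]
    z_myo = z_phys[myo]
    z0, z1 = float(z_myo.min()), float(z_myo.max())
    level_norm = (z_phys - z0) / max(z1 - z0, 1e-9)
    ang = np.degrees(np.arctan2(coords[..., 2], coords[..., 1]))  # about +z from +y
    ang = np.mod(ang, 360.0)

    infarct_mask = None
    inf = spec.infarct
    if inf is not None:
        a0, a1 = np.mod(inf.sector_range[0], 360.0), np.mod(inf.sector_range[1], 360.0)
        in_sector = (ang >= a0) & (ang <= a1) if a0 <= a1 else (ang >= a0) | (ang <= a1)
        region = myo & in_sector & (level_norm >= inf.level_range[0]) & (
            level_norm <= inf.level_range[1]
        )
        if not region.any():
            raise ValueError("infarct region does not intersect the myocardium")
        # endo surface outward (cavity dilation) and epi surface inward (thinning)
        f_cav = 1.0 - 1.0 / inf.cavity_dilation
        to_cavity = region & (depth < f_cav)
        to_background = region & (depth > inf.thinning_factor)
        labels[to_cavity] = LABEL_CAVITY
        labels[to_background] = 0
        myo = labels == LABEL_MYOCARDIUM
        region &= myo
        # re-normalize depth over the remaining wall inside the region
        depth[region] = np.clip(
            (depth[region] - f_cav) / max(inf.thinning_factor - f_cav, 1e-9), 0, 1
        )
        depth[~myo] = np.nan
        mask = LVMask(labels, (s, s, s), provenance="phantom+infarct")
        infarct_mask = region

    # ground-truth fiber direction: HA(depth) law in the local c-l plane
    ha = np.full(shape, np.nan, dtype=np.float32)
    ha[myo] = spec.ha_endo + (spec.ha_epi - spec.ha_endo) * depth[myo]
    direction = np.zeros(shape + (3,), dtype=np.float32)
    rad = np.radians(ha[myo]).astype(np.float32)
    l_hat = frame.axis.astype(np.float32)
    direction[myo] = (
        np.cos(rad)[:, None] * frame.c_hat[myo] + np.sin(rad)[:, None] * l_hat
    )

    if inf is not None and inf.jitter_sd > 0 and infarct_mask is not None:
        jit_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, inf.seed & 0x7FFFFFFF, 7])
        )
        direction[infarct_mask] = _jitter_rotate(
            direction[infarct_mask].astype(np.float64), inf.jitter_sd, jit_rng
        ).astype(np.float32)

    # texture: band-limited noise, LIC'd along the truth direction field
    ss = np.random.SeedSequence(spec.seed & 0x7FFFFFFF)
    rng_tex, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    noise = rng_tex.standard_normal(shape).astype(np.float32)
    sigma_tex = spec.texture_wavelength / (4.0 * s)
    if sigma_tex > 0:
        noise = ndimage.gaussian_filter(noise, sigma_tex)
    noise_vol = Volume3D(noise, (s, s, s), provenance="phantom noise")
    lic = lic_fiber_texture(noise_vol, direction, 3.0 * spec.texture_wavelength).data

    tex = np.zeros(shape, dtype=np.float32)
    tvals = lic[myo]
    tex[myo] = (tvals - tvals.mean()) / max(tvals.std(), 1e-12)
    amplitude = np.where(myo, 0.5 * spec.texture_contrast, 0.0).astype(np.float32)
    if inf is not None and infarct_mask is not None:
        amplitude[infarct_mask] *= inf.contrast_scale
    intensity = np.full(shape, 0.2, dtype=np.float32)
    intensity[labels == LABEL_CAVITY] = 0.35
    intensity[myo] = 0.5
    intensity += amplitude * tex
    if spec.noise_sd > 0:
        intensity += spec.noise_sd * rng_noise.standard_normal(shape).astype(np.float32)
    volume = Volume3D(intensity, (s, s, s), provenance=f"phantom seed={spec.seed}")

    segments = assign_segments(mask, frame, spec.n_levels, spec.n_sectors)
    mi_ids: list[int] = []
    if infarct_mask is not None:
        seg_ids = segments.segment_ids[myo]
        in_reg = infarct_mask[myo]
        for sid in np.unique(seg_ids):
            sel = seg_ids == sid
            if sel.sum() and in_reg[sel].mean() >= 0.5:
                mi_ids.append(int(sid))
        segments = derive_segment_categories(segments, mi_ids)

    return PhantomOutput(
        volume=volume,
        mask=mask,
        truth_orientation=direction,
        truth_ha=ha,
        truth_segments=segments,
        truth_depth=depth,
        frame=frame,
        spec=spec,
        infarct_mask=infarct_mask,
    )


def apply_infarct(phantom: PhantomOutput, infarct: InfarctSpec, seed: int = 0) -> PhantomOutput:
    """Regenerate the phantom with an infarct sector applied.

    The infarct modifies geometry (thinning, cavity dilation), jitters the
    ground-truth orientations, and damps the texture amplitude inside the
    region; all other random streams are untouched, so a neutral infarct
    (jitter 0, contrast 1, thinning 1, dilation 1) reproduces the input
    phantom bit for bit.
    """
    inf = dataclasses.replace(infarct, seed=seed)
    spec = dataclasses.replace(phantom.spec, infarct=inf)
    return generate_phantom(spec)


def save_phantom(output: PhantomOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write the phantom to disk: NIfTI volume + mask, HDF5 ground truth, JSON spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out_dir / "phantom_volume.nii.gz",
        "mask": out_dir / "phantom_mask.nii.gz",
        "truth": out_dir / "phantom_truth.h5",
        "spec": out_dir / "phantom_spec.json",
    }
    write_volume(output.volume, paths["volume"])
    write_mask(output.mask, paths["mask"])
    with h5py.File(paths["truth"], "w") as f:
        f.create_dataset("orientation", data=output.truth_orientation, compression="gzip")
        f.create_dataset("ha_deg", data=output.truth_ha, compression="gzip")
        f.create_dataset("depth", data=output.truth_depth, compression="gzip")
        f.create_dataset("segment_ids", data=output.truth_segments.segment_ids, compression="gzip")
        f.attrs["spacing_um"] = output.volume.spacing
        f.attrs["n_levels"] = output.truth_segments.n_levels
        f.attrs["n_sectors"] = output.truth_segments.n_sectors
    output.spec.to_json(paths["spec"])
    return paths
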