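"""LV geometry: mask construction, volumes/mass, wall thickness and depth,
the cardiac cylindrical frame, and the 45-segment regional model.

The regional model divides the myocardium into ``n_levels`` equal-length
bins along the apex-to-base axis times ``n_sectors`` equal angular bins
about that axis (default 5 x 9 = 45 segments). Infarcted (MI) segments are
user-declared (or come from phantom ground truth); peri-MI segments are the
grid neighbours of MI segments, and contralateral segments sit diametrically
opposite the MI segments at the same level.

All physical quantities are derived from voxel spacing in µm:
volumes in ml (1 ml = 1e12 µm^3), thickness per voxel in µm and per segment
in mm, mass in g via a configurable myocardial density (default 1.05 g/ml).

Vector fields store components in ``(z, y, x)`` order to match array
indexing; cross products are evaluated in the right-handed (x, y, z) basis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask

from .volio import LABEL_BACKGROUND, LABEL_CAVITY, LABEL_MYOCARDIUM, LVMask

__all__ = [
    "ContourSet",
    "CardiacFrame",
    "SegmentModel",
    "ThicknessMap",
    "DepthMap",
    "VolumesReport",
    "DEFAULT_DENSITY_G_PER_ML",
    "cross_zyx",
    "interpolate_mask_from_contours",
    "compute_volumes_and_mass",
    "compute_wall_thickness",
    "fit_heart_axis",
    "local_cardiac_frames",
    "normalized_wall_depth",
    "assign_segments",
    "derive_segment_categories",
]

#: Myocardial tissue density used to convert volume to mass.
DEFAULT_DENSITY_G_PER_ML = 1.05

UM3_PER_ML = 1.0e12

CAT_MI = "MI"
CAT_PERI = "peri-MI"
CAT_CONTRA = "contralateral"
CAT_REMAINING = "remaining"
CAT_NONE = "none"


def cross_zyx(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product of vectors whose components are stored (z, y, x)."""
    return np.cross(a[..., ::-1], b[..., ::-1])[..., ::-1]


# ---------------------------------------------------------------------------
# Contours -> mask
# ---------------------------------------------------------------------------

@dataclass
class ContourSet:
    """Sparse per-slice closed polygons for the endo- and epicardial borders.

    ``endo`` / ``epi`` map slice index (z) to an (K, 2) array of [y, x]
    vertices in voxel units. At least two delineated slices per surface are
    required so the surfaces can be interpolated between them.
    """

    endo: dict[int, np.ndarray]
    epi: dict[int, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.endo = {int(k): np.asarray(v, dtype=float) for k, v in self.endo.items()}
        self.epi = {int(k): np.asarray(v, dtype=float) for k, v in self.epi.items()}
        for name, polys in (("endo", self.endo), ("epi", self.epi)):
            if len(polys) < 2:
                raise ValueError(f"{name}: need >= 2 delineated slices, got {len(polys)}")
            for z, poly in polys.items():
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                    raise ValueError(f"{name} slice {z}: polygon must be (K>=3, 2) [y, x]")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "spacing_um": list(self.spacing),
            "endo": {str(z): p.tolist() for z, p in self.endo.items()},
            "epi": {str(z): p.tolist() for z, p in self.epi.items()},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContourSet":
        obj = json.loads(Path(path).read_text())
        return cls(
            endo={int(z): np.asarray(p) for z, p in obj["endo"].items()},
            epi={int(z): np.asarray(p) for z, p in obj["epi"].items()},
            spacing=tuple(obj["spacing_um"]),
        )


def _slice_sdf(shape2d: tuple[int, int], poly: np.ndarray) -> np.ndarray:
    """Signed distance (voxels) to the polygon boundary: negative inside."""
    inside = polygon2mask(shape2d, poly)
    # EDT of the complement measures distance from inside voxels to the border
    d_in = ndimage.distance_transform_edt(inside)
    d_out = ndimage.distance_transform_edt(~inside)
    return np.where(inside, -d_in, d_out).astype(np.float32)


def _interp_surface(polys: dict[int, np.ndarray], shape: tuple[int, int, int]) -> np.ndarray:
    """Per-voxel 'inside surface' boolean by linear interpolation of slice SDFs."""
    zs = sorted(polys)
    sdfs = {z: _slice_sdf(shape[1:], polys[z]) for z in zs}
    inside = np.zeros(shape, dtype=bool)
    for z0, z1 in zip(zs[:-1], zs[1:]):
        for z in range(z0, z1 + 1):
            t = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
            sdf = (1 - t) * sdfs[z0] + t * sdfs[z1]
            inside[z] = sdf < 0
    return inside


def interpolate_mask_from_contours(
    contours: ContourSet, shape: tuple[int, int, int]
) -> LVMask:
    """Build the whole LV mask from sparse short-axis contours.

    On delineated slices the mask equals the rasterized contours exactly;
    between them the endo- and epicardial surfaces come from linear
    interpolation of per-slice signed-distance maps thresholded at zero.
    Slices outside the delineated range stay background. Cavity is the
    interior of the endo surface, myocardium the shell between surfaces.
    """
    if max(max(contours.endo), max(contours.epi)) >= shape[0]:
        raise ValueError("contour slice index beyond target grid depth")
    in_endo = _interp_surface(contours.endo, shape)
    in_epi = _interp_surface(contours.epi, shape)
    crossing = in_endo & ~in_epi
    if crossing.any():
        bad = sorted(np.unique(np.nonzero(crossing)[0]).tolist())
        raise ValueError(
            f"endocardial surface falls outside the epicardial surface on slices {bad}"
        )
    labels = np.zeros(shape, dtype=np.uint8)
    labels[in_epi & ~in_endo] = LABEL_MYOCARDIUM
    labels[in_endo] = LABEL_CAVITY
    return LVMask(labels, contours.spacing, provenance="interpolated from contours")


# ---------------------------------------------------------------------------
# Volumes, thickness, depth
# ---------------------------------------------------------------------------

@dataclass
class VolumesReport:
    cavity_ml: float
    myocardial_ml: float
    mass_g: float
    density_g_per_ml: float

    def to_dict(self) -> dict:
        return {
            "cavity_ml": self.cavity_ml,
            "myocardial_ml": self.myocardial_ml,
            "mass_g": self.mass_g,
            "density_g_per_ml": self.density_g_per_ml,
        }


def compute_volumes_and_mass(
    mask: LVMask, density: float = DEFAULT_DENSITY_G_PER_ML
) -> VolumesReport:
    """Cavity and myocardial volumes (ml) and myocardial mass (g).

    Volume = voxel count x voxel volume; mass = myocardial volume x density,
    exactly, with the density recorded in the report.
    """
    n_myo = int(np.count_nonzero(mask.labels == LABEL_MYOCARDIUM))
    if n_myo == 0:
        raise ValueError("mask has no myocardial voxels")
    n_cav = int(np.count_nonzero(mask.labels == LABEL_CAVITY))
    vox_ml = float(np.prod(mask.spacing)) / UM3_PER_ML
    myo_ml = n_myo * vox_ml
    return VolumesReport(
        cavity_ml=n_cav * vox_ml,
        myocardial_ml=myo_ml,
        mass_g=myo_ml * density,
        density_g_per_ml=density,
    )


def _edt_pair(
    mask: LVMask, frame: "CardiacFrame | None" = None
) -> tuple[np.ndarray, np.ndarray]:
    """Distances (µm) from each voxel to the cavity and to the epicardial background.

    With a ``frame`` given, background voxels at or beyond the basal end of
    the myocardium (the open cut of a truncated ventricle) are not counted
    as epicardial surface: without this, wall depth near the base is
    measured against the cut plane instead of the epicardium.
    """
    if not np.any(mask.labels == LABEL_CAVITY):
        raise ValueError("mask has no cavity: wall thickness/depth need both surfaces")
    background = mask.labels == LABEL_BACKGROUND
    if not background.any():
        raise ValueError("mask has no background: wall thickness/depth need both surfaces")
    if frame is not None:
        t = (
            _physical_coords(mask.shape, mask.spacing) - frame.origin_um.astype(np.float32)
        ) @ frame.axis.astype(np.float32)
        t_base = t[mask.myocardium].max() - 0.5 * float(max(mask.spacing))
        epi_bg = background & (t < t_base)
        if not epi_bg.any():
            epi_bg = background
    else:
        epi_bg = background
    d_endo = ndimage.distance_transform_edt(mask.labels != LABEL_CAVITY, sampling=mask.spacing)
    d_epi = ndimage.distance_transform_edt(~epi_bg, sampling=mask.spacing)
    return d_endo.astype(np.float32), d_epi.astype(np.float32)


@dataclass
class ThicknessMap:
    """Per-voxel wall thickness (µm) on the myocardium; NaN elsewhere."""

    thickness_um: np.ndarray
    spacing: tuple[float, float, float]

    def per_segment_mm(self, segments: "SegmentModel") -> pd.DataFrame:
        """Mean thickness per segment, in mm."""
        rows = []
        for seg_id in range(1, segments.n_segments + 1):
            sel = segments.segment_ids == seg_id
            vals = self.thickness_um[sel]
            rows.append(
                {
                    "segment_id": seg_id,
                    "level": segments.level_of(seg_id),
                    "sector": segments.sector_of(seg_id),
                    "category": segments.categories.get(seg_id, CAT_NONE),
                    "thickness_mm": float(np.nanmean(vals)) / 1000.0 if vals.size else np.nan,
                    "voxels": int(vals.size),
                }
            )
        return pd.DataFrame(rows)


def compute_wall_thickness(mask: LVMask, frame: "CardiacFrame | None" = None) -> ThicknessMap:
    """Wall thickness from the Euclidean distance transform of the LV mask.

    Per-voxel thickness is the sum of the distances to the cavity
    (endocardial side) and to the background (epicardial side); on a wall
    with locally parallel surfaces this equals the true wall thickness.
    The EDT measures voxel-centre to voxel-centre, overshooting each surface
    by half a voxel, so one voxel spacing is subtracted from the sum.
    Pass the cardiac ``frame`` to keep the open basal cut of a truncated
    ventricle from being mistaken for epicardium (see :func:`_edt_pair`).
    """
    d_endo, d_epi = _edt_pair(mask, frame)
    thick = np.full(mask.shape, np.nan, dtype=np.float32)
    myo = mask.myocardium
    thick[myo] = d_endo[myo] + d_epi[myo] - float(max(mask.spacing))
    return ThicknessMap(thick, mask.spacing)


@dataclass
class DepthMap:
    """Normalized transmural depth: 0 at the endocardium, 1 at the epicardium."""

    depth: np.ndarray  # float32, NaN outside the myocardium
    spacing: tuple[float, float, float]


def normalized_wall_depth(mask: LVMask, frame: "CardiacFrame | None" = None) -> DepthMap:
    """depth = d_endo / (d_endo + d_epi) per myocardial voxel.

    As in :func:`compute_wall_thickness`, passing the ``frame`` excludes the
    open basal cut from the epicardial surface.
    """
    d_endo, d_epi = _edt_pair(mask, frame)
    depth = np.full(mask.shape, np.nan, dtype=np.float32)
    myo = mask.myocardium
    total = d_endo[myo] + d_epi[myo]
    depth[myo] = d_endo[myo] / np.maximum(total, 1e-9)
    return DepthMap(depth, mask.spacing)


# ---------------------------------------------------------------------------
# Cardiac cylindrical frame
# ---------------------------------------------------------------------------

@dataclass
class CardiacFrame:
    """Apex-to-base axis plus per-voxel local cylindrical directions.

    ``l_hat`` (longitudinal, along the axis) is constant; ``r_hat`` (radial,
    outward from the axis) and ``c_hat`` (circumferential, = l x r) are
    per-voxel fields with components in (z, y, x) order. The triple
    (c, l, r) is orthonormal and right-handed wherever ``valid``.
    """

    origin_um: np.ndarray  # (3,) physical (z, y, x)
    axis: np.ndarray  # (3,) unit, apex -> base
    spacing: tuple[float, float, float]
    r_hat: np.ndarray | None = None  # (Z, Y, X, 3)
    c_hat: np.ndarray | None = None
    valid: np.ndarray | None = None  # (Z, Y, X) bool

    @property
    def l_hat(self) -> np.ndarray:
        return self.axis


def _physical_coords(shape: tuple[int, int, int], spacing) -> np.ndarray:
    """(Z, Y, X, 3) physical coordinates in µm, (z, y, x) components."""
    axes = [np.arange(n, dtype=np.float32) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def fit_heart_axis(mask: LVMask, dominance_ratio: float = 1.1) -> CardiacFrame:
    """Apex-to-base axis as the principal axis of the myocardial voxel cloud.

    The axis is oriented apex -> base, the base being detected as the end
    where the cavity is open (the cavity extends to the myocardial extreme
    of the truncated base, but stops short of the closed apex). The origin
    is the myocardial centroid.
    """
    myo_idx = np.argwhere(mask.myocardium)
    if myo_idx.size == 0:
        raise ValueError("empty myocardium")
    coords = myo_idx.astype(np.float64) * np.asarray(mask.spacing)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] < dominance_ratio * evals[1]:
        raise ValueError(
            f"no dominant long axis: principal variance ratio "
            f"{evals[2] / max(evals[1], 1e-30):.3f} < {dominance_ratio}"
        )
    axis = evecs[:, 2]

    cav_idx = np.argwhere(mask.cavity)
    if cav_idx.size:
        cav_t = (cav_idx * np.asarray(mask.spacing) - centroid) @ axis
        myo_t = centered @ axis
        gap_pos = myo_t.max() - cav_t.max()  # myocardium beyond cavity at +axis end
        gap_neg = cav_t.min() - myo_t.min()
        if gap_pos > gap_neg:  # +axis end is the closed apex -> flip
            axis = -axis
    else:
        warnings.warn("no cavity voxels: apex/base orientation of the axis is arbitrary")
    return CardiacFrame(origin_um=centroid, axis=axis / np.linalg.norm(axis), spacing=mask.spacing)


def local_cardiac_frames(
    mask: LVMask, frame: CardiacFrame, min_radius_um: float | None = None
) -> CardiacFrame:
    """Fill in the per-voxel radial and circumferential unit vectors.

    l = axis direction; r = unit component of (voxel - origin) perpendicular
    to l; c = l x r. Voxels closer to the axis than ``min_radius_um``
    (default: one voxel) have an undefined radial direction and are flagged
    invalid.
    """
    if min_radius_um is None:
        min_radius_um = float(max(mask.spacing))
    p = _physical_coords(mask.shape, mask.spacing) - frame.origin_um.astype(np.float32)
    l = frame.axis.astype(np.float32)
    t = p @ l
    perp = p - t[..., None] * l
    rho = np.linalg.norm(perp, axis=-1)
    valid = mask.myocardium & (rho > min_radius_um)
    r_hat = perp / np.maximum(rho, 1e-12)[..., None]
    c_hat = cross_zyx(np.broadcast_to(l, r_hat.shape), r_hat)
    return CardiacFrame(
        origin_um=frame.origin_um,
        axis=frame.axis,
        spacing=mask.spacing,
        r_hat=r_hat.astype(np.float32),
        c_hat=c_hat.astype(np.float32),
        valid=valid,
    )


# ---------------------------------------------------------------------------
# Segment model
# ---------------------------------------------------------------------------

@dataclass
class SegmentModel:
    """Per-voxel segment ids (1..n_levels*n_sectors; 0 outside) + categories.

    Segment id = (level - 1) * n_sectors + sector with level 1 at the apex
    and sector 1 starting at the reference angle.
    """

    segment_ids: np.ndarray  # int16, 0 outside myocardium
    n_levels: int
    n_sectors: int
    categories: dict[int, str] = field(default_factory=dict)
    mi_ids: tuple[int, ...] = ()

    @property
    def n_segments(self) -> int:
        return self.n_levels * self.n_sectors

    def level_of(self, seg_id: int) -> int:
        return (seg_id - 1) // self.n_sectors + 1

    def sector_of(self, seg_id: int) -> int:
        return (seg_id - 1) % self.n_sectors + 1

    def seg_id(self, level: int, sector: int) -> int:
        return (level - 1) * self.n_sectors + sector

    def ids_present(self) -> np.ndarray:
        ids = np.unique(self.segment_ids)
        return ids[ids > 0]

    def category_of_voxels(self) -> np.ndarray:
        """Per-voxel category codes: '' outside, else the segment's category."""
        lut = np.array(
            [""] + [self.categories.get(i, CAT_NONE) for i in range(1, self.n_segments + 1)],
            dtype=object,
        )
        return lut[self.segment_ids]

    def to_table(self) -> pd.DataFrame:
        counts = np.bincount(self.segment_ids.ravel(), minlength=self.n_segments + 1)
        rows = [
            {
                "segment_id": i,
                "level": self.level_of(i),
                "sector": self.sector_of(i),
                "category": self.categories.get(i, CAT_NONE),
                "voxels": int(counts[i]),
            }
            for i in range(1, self.n_segments + 1)
        ]
        return pd.DataFrame(rows)


def assign_segments(
    mask: LVMask,
    frame: CardiacFrame,
    n_levels: int = 5,
    n_sectors: int = 9,
    reference_angle_deg: float = 0.0,
) -> SegmentModel:
    """Partition the myocardium into level x sector segments.

    Levels are equal-length bins of the axial coordinate from apex to base;
    sectors are equal angular bins of the circumferential angle about the
    axis, measured counter-clockwise about l from a reference direction,
    with sector 1 starting at ``reference_angle_deg``.
    """
    myo = mask.myocardium
    if not myo.any():
        raise ValueError("empty myocardium")
    p = _physical_coords(mask.shape, mask.spacing) - frame.origin_um.astype(np.float32)
    l = frame.axis.astype(np.float32)
    t = (p @ l)[myo]
    # reference direction in the plane perpendicular to the axis
    ref = np.array([0.0, 1.0, 0.0], dtype=np.float32)  # +y in (z, y, x)
    ref = ref - (ref @ l) * l
    if np.linalg.norm(ref) < 1e-6:
        ref = np.array([0.0, 0.0, 1.0], dtype=np.float32)
        ref = ref - (ref @ l) * l
    ref /= np.linalg.norm(ref)
    ref2 = cross_zyx(l, ref)
    perp = p[myo] - (p[myo] @ l)[:, None] * l
    ang = np.degrees(np.arctan2(perp @ ref2, perp @ ref)) - reference_angle_deg
    ang = np.mod(ang, 360.0)

    t0, t1 = t.min(), t.max()
    level = np.clip(((t - t0) / max(t1 - t0, 1e-9) * n_levels).astype(int), 0, n_levels - 1)
    sector = np.clip((ang / 360.0 * n_sectors).astype(int), 0, n_sectors - 1)
    ids = np.zeros(mask.shape, dtype=np.int16)
    ids[myo] = (level * n_sectors + sector + 1).astype(np.int16)

    model = SegmentModel(ids, n_levels, n_sectors)
    present = set(model.ids_present().tolist())
    empty = [i for i in range(1, model.n_segments + 1) if i not in present]
    if empty:
        warnings.warn(f"{len(empty)} empty segment(s): {empty}")
    model.categories = {i: CAT_REMAINING for i in range(1, model.n_segments + 1)}
    return model


def derive_segment_categories(segments: SegmentModel, mi_ids) -> SegmentModel:
    """Classify segments as MI / peri-MI / contralateral / remaining.

    peri-MI segments are the (<= 8) level x sector grid neighbours of each
    MI segment, with the sector index wrapping; contralateral segments are,
    for each MI segment, the segment(s) at the same level whose sector
    centre is nearest to the MI sector centre + 180 deg (both when two
    straddle it). Precedence: MI > peri-MI > contralateral > remaining.
    """
    mi_ids = tuple(int(i) for i in mi_ids)
    bad = [i for i in mi_ids if not (1 <= i <= segments.n_segments)]
    if bad:
        raise ValueError(f"unknown segment ids {bad}; valid range 1..{segments.n_segments}")
    nl, ns = segments.n_levels, segments.n_sectors
    cats = {i: CAT_REMAINING for i in range(1, segments.n_segments + 1)}

    peri: set[int] = set()
    contra: set[int] = set()
    for sid in mi_ids:
        lvl, sec = segments.level_of(sid), segments.sector_of(sid)
        for dl in (-1, 0, 1):
            for dsec in (-1, 0, 1):
                if dl == 0 and dsec == 0:
                    continue
                l2 = lvl + dl
                if not (1 <= l2 <= nl):
                    continue
                s2 = (sec - 1 + dsec) % ns + 1
                peri.add(segments.seg_id(l2, s2))
        # contralateral: sector centre(s) nearest to this sector centre + 180
        centers = (np.arange(ns) + 0.5) * 360.0 / ns
        target = centers[sec - 1] + 180.0
        d = np.abs((centers - target + 180.0) % 360.0 - 180.0)
        for s2 in (np.flatnonzero(np.isclose(d, d.min())) + 1).tolist():
            contra.add(segments.seg_id(lvl, s2))

    for sid in contra - set(mi_ids) - peri:
        cats[sid] = CAT_CONTRA
    for sid in peri - set(mi_ids):
        cats[sid] = CAT_PERI
    for sid in mi_ids:
        cats[sid] = CAT_MI
    return SegmentModel(
        segments.segment_ids, nl, ns, categories=cats, mi_ids=mi_ids
    )
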