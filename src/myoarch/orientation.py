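"""Structure-tensor estimation of local cardiomyocyte-aggregate orientation,
helical-angle (HA) maps, and transmural linear fits.

The structure tensor at a voxel is the Gaussian-windowed local sum of the
outer products of the image gradient, computed by central differences after
Gaussian pre-smoothing:

    ST = sum_w [ gx*gx  gx*gy  gx*gz
                 gy*gx  gy*gy  gy*gz
                 gz*gx  gz*gy  gz*gz ]

Its eigenvector with the smallest eigenvalue (the tertiary eigenvector v3)
points along the direction of least intensity variation, i.e. along the
cell aggregates. The helical angle is the signed angle, within the local
circumferential-longitudinal tangent plane, between the projection of v3
and the circumferential direction: positive when v3 tilts towards the base,
in [-90, +90] degrees. v3 is axial data (v3 and -v3 are the same
orientation); the sign conventions below make the HA well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import CardiacFrame, DepthMap, SegmentModel
from .volio import Volume3D

__all__ = [
    "StructureTensorField",
    "OrientationField",
    "HAMap",
    "TransmuralFit",
    "compute_structure_tensor",
    "principal_orientations",
    "helical_angle_map",
    "fit_transmural_profile",
    "fit_all_segments",
    "estimate_orientation",
]

DEFAULT_SIGMA_GRADIENT = 0.25  # voxels; pre-smoothing before central differences
DEFAULT_SIGMA_WINDOW = 1.5  # voxels; local integration window of the tensor
DEFAULT_MASK_EROSION = 2  # voxels; boundary gradients contaminated by the tissue edge
DEFAULT_MIN_SUPPORT = 0.4  # min fraction of window mass from interior myocardium
DEFAULT_COHERENCE_MIN = 0.1
#: minimum tangent-plane projection norm of v3 before the HA is considered stable
NEAR_RADIAL_THRESHOLD = 0.2


@dataclass
class StructureTensorField:
    """Per-voxel symmetric 3x3 structure tensor, stored as 6 unique channels.

    Channel order: (zz, zy, zx, yy, yx, xx) with gradient components in the
    internal (z, y, x) axis convention.
    """

    components: np.ndarray  # (Z, Y, X, 6) float32
    sigma_gradient: float
    sigma_window: float
    spacing: tuple[float, float, float]

    _IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]

    def as_matrices(self, where: np.ndarray | None = None) -> np.ndarray:
        """Dense (N, 3, 3) tensors at ``where`` (boolean mask) or all voxels."""
        comp = self.components if where is None else self.components[where]
        comp = comp.reshape(-1, 6)
        m = np.empty((comp.shape[0], 3, 3), dtype=comp.dtype)
        for k, (i, j) in enumerate(self._IDX):
            m[:, i, j] = comp[:, k]
            m[:, j, i] = comp[:, k]
        return m


def compute_structure_tensor(
    volume: Volume3D,
    sigma_gradient: float = DEFAULT_SIGMA_GRADIENT,
    sigma_window: float = DEFAULT_SIGMA_WINDOW,
    mask: np.ndarray | None = None,
    mask_erosion: int = DEFAULT_MASK_EROSION,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> StructureTensorField:
    """Assemble the structure tensor field of an isotropic volume.

    Gradients are central differences of the volume pre-smoothed with a
    Gaussian of ``sigma_gradient`` voxels; the tensor is the Gaussian-
    weighted local sum (window ``sigma_window`` voxels) of the gradient
    outer products. Scales are in voxels, which is why isotropic spacing is
    a precondition.

    With a boolean ``mask`` (e.g. the myocardium) the tensor is computed in
    masked normalized-convolution form: pre-smoothing interpolates only
    masked intensities, gradient products are accumulated with weights from
    the mask eroded by ``mask_erosion`` voxels (boundary gradients are
    dominated by the tissue edge, not the texture), and voxels whose window
    draws less than ``min_support`` of its mass from the eroded mask get a
    zero tensor (-> flagged invalid downstream). This keeps the strong
    endo-/epicardial edge gradient from biasing the texture orientation
    near the wall surfaces.
    """
    if not volume.is_isotropic:
        raise ValueError(
            f"structure tensor requires isotropic spacing, got {volume.spacing}"
        )
    if sigma_window <= 0:
        raise ValueError("sigma_window must be > 0")
    min_extent = int(np.ceil(4 * sigma_window + 2))
    if min(volume.shape) < min_extent:
        raise ValueError(
            f"volume shape {volume.shape} smaller than the integration window "
            f"(needs >= {min_extent} voxels per axis)"
        )
    data = volume.data.astype(np.float32)
    comp = np.empty(volume.shape + (6,), dtype=np.float32)
    if mask is None:
        if sigma_gradient > 0:
            data = ndimage.gaussian_filter(data, sigma_gradient)
        gz, gy, gx = np.gradient(data)  # central differences, one-sided at borders
        grads = (gz, gy, gx)
        for k, (i, j) in enumerate(StructureTensorField._IDX):
            comp[..., k] = ndimage.gaussian_filter(grads[i] * grads[j], sigma_window)
        return StructureTensorField(comp, sigma_gradient, sigma_window, volume.spacing)

    mask = np.asarray(mask, dtype=bool)
    w = mask.astype(np.float32)
    if sigma_gradient > 0:
        den = ndimage.gaussian_filter(w, sigma_gradient)
        data = np.where(den > 1e-3, ndimage.gaussian_filter(data * w, sigma_gradient)
                        / np.maximum(den, 1e-3), 0.0)
    else:
        data = np.where(mask, data, 0.0)
    gz, gy, gx = np.gradient(data)
    grads = (gz, gy, gx)
    w2 = mask
    if mask_erosion > 0:
        w2 = ndimage.binary_erosion(mask, iterations=mask_erosion)
    w2 = w2.astype(np.float32)
    support = ndimage.gaussian_filter(w2, sigma_window)
    for k, (i, j) in enumerate(StructureTensorField._IDX):
        comp[..., k] = ndimage.gaussian_filter(grads[i] * grads[j] * w2, sigma_window) / np.maximum(
            support, 1e-6
        )
    comp[support < min_support] = 0.0
    return StructureTensorField(comp, sigma_gradient, sigma_window, volume.spacing)


@dataclass
class OrientationField:
    """Sorted eigen-system of the structure tensor on a region of interest."""

    eigenvalues: np.ndarray  # (Z, Y, X, 3), descending l1 >= l2 >= l3; NaN outside
    v3: np.ndarray  # (Z, Y, X, 3) unit tertiary eigenvector, (z, y, x) comps
    coherence: np.ndarray  # (Z, Y, X) in [0, 1]
    valid: np.ndarray  # (Z, Y, X) bool
    spacing: tuple[float, float, float]


def _canonicalize_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each vector so its last nonzero component is >= 0 (axial data)."""
    v = vectors.copy()
    sign = np.where(v[..., 2] != 0, np.sign(v[..., 2]), 0.0)
    sign = np.where(sign == 0, np.where(v[..., 1] != 0, np.sign(v[..., 1]), 0.0), sign)
    sign = np.where(sign == 0, np.where(v[..., 0] < 0, -1.0, 1.0), sign)
    return v * sign[..., None]


def principal_orientations(
    st: StructureTensorField,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
    roi: np.ndarray | None = None,
) -> OrientationField:
    """Eigen-decompose the structure tensor and extract v3 + coherence.

    coherence = (l2 - l3) / (l1 + l2 + l3), the contrast between the two
    smallest eigenvalues: high when one direction clearly varies least
    (fibrous texture), zero for isotropic or empty texture. Voxels with a
    zero tensor or coherence below ``coherence_min`` are flagged invalid.
    ``roi`` restricts the (costly) eigendecomposition to a boolean mask.
    """
    shape = st.components.shape[:3]
    if roi is None:
        roi = np.ones(shape, dtype=bool)
    mats = st.as_matrices(roi).astype(np.float64)
    w, v = np.linalg.eigh(mats)  # ascending eigenvalues
    evals = w[:, ::-1]  # descending: l1, l2, l3
    v3_roi = v[:, :, 0]  # eigenvector of the smallest eigenvalue
    total = evals.sum(axis=1)
    zero = total <= 1e-20
    coh_roi = np.where(zero, 0.0, (evals[:, 1] - evals[:, 2]) / np.where(zero, 1.0, total))
    valid_roi = ~zero & (coh_roi >= coherence_min)

    eigenvalues = np.full(shape + (3,), np.nan, dtype=np.float32)
    v3 = np.zeros(shape + (3,), dtype=np.float32)
    coherence = np.zeros(shape, dtype=np.float32)
    valid = np.zeros(shape, dtype=bool)
    eigenvalues[roi] = evals.astype(np.float32)
    v3[roi] = _canonicalize_sign(v3_roi).astype(np.float32)
    coherence[roi] = coh_roi.astype(np.float32)
    valid[roi] = valid_roi
    return OrientationField(eigenvalues, v3, coherence, valid, st.spacing)


@dataclass
class HAMap:
    """Per-voxel helical angle in degrees, [-90, +90]; NaN where invalid."""

    ha_deg: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]


def helical_angle_map(orient: OrientationField, frame: CardiacFrame) -> HAMap:
    """Helical angle of v3 relative to the local circumferential direction.

    v3 is decomposed onto the local (c, l, r) frame, re-signed so that its
    circumferential component is >= 0 (v3 is axial data), and
    HA = atan2(l-component, c-component). Purely longitudinal vectors map
    to +90 deg by convention. Voxels whose tangent-plane projection norm is
    below ``NEAR_RADIAL_THRESHOLD`` (near-radial vectors, unstable angle)
    or whose frame is undefined are flagged invalid.
    """
    if frame.c_hat is None or frame.valid is None:
        raise ValueError("frame lacks per-voxel directions; call local_cardiac_frames first")
    comp_c = np.sum(orient.v3 * frame.c_hat, axis=-1)
    comp_l = orient.v3 @ frame.l_hat.astype(np.float32)
    # axial re-signing: circumferential component >= 0; pure +-longitudinal -> +90
    flip = (comp_c < 0) | ((comp_c == 0) & (comp_l < 0))
    comp_c = np.where(flip, -comp_c, comp_c)
    comp_l = np.where(flip, -comp_l, comp_l)
    tangent_norm = np.hypot(comp_c, comp_l)
    valid = orient.valid & frame.valid & (tangent_norm >= NEAR_RADIAL_THRESHOLD)
    ha = np.degrees(np.arctan2(comp_l, np.maximum(comp_c, 0.0)))
    ha = np.where(valid, ha, np.nan).astype(np.float32)
    return HAMap(ha, valid, orient.spacing)


@dataclass
class TransmuralFit:
    """OLS fit HA = beta0 + beta1 * depth over one segment's valid voxels."""

    segment_id: int
    beta0: float
    beta1: float
    r2: float
    n: int
    ok: bool = True
    reason: str = ""


def fit_transmural_profile(
    ha: HAMap,
    depth: DepthMap,
    segments: SegmentModel,
    segment_id: int,
    min_points: int = 10,
    n_depth_bins: int | None = None,
) -> TransmuralFit:
    """Fit the transmural HA profile of one segment by ordinary least squares.

    ``y`` is the helical angle and ``x`` the normalized wall depth; beta1 is
    the total HA gradient over the wall and beta0 the (endocardial)
    intercept. With ``n_depth_bins`` set, the fit uses per-bin mean HA at
    bin-centre depths instead of all voxels. Too few points or zero depth
    variance yield a missing-fit record, not an exception.
    """
    sel = (segments.segment_ids == segment_id) & ha.valid & np.isfinite(depth.depth)
    x = depth.depth[sel].astype(np.float64)
    y = ha.ha_deg[sel].astype(np.float64)
    if n_depth_bins:
        bins = np.clip((x * n_depth_bins).astype(int), 0, n_depth_bins - 1)
        centers, means = [], []
        for b in range(n_depth_bins):
            m = bins == b
            if m.any():
                centers.append((b + 0.5) / n_depth_bins)
                means.append(y[m].mean())
        x, y = np.asarray(centers), np.asarray(means)
    n = x.size
    if n < min_points:
        return TransmuralFit(segment_id, np.nan, np.nan, np.nan, int(n), ok=False,
                             reason=f"only {n} valid points (< {min_points})")
    if np.ptp(x) < 1e-9:
        return TransmuralFit(segment_id, np.nan, np.nan, np.nan, int(n), ok=False,
                             reason="zero depth variance")
    beta1, beta0 = np.polyfit(x, y, 1)
    resid = y - (beta0 + beta1 * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return TransmuralFit(segment_id, float(beta0), float(beta1), float(r2), int(n))


def fit_all_segments(
    ha: HAMap,
    depth: DepthMap,
    segments: SegmentModel,
    min_points: int = 10,
    n_depth_bins: int | None = None,
) -> pd.DataFrame:
    """Transmural fits for every segment, as a table (one row per segment)."""
    rows = []
    for sid in range(1, segments.n_segments + 1):
        fit = fit_transmural_profile(ha, depth, segments, sid, min_points, n_depth_bins)
        rows.append(
            {
                "segment_id": sid,
                "category": segments.categories.get(sid, "none"),
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "r2": fit.r2,
                "n": fit.n,
                "ok": fit.ok,
                "reason": fit.reason,
            }
        )
    return pd.DataFrame(rows)


def estimate_orientation(
    volume: Volume3D,
    roi: np.ndarray | None = None,
    sigma_gradient: float = DEFAULT_SIGMA_GRADIENT,
    sigma_window: float = DEFAULT_SIGMA_WINDOW,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
    mask: np.ndarray | None = None,
) -> OrientationField:
    """Convenience: structure tensor + eigendecomposition in one call.

    ``roi`` limits where the eigen-system is computed; ``mask`` (typically
    the same myocardium) switches the tensor to its masked form.
    """
    st = compute_structure_tensor(volume, sigma_gradient, sigma_window, mask=mask)
    return principal_orientations(st, coherence_min, roi=roi)
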