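"""Myocardial disarray index (MDI) and regional summaries.

The MDI scores, per voxel, the uniformity of the local cardiomyocyte
longitudinal direction (the tertiary structure-tensor eigenvector) within
a cubic neighborhood (default side 200 µm). Orientations are axial data
(v and -v are equivalent), so uniformity is measured on the mean dyadic
tensor D = mean(v v^T) over the neighborhood's valid vectors:

    MDI = (3 * lambda_max(D) - 1) / 2, clipped to [0, 1]

which is 1 for perfectly aligned vectors (lambda_max = 1), 0 for an
isotropic distribution (lambda_max = 1/3), invariant under global rotation
and under any per-vector sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import SegmentModel
from .orientation import OrientationField

__all__ = ["MDIMap", "compute_mdi", "mdi_of_vectors", "region_summary"]

DEFAULT_NEIGHBORHOOD_SIDE_UM = 200.0
DEFAULT_MIN_VALID_FRACTION = 0.5


@dataclass
class MDIMap:
    """Per-voxel myocardial disarray index in [0, 1]; NaN where invalid."""

    mdi: np.ndarray
    valid: np.ndarray
    neighborhood_side_um: float
    spacing: tuple[float, float, float]


def _lambda_max_sym3(d6: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of symmetric 3x3 tensors given as (N, 6) channels
    ordered (zz, zy, zx, yy, yx, xx)."""
    m = np.empty(d6.shape[:-1] + (3, 3), dtype=np.float64)
    m[..., 0, 0] = d6[..., 0]
    m[..., 0, 1] = m[..., 1, 0] = d6[..., 1]
    m[..., 0, 2] = m[..., 2, 0] = d6[..., 2]
    m[..., 1, 1] = d6[..., 3]
    m[..., 1, 2] = m[..., 2, 1] = d6[..., 4]
    m[..., 2, 2] = d6[..., 5]
    return np.linalg.eigvalsh(m)[..., -1]


def mdi_of_vectors(vectors: np.ndarray) -> float:
    """MDI of a flat set of unit orientation vectors (axial data)."""
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
        raise ValueError("expected a non-empty (N, 3) array of vectors")
    d = np.einsum("ni,nj->ij", v, v) / v.shape[0]
    lam = np.linalg.eigvalsh(d)[-1]
    return float(np.clip((3.0 * lam - 1.0) / 2.0, 0.0, 1.0))


def compute_mdi(
    orient: OrientationField,
    neighborhood_side_um: float = DEFAULT_NEIGHBORHOOD_SIDE_UM,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> MDIMap:
    """MDI from the tertiary-eigenvector field over cubic neighborhoods.

    The neighborhood side is given in µm and converted to an odd voxel
    count (>= 3). Invalid vectors are excluded from the dyadic average;
    voxels where fewer than ``min_valid_fraction`` of the neighborhood is
    valid are flagged invalid.
    """
    spacing = float(orient.spacing[0])
    k = int(round(neighborhood_side_um / spacing))
    k = max(k + (1 - k % 2), 3)  # odd, >= 3
    v = np.where(orient.valid[..., None], orient.v3, 0.0).astype(np.float32)
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    sums = np.empty(orient.valid.shape + (6,), dtype=np.float32)
    for idx, (i, j) in enumerate(pairs):
        sums[..., idx] = ndimage.uniform_filter(v[..., i] * v[..., j], size=k)
    count = ndimage.uniform_filter(orient.valid.astype(np.float32), size=k)

    frac_valid = count  # uniform_filter already normalizes by k^3
    out_valid = orient.valid & (frac_valid >= min_valid_fraction)
    mdi = np.full(orient.valid.shape, np.nan, dtype=np.float32)
    if out_valid.any():
        d6 = sums[out_valid] / np.maximum(count[out_valid, None], 1e-12)
        lam = _lambda_max_sym3(d6)
        mdi[out_valid] = np.clip((3.0 * lam - 1.0) / 2.0, 0.0, 1.0).astype(np.float32)
    return MDIMap(mdi, out_valid, neighborhood_side_um, orient.spacing)


def region_summary(
    values: np.ndarray,
    segments: SegmentModel,
    group_by: str = "segment",
) -> pd.DataFrame:
    """Median and IQR of a per-voxel map, per segment or per category.

    Quartiles use linear interpolation between order statistics. Per-segment
    values are medians of the segment's valid (finite) voxels; category
    summaries pool the per-segment medians of their segments. Empty groups
    are simply absent from the table.
    """
    if group_by not in {"segment", "category"}:
        raise ValueError("group_by must be 'segment' or 'category'")
    per_segment = []
    for sid in range(1, segments.n_segments + 1):
        vals = values[segments.segment_ids == sid]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        per_segment.append(
            {
                "segment_id": sid,
                "category": segments.categories.get(sid, "none"),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "n_voxels": int(vals.size),
            }
        )
    seg_df = pd.DataFrame(per_segment)
    if group_by == "segment" or seg_df.empty:
        return seg_df
    rows = []
    for cat, sub in seg_df.groupby("category"):
        q1, med, q3 = np.percentile(sub["median"].to_numpy(), [25, 50, 75])
        rows.append(
            {
                "category": cat,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "n_segments": int(len(sub)),
            }
        )
    overall = np.percentile(seg_df["median"].to_numpy(), [25, 50, 75])
    rows.append(
        {
            "category": "overall",
            "median": float(overall[1]),
            "q1": float(overall[0]),
            "q3": float(overall[2]),
            "n_segments": int(len(seg_df)),
        }
    )
    return pd.DataFrame(rows)
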