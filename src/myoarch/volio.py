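"""Reading, writing and pre-processing of 3D image volumes and LV masks.

Internal convention: arrays are indexed ``(z, y, x)`` with slice index first.
Physical coordinates are ``index * spacing`` in micrometres; every µm-unit
quantity downstream goes through the :class:`Volume3D.spacing` triple, which
is stored in the same ``(z, y, x)`` order.

Supported on-disk formats are NIfTI-1 (spacing from the header zooms) and
TIFF stacks (multipage file or a directory of per-slice files) with a
required sidecar JSON ``{"spacing_um": [z, y, x]}`` — plain TIFF has no
reliable 3D spacing convention, so a stack without a sidecar is rejected
rather than silently assumed isotropic.

Masks use the fixed label map ``{0: background, 1: myocardium, 2: cavity}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "Volume3D",
    "LVMask",
    "LABEL_BACKGROUND",
    "LABEL_MYOCARDIUM",
    "LABEL_CAVITY",
    "read_volume",
    "write_volume",
    "normalize_intensity",
]

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_CAVITY = 2

#: NIfTI spatial-unit codes understood on read, as µm per unit.
_NIFTI_UNIT_UM = {0: 1.0, 1: 1.0e6, 2: 1.0e3, 3: 1.0}  # unknown, m, mm, µm


@dataclass
class Volume3D:
    """A 3D scalar grid with isotropic-or-not voxel spacing in µm.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.
    spacing
        Voxel spacing in µm per axis, ``(z, y, x)`` order, strictly positive.
    axis_order
        Convention tag; always ``"zyx"`` for volumes built by this package.
    provenance
        Free-text metadata (source path, processing history).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "zyx"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("Volume3D requires a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.axis_order != "zyx":
            raise ValueError("only the (z, y, x) axis convention is supported")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        """Whether spacing is (numerically) equal along all axes.

        Orientation estimation requires isotropic spacing; anisotropic
        volumes load fine but are refused by those operations.
        """
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-6))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, note: str = "") -> "Volume3D":
        prov = self.provenance + ("; " + note if note else "")
        return replace(self, data=data, provenance=prov)


@dataclass
class LVMask:
    """Labeled grid over {background, myocardium, cavity} sharing a Volume3D geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("LVMask requires a non-empty 3D label array")
        extra = set(np.unique(self.labels)) - {LABEL_BACKGROUND, LABEL_MYOCARDIUM, LABEL_CAVITY}
        if extra:
            raise ValueError(f"unexpected mask labels {sorted(extra)}; allowed are 0/1/2")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def myocardium(self) -> np.ndarray:
        return self.labels == LABEL_MYOCARDIUM

    @property
    def cavity(self) -> np.ndarray:
        return self.labels == LABEL_CAVITY

    def as_volume(self) -> Volume3D:
        return Volume3D(self.labels.astype(np.uint8), self.spacing, provenance=self.provenance)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "spacing.json"
    return path.with_suffix(path.suffix + ".json")


def _read_tiff_stack(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
        if not slices:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        arrays = [tifffile.imread(p) for p in slices]
        shapes = {a.shape for a in arrays}
        dtypes = {a.dtype for a in arrays}
        if len(shapes) > 1 or len(dtypes) > 1:
            raise ValueError(
                f"inconsistent TIFF stack in {path}: shapes {shapes}, dtypes {dtypes}"
            )
        data = np.stack(arrays, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF, got ndim={data.ndim}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing spacing sidecar {sidecar}; TIFF stacks require "
            '{"spacing_um": [z, y, x]} because spacing is load-bearing for all µm outputs'
        )
    meta = json.loads(sidecar.read_text())
    spacing = tuple(float(s) for s in meta["spacing_um"])
    return data, spacing


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    unit_code = int(img.header["xyzt_units"]) & 0x07
    scale = _NIFTI_UNIT_UM.get(unit_code, 1.0)
    # NIfTI stores (x, y, z) fastest-first; flip to the internal (z, y, x).
    spacing = tuple(float(z) * scale for z in zooms[::-1])
    return np.transpose(data, (2, 1, 0)), spacing


def read_volume(path: str | Path, format: str | None = None) -> Volume3D:
    """Read a 3D volume from a TIFF stack or NIfTI file.

    ``format`` is ``"tiff-stack"`` or ``"nifti"``; when omitted it is inferred
    from the file suffix (directories are treated as per-slice TIFF stacks).
    Voxel values are preserved losslessly; missing spacing metadata is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir() or path.suffix.lower() in {".tif", ".tiff"}:
            format = "tiff-stack"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format=")
    if format == "tiff-stack":
        data, spacing = _read_tiff_stack(path)
    elif format == "nifti":
        data, spacing = _read_nifti(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing} in {path}")
    return Volume3D(data, spacing, provenance=f"read:{path}")


def write_volume(volume: Volume3D, path: str | Path, format: str | None = None) -> None:
    """Write a volume (inverse of :func:`read_volume`; lossless for integer dtypes)."""
    path = Path(path)
    if format is None:
        if path.suffix.lower() in {".tif", ".tiff"}:
            format = "tiff-stack"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format=")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tiff-stack":
        tifffile.imwrite(path, volume.data, photometric="minisblack")
        _sidecar_path(path).write_text(json.dumps({"spacing_um": list(volume.spacing)}))
    elif format == "nifti":
        # back to NIfTI's (x, y, z); zooms in µm with the micron unit code
        data = np.transpose(volume.data, (2, 1, 0))
        affine = np.diag([*volume.spacing[::-1], 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(volume.spacing[::-1])
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def write_mask(mask: LVMask, path: str | Path, format: str | None = None) -> None:
    """Write an LV mask as an unsigned-integer volume (labels 0/1/2)."""
    write_volume(mask.as_volume(), path, format=format)


def read_mask(path: str | Path, format: str | None = None) -> LVMask:
    vol = read_volume(path, format=format)
    return LVMask(np.rint(vol.data).astype(np.uint8), vol.spacing, provenance=vol.provenance)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def normalize_intensity(volume: Volume3D, low_pct: float = 1.0, high_pct: float = 99.0) -> Volume3D:
    """Robust percentile contrast normalization to [0, 1].

    The ``low_pct``/``high_pct`` intensity percentiles map linearly to 0 and
    1; values beyond them are clipped. Rank order is preserved between the
    clip points. A constant volume cannot be windowed: it maps to all zeros
    and a warning is emitted instead of an exception.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"require 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    data = volume.data.astype(np.float64)
    lo, hi = np.percentile(data, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn(
            f"degenerate intensity window [{lo}, {hi}] (constant volume?); output is all zeros",
            stacklevel=2,
        )
        out = np.zeros_like(data, dtype=np.float32)
    else:
        out = np.clip((data - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    return volume.with_data(out, note=f"normalized pct ({low_pct}, {high_pct})")
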