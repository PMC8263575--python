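"""End-to-end analysis pipeline and its run configuration.

The pipeline chains: input (phantom generation, or a volume plus a mask or
sparse contours) -> intensity normalization -> LV geometry (axis, frames,
volumes/mass, thickness, depth, segments, categories) -> structure-tensor
orientation (HA map, transmural fits) -> disarray (MDI map, regional
summaries) -> report tables and a manifest with content hashes. Fully
deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import disarray, geometry, orientation, phantom, stats_report, volio

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("myoarch")


class PipelineError(RuntimeError):
    """An error in a named pipeline stage (partial outputs are retained)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys are rejected).

    Exactly one input source must be set: ``phantom_spec`` (inline dict or
    path to a spec JSON), or ``volume_path`` with either ``mask_path`` or
    ``contours_path``. Parameter defaults match the module-level defaults.
    """

    model_config = ConfigDict(extra="forbid")

    phantom_spec: dict | str | None = None
    volume_path: str | None = None
    mask_path: str | None = None
    contours_path: str | None = None

    sigma_gradient: float = orientation.DEFAULT_SIGMA_GRADIENT
    sigma_window: float = orientation.DEFAULT_SIGMA_WINDOW
    coherence_min: float = orientation.DEFAULT_COHERENCE_MIN
    neighborhood_side_um: float = disarray.DEFAULT_NEIGHBORHOOD_SIDE_UM
    min_valid_fraction: float = disarray.DEFAULT_MIN_VALID_FRACTION
    n_levels: int = 5
    n_sectors: int = 9
    density_g_per_ml: float = geometry.DEFAULT_DENSITY_G_PER_ML
    normalize_percentiles: tuple[float, float] = (1.0, 99.0)
    alpha: float = stats_report.ALPHA
    mi_segment_ids: list[int] = Field(default_factory=list)

    output_dir: str = "myoarch_out"
    seed: int = 0
    write_volumes: bool = True  # write NIfTI intermediates (maps can be large)

    @model_validator(mode="after")
    def _check_source(self) -> "RunConfig":
        has_phantom = self.phantom_spec is not None
        has_volume = self.volume_path is not None
        if has_phantom == has_volume:
            raise ValueError("exactly one of phantom_spec or volume_path must be set")
        if has_volume and (self.mask_path is None) == (self.contours_path is None):
            raise ValueError("volume input needs exactly one of mask_path or contours_path")
        return self


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %-14s %6.1f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written).

    Every intermediate artifact is written under ``config.output_dir``:
    mask, thickness/depth/HA/MDI maps (NIfTI), per-segment tables (CSV),
    volumes report and manifest (JSON).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    truth = None

    @_stage("input")
    def load_input():
        if config.phantom_spec is not None:
            spec_obj = config.phantom_spec
            if isinstance(spec_obj, str):
                spec = phantom.PhantomSpec.from_json(spec_obj)
            else:
                spec = phantom.PhantomSpec.from_json(json.dumps(spec_obj))
            ph = phantom.generate_phantom(spec)
            return ph.volume, ph.mask, ph
        vol = volio.read_volume(config.volume_path)
        if config.mask_path is not None:
            mask = volio.read_mask(config.mask_path)
        else:
            contours = geometry.ContourSet.from_json(config.contours_path)
            mask = geometry.interpolate_mask_from_contours(contours, vol.shape)
        return vol, mask, None

    volume, mask, truth = load_input()

    @_stage("normalize")
    def normalize():
        lo, hi = config.normalize_percentiles
        return volio.normalize_intensity(volume, lo, hi)

    volume_n = normalize()

    @_stage("geometry")
    def run_geometry():
        axis = geometry.fit_heart_axis(mask)
        frames = geometry.local_cardiac_frames(mask, axis)
        volumes = geometry.compute_volumes_and_mass(mask, config.density_g_per_ml)
        thickness = geometry.compute_wall_thickness(mask, frames)
        depth = geometry.normalized_wall_depth(mask, frames)
        segments = geometry.assign_segments(mask, frames, config.n_levels, config.n_sectors)
        mi_ids = config.mi_segment_ids
        if not mi_ids and truth is not None:
            mi_ids = list(truth.truth_segments.mi_ids)
        segments = geometry.derive_segment_categories(segments, mi_ids)
        return frames, volumes, thickness, depth, segments

    frames, volumes, thickness, depth, segments = run_geometry()

    @_stage("orientation")
    def run_orientation():
        orient = orientation.estimate_orientation(
            volume_n,
            roi=mask.myocardium,
            sigma_gradient=config.sigma_gradient,
            sigma_window=config.sigma_window,
            coherence_min=config.coherence_min,
            mask=mask.myocardium,
        )
        ha = orientation.helical_angle_map(orient, frames)
        fits = orientation.fit_all_segments(ha, depth, segments)
        return orient, ha, fits

    orient, ha, fits = run_orientation()

    @_stage("disarray")
    def run_disarray():
        mdi = disarray.compute_mdi(
            orient, config.neighborhood_side_um, config.min_valid_fraction
        )
        per_segment = disarray.region_summary(mdi.mdi, segments, group_by="segment")
        per_category = disarray.region_summary(mdi.mdi, segments, group_by="category")
        return mdi, per_segment, per_category

    mdi, mdi_per_segment, mdi_per_category = run_disarray()

    @_stage("report")
    def write_report():
        spacing = mask.spacing
        thick_table = thickness.per_segment_mm(segments)
        thick_table.to_csv(out / "thickness_per_segment.csv", index=False)
        outputs["thickness_per_segment"] = str(out / "thickness_per_segment.csv")
        fits.to_csv(out / "transmural_fits.csv", index=False)
        outputs["transmural_fits"] = str(out / "transmural_fits.csv")
        mdi_per_segment.to_csv(out / "mdi_per_segment.csv", index=False)
        outputs["mdi_per_segment"] = str(out / "mdi_per_segment.csv")
        mdi_per_category.to_csv(out / "mdi_per_category.csv", index=False)
        outputs["mdi_per_category"] = str(out / "mdi_per_category.csv")
        segments.to_table().to_csv(out / "segments.csv", index=False)
        outputs["segments"] = str(out / "segments.csv")
        (out / "volumes.json").write_text(json.dumps(volumes.to_dict(), indent=2))
        outputs["volumes"] = str(out / "volumes.json")

        summary = {
            "volumes": volumes.to_dict(),
            "mean_wall_thickness_mm": float(np.nanmean(thick_table["thickness_mm"])),
            "n_valid_ha_voxels": int(ha.valid.sum()),
            "median_mdi": float(np.nanmedian(mdi.mdi[mdi.valid])) if mdi.valid.any() else None,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        outputs["summary"] = str(out / "summary.json")

        if config.write_volumes:
            volio.write_mask(mask, out / "mask.nii.gz")
            outputs["mask"] = str(out / "mask.nii.gz")
            for name, arr in (
                ("thickness_um", thickness.thickness_um),
                ("depth", depth.depth),
                ("ha_deg", ha.ha_deg),
                ("mdi", mdi.mdi),
            ):
                vol = volio.Volume3D(arr, spacing, provenance=name)
                volio.write_volume(vol, out / f"{name}.nii.gz")
                outputs[name] = str(out / f"{name}.nii.gz")
        return summary

    write_report()

    manifest = stats_report.run_manifest(
        config.model_dump(mode="json"), outputs, seed=config.seed
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
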