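"""End-to-end run configuration and execution.

``run_pipeline`` ties the stages together in the order a carotid TOF-MRA
study uses them: read -> (normalize) -> wall extraction -> morphological
cleanup -> SIG -> (cross-section sampling) -> export, and emits a JSON-safe
run report with the normalization stats, iso value used, point counts,
flagged-point counts, a wall-SIG summary and a wall-clock breakdown.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError, TofsigError
from . import volume_io
from .normalization import normalize_volume
from .sig_core import compute_sig
from .wall_geometry import (
    clean_components,
    extract_wall,
    remove_small_voxel_components,
    suggest_threshold,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``iso_value`` / ``auto_iso`` must be set.  Sampling is
    performed only when ``axis_point`` and ``axis_direction`` are given.
    """

    input: str | Path | None = None
    format: str | None = None  # nifti | dicom_series | None (auto)
    normalize: bool = True
    mask: str | Path | None = None
    iso_value: float | None = None
    auto_iso: bool = False
    offset_d: float = 0.03
    min_component_voxels: int = 27
    min_component_vertices: int = 0
    axis_point: Sequence[float] | None = None
    axis_direction: Sequence[float] | None = None
    n_levels: int = 6
    level_spacing: float = 2.5
    sites_per_level: int = 12
    reference_azimuth: Sequence[float] | None = None
    out_mesh: str | Path | None = None
    out_csv: str | Path | None = None
    out_table: str | Path | None = None
    report: str | Path | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.iso_value is None) == (not self.auto_iso):
            raise ParameterError("set exactly one of iso_value / auto_iso")
        if self.offset_d <= 0:
            raise ParameterError("offset_d must be positive")
        if self.level_spacing <= 0:
            raise ParameterError("level_spacing must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def run_pipeline(cfg: RunConfig, volume: "volume_io.Volume | None" = None) -> dict:
    """Execute the configured pipeline and return the run report.

    ``volume`` may be passed directly (e.g. a freshly generated phantom)
    instead of ``cfg.input``.  On failure, partially written outputs are
    removed and the stage error is re-raised with its stage name.
    """
    cfg.validate()
    report: dict = {"config": _jsonable(dataclasses.asdict(cfg)), "stages": {}}
    outputs = [p for p in (cfg.out_mesh, cfg.out_csv, cfg.out_table, cfg.report) if p]
    t_all = time.perf_counter()
    try:
        stage = "read"
        t0 = time.perf_counter()
        if volume is None:
            if cfg.input is None:
                raise ParameterError("no input volume")
            volume = volume_io.read_volume(cfg.input, cfg.format)
        report["volume"] = {"shape": list(volume.shape), "spacing": list(volume.spacing)}
        report["stages"][stage] = time.perf_counter() - t0

        stage = "normalize"
        t0 = time.perf_counter()
        if cfg.normalize:
            mask = None
            if cfg.mask is not None:
                mask = volume_io.read_volume(cfg.mask).data > 0
            volume, stats = normalize_volume(volume, mask=mask)
            report["normalization"] = stats.to_dict()
        else:
            report["normalization"] = None
        report["stages"][stage] = time.perf_counter() - t0

        stage = "threshold"
        t0 = time.perf_counter()
        if cfg.auto_iso:
            suggestion = suggest_threshold(volume)
            report["threshold_suggestion"] = suggestion.to_dict()
            if not suggestion.ok:
                raise TofsigError(
                    f"auto-iso failed: {suggestion.diagnostics.get('reason')}"
                )
            iso = float(suggestion.value)
        else:
            iso = float(cfg.iso_value)
        report["iso_value"] = iso
        report["stages"][stage] = time.perf_counter() - t0

        stage = "wall_extraction"
        t0 = time.perf_counter()
        if cfg.min_component_voxels > 0:
            volume_clean = remove_small_voxel_components(
                volume, iso, cfg.min_component_voxels
            )
        else:
            volume_clean = volume
        mesh = extract_wall(volume_clean, iso)
        if cfg.min_component_vertices > 0:
            mesh = clean_components(mesh, cfg.min_component_vertices)
        from .wall_geometry import mesh_component_labels

        mesh.component_id = mesh_component_labels(mesh)
        report["n_vertices"] = mesh.n_vertices
        report["n_components"] = int(mesh.component_id.max()) + 1 if mesh.n_vertices else 0
        report["stages"][stage] = time.perf_counter() - t0

        stage = "sig"
        t0 = time.perf_counter()
        wps = compute_sig(volume, mesh, d=cfg.offset_d)
        summary = wps.summary()
        report["sig_summary"] = summary
        report["n_flagged_points"] = summary["n_flat"] + summary["n_out_of_bounds"]
        components = {}
        for c in np.unique(mesh.component_id):
            sel = (mesh.component_id == c) & wps.valid
            vals = wps.sig_scalar[sel]
            components[int(c)] = {
                "n": int(vals.size),
                "sig_mean": float(vals.mean()) if vals.size else float("nan"),
                "sig_sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
        report["per_component"] = components
        report["stages"][stage] = time.perf_counter() - t0

        stage = "sampling"
        t0 = time.perf_counter()
        table = None
        if cfg.axis_point is not None and cfg.axis_direction is not None:
            from .sampling_stats import sample_cross_sections

            table = sample_cross_sections(
                wps,
                axis_point=cfg.axis_point,
                axis_direction=cfg.axis_direction,
                n_levels=cfg.n_levels,
                level_spacing=cfg.level_spacing,
                sites_per_level=cfg.sites_per_level,
                reference_azimuth=cfg.reference_azimuth,
            )
            report["sampling"] = {
                "n_rows": int(len(table.frame)),
                "missing_levels": table.missing_levels,
            }
        report["stages"][stage] = time.perf_counter() - t0

        stage = "export"
        t0 = time.perf_counter()
        if cfg.out_mesh:
            volume_io.write_wall_map(mesh.with_sig(wps.sig_scalar), cfg.out_mesh)
        if cfg.out_csv:
            wps.to_dataframe().to_csv(cfg.out_csv, index=False)
        if cfg.out_table and table is not None:
            table.to_csv(cfg.out_table)
        report["stages"][stage] = time.perf_counter() - t0
        report["elapsed_s"] = time.perf_counter() - t_all

        if cfg.report:
            with open(cfg.report, "w") as fh:
                json.dump(_jsonable(report), fh, indent=2)
        return _jsonable(report)
    except Exception as exc:
        for p in outputs:
            Path(p).unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays and paths to JSON types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
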