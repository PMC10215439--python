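"""End-to-end driver: indices -> thickness -> regions -> statistics.

``run_pipeline`` takes a :class:`PipelineConfig` pointing at a lumen
surface, an outer ILT surface and a WSS series, and writes per-vertex
overlays (VTP), tabular reports (CSV/JSON) and a provenance block that
echoes the full effective configuration. Outputs are deterministic:
identical config and inputs give byte-identical reports.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .io import read_surface, read_wss_series, write_indices_csv, write_surface
from .regions import (
    ThresholdConfig,
    classify_flow_nature,
    growth_potential_report,
    make_roi,
    split_ilt,
    extreme_ilt_regions,
    threshold_maps,
)
from .thickness import DEFAULT_WALL_MASK_MM, compute_thickness, patch_to_surface
from .wss import IndexConfig, compute_all_indices

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    lumen_path: str
    wss_path: str
    outer_path: str | None = None
    output_dir: str = "."
    roi_z_bounds: tuple[float, float] | None = None
    roi_labels_path: str | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    index_config: IndexConfig = field(default_factory=IndexConfig)
    wall_mask_mm: float = DEFAULT_WALL_MASK_MM
    distance_mode: str = "vertex"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the in-memory products (indices, thickness,
    masks, report DataFrame) and the paths written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    lumen = _stage("read_lumen")(read_surface)(config.lumen_path)
    wss = _stage("read_wss")(read_wss_series)(config.wss_path, lumen)

    if config.roi_labels_path is not None:
        labels = np.loadtxt(config.roi_labels_path, dtype=int).astype(bool)
        roi = _stage("roi")(make_roi)(lumen, labels=labels)
    elif config.roi_z_bounds is not None:
        roi = _stage("roi")(make_roi)(lumen, z_bounds=tuple(config.roi_z_bounds))
    else:
        roi = make_roi(lumen, labels=np.ones(lumen.n_vertices, dtype=bool))

    indices = _stage("indices")(compute_all_indices)(
        wss, config.index_config, roi=roi.selected
    )

    if config.outer_path is None:
        raise PipelineError(
            "stage 'thickness' failed: no outer ILT surface configured"
        )
    outer = _stage("read_outer")(read_surface)(config.outer_path)
    thickness = _stage("thickness")(compute_thickness)(
        lumen, outer, wall_mask=config.wall_mask_mm, mode=config.distance_mode
    )

    cfg = config.thresholds
    parts = _stage("regions")(split_ilt)(thickness, cfg, roi)
    extremes = _stage("regions")(extreme_ilt_regions)(thickness, cfg, roi)
    fav = _stage("regions")(threshold_maps)(indices, cfg, roi)
    if indices.ntranswss is not None:
        flow_labels, flow_table = _stage("regions")(classify_flow_nature)(
            indices, cfg, roi
        )
    else:
        flow_labels, flow_table = None, None

    report = _stage("stats")(growth_potential_report)(indices, thickness, cfg, roi)

    # -- outputs --------------------------------------------------------------
    overlay = patch_to_surface(thickness)
    for name, arr in indices.as_dict().items():
        overlay.point_data[name] = arr
    overlay.point_data["ROI"] = roi.selected.astype(float)
    for name, mask in {**parts, **extremes, **fav}.items():
        overlay.point_data[name] = mask.selected.astype(float)
    if flow_labels is not None:
        overlay.point_data["flow_class"] = flow_labels.astype(float)

    paths = {
        "overlay_vtp": out / "overlay.vtp",
        "indices_csv": out / "indices.csv",
        "report_csv": out / "report.csv",
        "report_json": out / "report.json",
        "provenance_json": out / "provenance.json",
    }
    write_surface(overlay, paths["overlay_vtp"])
    write_indices_csv(indices, paths["indices_csv"])
    report.to_csv(paths["report_csv"], index=False)

    report_payload = {
        "config": config.to_dict(),
        "regions": {m.name: m.vertex_count for m in
                    [roi, *parts.values(), *extremes.values(), *fav.values()]},
        "report": report.to_dict(orient="records"),
    }
    if flow_table is not None:
        report_payload["flow_nature"] = flow_table.to_dict(orient="records")
    paths["report_json"].write_text(
        json.dumps(report_payload, indent=2, default=float) + "\n"
    )
    provenance = {
        "package": "thrombomap",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    paths["provenance_json"].write_text(
        json.dumps(provenance, indent=2, default=float) + "\n"
    )

    return {
        "indices": indices,
        "thickness": thickness,
        "roi": roi,
        "regions": {**parts, **extremes, **fav},
        "flow_table": flow_table,
        "report": report,
        "paths": {k: str(v) for k, v in paths.items()},
    }
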