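"""End-to-end orchestration: inputs -> phi_M, phi_P, phi_F -> OM -> traces.

The pipeline composes the stage functions through their file formats
(TIFF orientation maps, HDF5 stacks, JSON geometry, CSV traces), writes
a config snapshot and a stage log alongside the outputs, and is
idempotent for identical configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, fusion, intensity, jansonius, polarization, tracing
from .core import AxialAngleMap, RetinalGeometry

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run.

    Numeric defaults follow the study settings: projection band cap
    ``maxlen`` 15 voxels, structure-tensor half-window 7 px, background
    window 145 px, offset search in 1-degree steps, tracing step 1 px,
    ONH entry radius 4 degrees.
    """

    geometry: str = None  # JSON path
    psoct: str = None  # HDF5 stack (intensity/retardation/axis + boundaries)
    projection: str = None  # precomputed projection TIFF (alternative input)
    vessels: str = None  # binary vessel-mask TIFF
    seeds: str = None  # seeds CSV (id,x_deg,y_deg) — default: bundled 24-2 grid
    reference_traces: str = None  # traces.json bundle for agreement reports
    out_dir: str = "run_out"
    eye: str = "auto"

    maxlen: int = 15
    bg_window: int = 145
    tensor_halfwin: int = 7
    neighbor_halfwin: int = 7
    weight_window: int = 15
    smooth_halfwin: int = 30
    onh_exclusion_deg: float = 6.0
    band_inner_deg: float = 5.0
    band_outer_deg: float = 10.0
    ofs_step_deg: float = 1.0
    fuse_smooth_window: int = 15
    step_px: float = 1.0
    max_steps: int = 20000
    traces_per_degree: float = 1.0
    #: rescale the pixel-valued windows from the instrument grid (8.2 um)
    #: to the actual grid spacing of the inputs
    scale_windows: bool = True
    seed: int = 0

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _read_mask_tiff(path):
    import tifffile

    return tifffile.imread(path) > 0


def run_pipeline(config: RunConfig):
    """Run every stage the configured inputs allow; return the output dir.

    Emits ``phiM.tif``, ``phiF.tif``, ``phiP.tif`` (when polarization
    input exists), ``OM.tif``, ``fusion.json``, a trace bundle, and —
    when reference traces are supplied — an agreement report.  Missing
    polarization input degrades gracefully to phi_F + model fusion and
    is logged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = []

    def stage(name, fn, *a, **kw):
        try:
            result = fn(*a, **kw)
        except Exception as e:  # noqa: BLE001 — name the failing stage
            raise PipelineError(name, str(e)) from e
        log.append({"stage": name, "ok": True})
        return result

    if config.geometry is None:
        raise PipelineError("inputs", "a geometry JSON is required")
    geometry = stage("geometry", RetinalGeometry.load, config.geometry)
    fit = stage(
        "fit_model", jansonius.fit_to_eye, geometry.fovea_xy, geometry.onh_xy, geometry, config.eye
    )

    # ---- phi_P: polarization ------------------------------------------
    phi_p = None
    stack = None
    if config.psoct:
        stack = stage("load_psoct", polarization.load_psoct_h5, config.psoct)
        maps = stage(
            "orient_polarization",
            polarization.extract_polarization_maps,
            stack,
            spacing_x=geometry.spacing_x,
            spacing_y=geometry.spacing_y,
        )
        phi_p = maps.axis
        phi_p.save(out / "phiP.tif")
        import tifffile

        tifffile.imwrite(out / "retardation.tif", maps.retardation.astype(np.float32))
    else:
        log.append({"stage": "orient_polarization", "ok": True, "skipped": "no PS-OCT input"})

    # ---- projection ----------------------------------------------------
    vessel_mask = _read_mask_tiff(config.vessels) if config.vessels else None
    if config.projection:
        import tifffile

        proj = intensity.ProjectionImage(
            values=tifffile.imread(config.projection).astype(float),
            vessel_mask=vessel_mask,
            max_len=config.maxlen,
            spacing_x=geometry.spacing_x,
            spacing_y=geometry.spacing_y,
        )
    elif stack is not None:
        proj = stage(
            "project_rnfl",
            intensity.project_rnfl,
            stack.intensity,
            stack.boundaries,
            config.maxlen,
            vessel_mask,
            geometry.spacing_x,
            geometry.spacing_y,
        )
    else:
        raise PipelineError("inputs", "need either a PS-OCT stack or a projection image")

    # ---- phi_M ---------------------------------------------------------
    phi_m = stage(
        "fit_model_raster",
        jansonius.rasterize_model,
        fit,
        proj.shape,
        config.traces_per_degree,
    )
    phi_m.save(out / "phiM.tif")

    # ---- phi_F ---------------------------------------------------------
    win = {
        "tensor_halfsize": config.tensor_halfwin,
        "neighbor_halfsize": config.neighbor_halfwin,
        "weight_window": config.weight_window,
        "smooth_halfsize": config.smooth_halfwin,
        "bg_window": config.bg_window,
    }
    if config.scale_windows:
        win = intensity.scaled_parameters(geometry.spacing_x)
    chain = stage(
        "orient_intensity",
        intensity.estimate_intensity_orientation,
        proj,
        phi_m,
        geometry.fovea_xy,
        win["tensor_halfsize"],
        win["neighbor_halfsize"],
        win["weight_window"],
        win["smooth_halfsize"],
        win["bg_window"],
        geometry,
        config.onh_exclusion_deg,
    )
    phi_f = chain["phi_f"]
    phi_f.save(out / "phiF.tif")

    # ---- fusion --------------------------------------------------------
    fusion_info = {"offset_applied": False}
    if phi_p is not None:
        ofs = stage(
            "axis_offset",
            fusion.find_axis_offset,
            phi_p,
            phi_f,
            geometry,
            config.band_inner_deg,
            config.band_outer_deg,
            config.ofs_step_deg,
        )
        phi_p = fusion.apply_offset(phi_p, ofs.ofs_deg)
        fusion_info = {
            "offset_applied": True,
            "ofs_deg": ofs.ofs_deg,
            "n_pixels": ofs.n_pixels,
            "objective_curve": ofs.objective_curve,
        }
    else:
        # no polarization source: an all-invalid placeholder lets phi_F
        # carry the fusion on its own, with model fill elsewhere
        phi_p = AxialAngleMap(
            values=np.zeros(phi_f.shape),
            valid=np.zeros(phi_f.shape, dtype=bool),
            spacing_x=phi_f.spacing_x,
            spacing_y=phi_f.spacing_y,
        )
        log.append({"stage": "axis_offset", "ok": True, "skipped": "no polarization map"})
    w_p = fusion.source_weight(phi_p, phi_m)
    w_f = fusion.source_weight(phi_f, phi_m)
    om, model_filled = stage(
        "fuse", fusion.fuse_maps, phi_p, phi_f, w_p, w_f, phi_m, config.fuse_smooth_window
    )
    om.save(out / "OM.tif")
    fusion_info["model_filled_px"] = int(model_filled.sum())
    with open(out / "fusion.json", "w") as fh:
        json.dump(fusion_info, fh, indent=2)

    # ---- tracing -------------------------------------------------------
    if config.seeds:
        import pandas as pd

        seed_df = pd.read_csv(config.seeds)
    else:
        seed_df = evaluation.load_vf_grid().points
    if {"x_px", "y_px"}.issubset(seed_df.columns):
        seeds_px = seed_df[["x_px", "y_px"]].to_numpy(dtype=float)
    else:
        vf = evaluation.VFGrid(
            points=seed_df
            if "sector" in seed_df.columns
            else seed_df.assign(sector="T")
        )
        seeds_px = vf.seed_points_px(fit)
    traces, ids = [], []
    h, w = om.shape
    for (x, y), pid in zip(seeds_px, seed_df["id"]):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            continue
        tr = tracing.trace_through_point(
            (float(x), float(y)), om, geometry, r_px=config.step_px, max_steps=config.max_steps
        )
        traces.append(tr)
        ids.append(pid)
    stage("trace", tracing.save_traces, traces, out / "traces", ids)

    # ---- evaluation ----------------------------------------------------
    if config.reference_traces:
        ref = tracing.load_traces(config.reference_traces)
        ref_polar = {}
        for pid, tr in zip(ids, ref):
            try:
                ref_polar[pid] = evaluation.to_polar(tr, geometry)
            except ValueError:
                pass
        ours = {}
        for pid, tr in zip(ids, traces):
            try:
                ours[pid] = evaluation.to_polar(tr, geometry)
            except ValueError:
                pass
        vf_grid = evaluation.load_vf_grid()
        report = stage(
            "evaluate",
            evaluation.build_report,
            {"auto": ours, "reference": ref_polar},
            vf_grid,
            geometry,
        )
        report.save(out / "report.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report.rows, fh, indent=2)

    config.save(out / "config_snapshot.yaml")
    with open(out / "stages.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out
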