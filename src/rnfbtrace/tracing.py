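"""Streamline integration of an orientation map into fiber-bundle traces.

An axial orientation map assigns each position a line direction, not a
heading: at every step two antipodal candidate moves

    (x', y') = (x, y) +- r * (cos OM(x, y), sin OM(x, y))

exist, and the tracer picks one.  Tracing *inward* (periphery toward the
ONH, candidate with minimum distance to the ONH center) is the robust
mode: bundle paths converge on the ONH, so orientation errors shrink
along the way, whereas outward traces diverge.  A trace through a point
of interest is assembled from an outward and an inward sub-trace.

Positions are kept in micrometres internally so steps are isotropic
despite anisotropic pixel spacing; ``Trace.points`` are pixel
coordinates and the step length is exact in the physical frame.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AxialAngleMap, RetinalGeometry

__all__ = [
    "Trace",
    "step",
    "trace_inward",
    "trace_outward",
    "trace_through_point",
    "save_traces",
    "load_traces",
]


@dataclass
class Trace:
    """Ordered polyline of a traced fiber bundle.

    ``points`` is an (N, 2) array of (x, y) pixel coordinates ordered
    periphery -> ONH for inward and combined traces.  ``step_px`` is the
    step length in units of the x pixel pitch; consecutive points are
    exactly one step apart in the physical frame.  ``termination`` is one
    of ``onh_reached``, ``boundary``, ``invalid_pixel``, ``max_steps``.
    """

    points: np.ndarray
    step_px: float
    seed: tuple
    direction_mode: str
    termination: str

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self):
        return len(self.points)

    def points_um(self, geometry: RetinalGeometry):
        return self.points * np.array([geometry.spacing_x, geometry.spacing_y])

    def arc_length_um(self, geometry: RetinalGeometry):
        if len(self.points) < 2:
            return 0.0
        d = np.diff(self.points_um(geometry), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _sample_direction(om: AxialAngleMap, pos_um):
    """Axial direction at a micrometre position; None when off the valid set."""
    x_px = pos_um[0] / om.spacing_x
    y_px = pos_um[1] / om.spacing_y
    h, w = om.shape
    if not (0.0 <= x_px <= w - 1 and 0.0 <= y_px <= h - 1):
        return None, "boundary"
    ang, ok = om.sample(x_px, y_px)
    if not ok:
        return None, "invalid_pixel"
    return ang, None


def step(pos, om: AxialAngleMap, r_px, choose, onh_xy, prev_heading=None):
    """One integration step from pixel position ``pos``.

    Picks between the two antipodal candidates by ``choose``
    (``"min_dist"`` / ``"max_dist"`` w.r.t. the ONH center ``onh_xy``);
    once a previous heading exists the candidate continuing that heading
    wins (prevents 180-degree oscillation near the raphe, where the two
    candidates can be nearly equidistant).

    Returns ``(new_pos_px, heading_unit_um)``.  Raises if ``pos`` lies on
    an invalid pixel.
    """
    sp = np.array([om.spacing_x, om.spacing_y])
    pos_um = np.asarray(pos, dtype=float) * sp
    ang, why = _sample_direction(om, pos_um)
    if ang is None:
        raise ValueError(f"cannot step from {tuple(pos)}: {why}")
    d = np.array([np.cos(ang), np.sin(ang)])
    r_um = r_px * om.spacing_x
    cands = [pos_um + r_um * d, pos_um - r_um * d]
    if prev_heading is not None:
        dots = [float(np.dot(d, prev_heading)), float(np.dot(-d, prev_heading))]
        pick = int(np.argmax(dots))
    else:
        onh_um = np.asarray(onh_xy, dtype=float) * sp
        dists = [float(np.linalg.norm(c - onh_um)) for c in cands]
        pick = int(np.argmin(dists)) if choose == "min_dist" else int(np.argmax(dists))
    heading = (cands[pick] - pos_um) / r_um
    return cands[pick] / sp, heading


def _integrate(seed, om, geometry, r_px, max_steps, choose, mode):
    sx, sy = om.spacing_x, om.spacing_y
    ox_um, oy_um = geometry.onh_um
    r_onh_um = geometry.onh_radius_um
    r_um = r_px * sx
    sampler = om.sampler()
    h, w = om.shape
    x, y = float(seed[0]), float(seed[1])
    pts = [(x, y)]
    if choose == "min_dist" and math.hypot(x * sx - ox_um, y * sy - oy_um) <= r_onh_um:
        return Trace(np.empty((0, 2)), r_px, tuple(seed), mode, "onh_reached")
    hx = hy = None
    termination = "max_steps"
    for _ in range(int(max_steps)):
        ang, ok = sampler(x, y)
        if not ok:
            termination = (
                "boundary" if not (0 <= x <= w - 1 and 0 <= y <= h - 1) else "invalid_pixel"
            )
            break
        ux_um, uy_um = x * sx, y * sy
        dx_um, dy_um = r_um * math.cos(ang), r_um * math.sin(ang)
        if hx is not None:
            # continue the previous heading (anti-reversal rule)
            if dx_um * hx + dy_um * hy < 0:
                dx_um, dy_um = -dx_um, -dy_um
        else:
            d_plus = math.hypot(ux_um + dx_um - ox_um, uy_um + dy_um - oy_um)
            d_minus = math.hypot(ux_um - dx_um - ox_um, uy_um - dy_um - oy_um)
            flip = d_plus > d_minus if choose == "min_dist" else d_plus < d_minus
            if flip:
                dx_um, dy_um = -dx_um, -dy_um
        # midpoint refinement: re-sample the axial direction halfway along
        # the chosen displacement and step along it (aligned with the
        # choice already made); the step length stays exactly r and the
        # first-order curvature bias of plain Euler integration drops out
        mang, mok = sampler((ux_um + 0.5 * dx_um) / sx, (uy_um + 0.5 * dy_um) / sy)
        if mok:
            mdx, mdy = r_um * math.cos(mang), r_um * math.sin(mang)
            if mdx * dx_um + mdy * dy_um < 0:
                mdx, mdy = -mdx, -mdy
            dx_um, dy_um = mdx, mdy
        hx, hy = dx_um, dy_um
        x, y = (ux_um + dx_um) / sx, (uy_um + dy_um) / sy
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            termination = "boundary"
            break
        pts.append((x, y))
        if choose == "min_dist" and math.hypot(x * sx - ox_um, y * sy - oy_um) <= r_onh_um:
            termination = "onh_reached"
            break
    return Trace(np.array(pts), r_px, tuple(seed), mode, termination)


def trace_inward(seed, om: AxialAngleMap, geometry: RetinalGeometry, r_px=1.0, max_steps=20000) -> Trace:
    """Trace from ``seed`` toward the ONH; stops on entering the ONH entry
    circle, leaving the valid region, or after ``max_steps``."""
    return _integrate(seed, om, geometry, r_px, max_steps, "min_dist", "inward")


def trace_outward(seed, om: AxialAngleMap, geometry: RetinalGeometry, r_px=1.0, max_steps=20000) -> Trace:
    """Trace from ``seed`` away from the ONH (the divergent direction)."""
    return _integrate(seed, om, geometry, r_px, max_steps, "max_dist", "outward")


def trace_through_point(seed, om: AxialAngleMap, geometry: RetinalGeometry, r_px=1.0, max_steps=20000) -> Trace:
    """Bidirectional trace through a point of interest.

    The outward sub-trace is reversed and concatenated with the inward
    sub-trace so that points run periphery -> ONH and the seed appears
    exactly once.
    """
    outward = trace_outward(seed, om, geometry, r_px=r_px, max_steps=max_steps)
    inward = trace_inward(seed, om, geometry, r_px=r_px, max_steps=max_steps)
    if len(outward) > 1:
        pts = np.vstack([outward.points[::-1][:-1], inward.points])
    else:
        pts = inward.points
    return Trace(pts, r_px, tuple(seed), "bidirectional", inward.termination)


# ---------------------------------------------------------------------------
# trace bundles on disk: one CSV polyline per trace plus a JSON manifest
# ---------------------------------------------------------------------------


def save_traces(traces, out_dir, ids=None):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, tr in enumerate(traces):
        tid = str(ids[i]) if ids is not None else f"{i:04d}"
        fname = f"trace_{tid}.csv"
        with open(out_dir / fname, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["x_px", "y_px"])
            wr.writerows(np.round(tr.points, 6).tolist())
        manifest.append(
            {
                "id": tid,
                "file": fname,
                "seed": list(tr.seed),
                "step_px": tr.step_px,
                "direction_mode": tr.direction_mode,
                "termination": tr.termination,
                "n_points": len(tr),
            }
        )
    with open(out_dir / "traces.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir / "traces.json"


def load_traces(bundle_json):
    bundle_json = Path(bundle_json)
    with open(bundle_json) as fh:
        manifest = json.load(fh)
    traces = []
    for entry in manifest:
        pts = np.loadtxt(bundle_json.parent / entry["file"], delimiter=",", skiprows=1)
        traces.append(
            Trace(
                points=pts,
                step_px=entry["step_px"],
                seed=tuple(entry["seed"]),
                direction_mode=entry["direction_mode"],
                termination=entry["termination"],
            )
        )
    return traces
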