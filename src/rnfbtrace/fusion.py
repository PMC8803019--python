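"""Axis-offset calibration and weighted merging of orientation sources.

The polarization axis ``phi_P`` is a *relative* orientation (it derives
from the phase difference of the two OCT detection channels), so before
merging it with the intensity-derived map ``phi_F`` a global angular
offset must be found.  A broad circular band around the ONH is taken and
``phi_P + ofs`` is compared against ``phi_F`` by the sum of squared
differences of the doubled-angle sine and cosine components, for integer
offsets from -90 to +90 degrees; the minimizing offset is applied.

The calibrated ``phi_P`` and ``phi_F`` are then fused into the final
orientation map ``OM`` by a weighted axial mean, with per-source weights
measuring each source's local agreement with the trajectory model map
``phi_M`` (the model acts as referee, never as a direct source).  Where
neither source is usable the model itself is blended in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    AxialAngleMap,
    RetinalGeometry,
    WeightMap,
    axial_distance,
    components_to_angle,
    fold_axial,
)

__all__ = [
    "OffsetSearchResult",
    "find_axis_offset",
    "apply_offset",
    "source_weight",
    "fuse_maps",
]


@dataclass
class OffsetSearchResult:
    """Result of the exhaustive axis-offset search.

    ``ofs_deg`` minimizes the objective; ``objective_curve`` holds all
    181 ``(offset_deg, sum_of_squared_differences)`` pairs.
    ``n_pixels`` is the number of jointly valid band pixels used.
    """

    ofs_deg: float
    objective_curve: list
    n_pixels: int


def find_axis_offset(
    phi_p: AxialAngleMap,
    phi_f: AxialAngleMap,
    geometry: RetinalGeometry,
    band_inner_deg=5.0,
    band_outer_deg=10.0,
    step_deg=1.0,
    min_pixels=100,
) -> OffsetSearchResult:
    """Search the global axis offset of ``phi_P`` against ``phi_F``.

    Evaluates, for each offset in [-90, +90] degrees at ``step_deg``
    increments, the sum over jointly valid annulus pixels
    (``band_inner_deg`` to ``band_outer_deg`` eccentricity from the ONH
    center) of the squared doubled-component differences between
    ``phi_P + ofs`` and ``phi_F``.
    """
    if phi_p.shape != phi_f.shape:
        raise ValueError("maps must share a shape")
    h, w = phi_p.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ecc = geometry.eccentricity_deg(xx, yy)
    band = (ecc >= band_inner_deg) & (ecc <= band_outer_deg)
    joint = band & phi_p.valid & phi_f.valid
    n = int(joint.sum())
    if n < min_pixels:
        raise ValueError(
            f"axis-offset search needs >= {min_pixels} jointly valid band pixels, got {n}"
        )
    p = phi_p.values[joint]
    f = phi_f.values[joint]
    sf, cf = np.sin(2 * f), np.cos(2 * f)
    offsets = np.arange(-90.0, 90.0 + step_deg / 2, step_deg)
    curve = []
    for ofs in offsets:
        shifted = 2 * (p + np.deg2rad(ofs))
        obj = float(np.sum((np.sin(shifted) - sf) ** 2 + (np.cos(shifted) - cf) ** 2))
        curve.append((float(ofs), obj))
    best = min(curve, key=lambda t: t[1])
    return OffsetSearchResult(ofs_deg=best[0], objective_curve=curve, n_pixels=n)


def apply_offset(phi_p: AxialAngleMap, ofs_deg) -> AxialAngleMap:
    """Add a global offset (degrees) to an orientation map."""
    out = phi_p.copy()
    out.values = np.where(
        out.valid, fold_axial(out.values + np.deg2rad(ofs_deg)), 0.0
    )
    return out


def source_weight(phi: AxialAngleMap, phi_m: AxialAngleMap) -> WeightMap:
    """Per-pixel agreement of a source map with the model map.

    ``W = 1 - d/2`` with ``d`` the doubled-angle component distance:
    1 where the source matches the model, 0 where perpendicular or where
    the source is invalid.
    """
    if phi.shape != phi_m.shape:
        raise ValueError("maps must share a shape")
    d = axial_distance(phi.values, phi_m.values)
    w = 1.0 - 0.5 * d
    w = np.where(phi.valid & phi_m.valid, w, 0.0)
    return WeightMap(values=np.clip(w, 0.0, 1.0))


def fuse_maps(
    phi_p: AxialAngleMap,
    phi_f: AxialAngleMap,
    w_p: WeightMap,
    w_f: WeightMap,
    phi_m: AxialAngleMap = None,
    smoothing_window=15,
    blend_ramp_px=10,
):
    """Fuse the calibrated source maps into the final orientation map ``OM``.

    The weight maps are smoothed with a sliding average filter, then the
    doubled-angle components of the two sources are combined in a
    weighted mean.  Where exactly one source is valid the output equals
    that source; where neither is (or the weighted resultant vanishes,
    e.g. perpendicular sources of equal weight) the model map fills in,
    blended over ``blend_ramp_px`` pixels at the validity boundary to
    avoid orientation seams.

    Returns ``(om, model_filled)`` — the fused map and the boolean mask
    of model-filled pixels (empty where no model map was given).
    """
    if phi_p.shape != phi_f.shape:
        raise ValueError("maps must share a shape")
    wp = ndimage.uniform_filter(
        np.where(phi_p.valid, w_p.values, 0.0), size=smoothing_window, mode="constant"
    )
    wf = ndimage.uniform_filter(
        np.where(phi_f.valid, w_f.values, 0.0), size=smoothing_window, mode="constant"
    )
    # smoothing can leak weight onto invalid pixels; a source only ever
    # contributes where it is itself valid
    wp = np.where(phi_p.valid, wp, 0.0)
    wf = np.where(phi_f.valid, wf, 0.0)
    # a valid lone source must win even if its smoothed weight is zero
    lone_p = phi_p.valid & ~phi_f.valid & (wp <= 0)
    lone_f = phi_f.valid & ~phi_p.valid & (wf <= 0)
    wp = np.where(lone_p, 1.0, wp)
    wf = np.where(lone_f, 1.0, wf)

    sp, cp = phi_p.components()
    sf, cf = phi_f.components()
    s = wp * sp + wf * sf
    c = wp * cp + wf * cf
    total = wp + wf
    resultant = np.hypot(s, c)
    fused_ok = (total > 1e-12) & (resultant > 1e-9 * np.maximum(total, 1e-12))
    values = np.where(fused_ok, components_to_angle(s, c), 0.0)

    model_filled = ~fused_ok
    if phi_m is None:
        om = AxialAngleMap(
            values=values,
            valid=fused_ok,
            spacing_x=phi_p.spacing_x,
            spacing_y=phi_p.spacing_y,
        )
        return om, np.zeros(om.shape, dtype=bool)

    if phi_m.shape != phi_p.shape:
        raise ValueError("model map must share the shape of the sources")
    # blend fused orientations into the model across the validity boundary
    sm, cm = phi_m.components()
    if fused_ok.any():
        dist, (iy, ix) = ndimage.distance_transform_edt(~fused_ok, return_indices=True)
        t = np.clip(dist / max(blend_ramp_px, 1e-9), 0.0, 1.0)
        s_near, c_near = s[iy, ix], c[iy, ix]
        nrm = np.hypot(s_near, c_near)
        nrm = np.where(nrm > 1e-12, nrm, 1.0)
        s_fill = (1.0 - t) * s_near / nrm + t * sm
        c_fill = (1.0 - t) * c_near / nrm + t * cm
    else:
        s_fill, c_fill = sm, cm
    fill_ok = model_filled & phi_m.valid & (np.hypot(s_fill, c_fill) > 1e-12)
    values = np.where(fill_ok, components_to_angle(s_fill, c_fill), values)
    om = AxialAngleMap(
        values=values,
        valid=fused_ok | fill_ok,
        spacing_x=phi_p.spacing_x,
        spacing_y=phi_p.spacing_y,
    )
    return om, model_filled & om.valid
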