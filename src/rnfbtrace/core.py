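"""Axial-angle algebra and the shared 2-D field containers.

An *axial* angle is an orientation defined modulo 180 degrees — a line
direction, not a vector heading.  Retinal nerve fiber bundles have no
intrinsic "forward", so every orientation map in this package stores axial
angles in radians in ``[0, pi)``.  All averaging, interpolation and
distance computation happens on the doubled-angle unit vectors
``(sin 2*phi, cos 2*phi)``: doubling maps the half-circle of orientations
onto the full circle, where ordinary vector arithmetic applies, and the
result is halved back.

Conventions
-----------
* Arrays are indexed ``[y, x]`` (row = y).  An angle ``phi`` denotes the
  direction ``(dx, dy) = (cos phi, sin phi)`` measured counterclockwise
  from the +x image axis, in the *physical* (micrometre) frame, so that
  orientations stay meaningful under anisotropic pixel spacing.
* Invalid pixels are carried as mask bits, never as sentinel angles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "AxialAngleMap",
    "WeightMap",
    "RetinalGeometry",
    "axial_mean",
    "axial_distance",
    "rotate_map",
    "fold_axial",
    "components_to_angle",
    "angle_to_components",
    "masked_window_mean",
]


def fold_axial(angles):
    """Reduce angles (radians) to the axial range ``[0, pi)``."""
    return np.mod(angles, np.pi)


def angle_to_components(angles):
    """Doubled-angle unit components ``(sin 2*phi, cos 2*phi)``."""
    a2 = 2.0 * np.asarray(angles, dtype=float)
    return np.sin(a2), np.cos(a2)


def components_to_angle(s, c):
    """Half-angle of the doubled-angle vector ``(s, c)``, folded to ``[0, pi)``.

    ``s`` and ``c`` need not be normalized; only the direction matters.
    """
    return fold_axial(0.5 * np.arctan2(s, c))


def axial_mean(angles, weights=None):
    """Weighted mean of axial angles via doubled-angle vector summation.

    Parameters
    ----------
    angles : array-like of float
        Axial angles in radians (any branch; values are used mod pi).
    weights : array-like of float, optional
        Nonnegative weights, same shape.  Defaults to uniform.

    Returns
    -------
    float
        The axial mean in ``[0, pi)``: the half-angle of the weighted
        resultant of the doubled-angle unit vectors.

    Raises
    ------
    ValueError
        If no weight is positive, or the resultant vector vanishes (the
        mean orientation is undefined, e.g. two perpendicular inputs of
        equal weight).
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    if angles.shape != weights.shape:
        raise ValueError("angles and weights must have the same shape")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(weights > 0):
        raise ValueError("axial mean undefined: all weights are zero")
    s, c = angle_to_components(angles)
    rs = float(np.sum(weights * s))
    rc = float(np.sum(weights * c))
    if np.hypot(rs, rc) < 1e-12 * float(np.sum(weights)):
        raise ValueError("axial mean undefined: zero resultant vector")
    return float(components_to_angle(rs, rc))


def axial_distance(a, b):
    """Euclidean distance between doubled-angle unit vectors, in ``[0, 2]``.

    Equals ``2 * |sin(a - b)|``: zero iff the orientations coincide
    (mod pi), maximal (2) at 90 degrees separation.  Broadcasts.
    """
    sa, ca = angle_to_components(a)
    sb, cb = angle_to_components(b)
    return np.hypot(sa - sb, ca - cb)


@dataclass
class AxialAngleMap:
    """2-D field of axial orientations with a validity mask.

    Attributes
    ----------
    values : ndarray, shape (H, W)
        Axial orientation in radians, ``[0, pi)`` on valid pixels.
        Invalid pixels carry no meaningful angle.
    valid : ndarray of bool, shape (H, W)
    spacing_x, spacing_y : float
        Micrometres per pixel along x (columns) and y (rows).
    """

    values: np.ndarray
    valid: np.ndarray
    spacing_x: float = 1.0
    spacing_y: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")
        if self.values.ndim != 2:
            raise ValueError("AxialAngleMap is 2-D")
        folded = fold_axial(self.values)
        self.values = np.where(self.valid, folded, 0.0)

    @property
    def shape(self):
        return self.values.shape

    def components(self):
        """(sin 2*phi, cos 2*phi); zero on invalid pixels."""
        s, c = angle_to_components(self.values)
        v = self.valid
        return np.where(v, s, 0.0), np.where(v, c, 0.0)

    def copy(self) -> "AxialAngleMap":
        return replace(self, values=self.values.copy(), valid=self.valid.copy())

    # -- continuous sampling -------------------------------------------------

    def sample(self, x, y):
        """Bilinear doubled-angle sample at fractional pixel positions.

        Returns ``(angles, ok)`` where ``ok`` is True only where every
        contributing pixel is valid and inside the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        coords = np.stack([np.atleast_1d(y), np.atleast_1d(x)])
        s, c = self.components()
        si = ndimage.map_coordinates(s, coords, order=1, mode="constant", cval=0.0)
        ci = ndimage.map_coordinates(c, coords, order=1, mode="constant", cval=0.0)
        vi = ndimage.map_coordinates(
            self.valid.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        ok = vi > 0.999
        ang = components_to_angle(si, ci)
        if np.isscalar(x.tolist()) or x.ndim == 0:
            return float(ang[0]), bool(ok[0])
        return ang, ok

    def sampler(self) -> "FieldSampler":
        """A fast repeated-sampling handle (snapshot of the current state)."""
        return FieldSampler(self)

    # -- I/O -------------------------------------------------------------

    def save(self, path):
        """Write as 2-channel float32 TIFF (sin 2*phi, cos 2*phi) plus an
        8-bit validity TIFF at ``<stem>.valid.tif``."""
        import tifffile

        path = Path(path)
        s, c = self.components()
        tifffile.imwrite(
            path,
            np.stack([s, c]).astype(np.float32),
            metadata={
                "spacing_x": self.spacing_x,
                "spacing_y": self.spacing_y,
                "channels": "sin2phi,cos2phi",
            },
        )
        tifffile.imwrite(
            path.with_suffix(".valid.tif"),
            (self.valid.astype(np.uint8) * 255),
        )

    @classmethod
    def load(cls, path, spacing_x=None, spacing_y=None) -> "AxialAngleMap":
        import tifffile

        path = Path(path)
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        s, c = arr[0].astype(float), arr[1].astype(float)
        vpath = path.with_suffix(".valid.tif")
        if vpath.exists():
            valid = tifffile.imread(vpath) > 127
        else:
            valid = np.hypot(s, c) > 1e-6
        return cls(
            values=components_to_angle(s, c),
            valid=valid,
            spacing_x=float(spacing_x if spacing_x is not None else meta.get("spacing_x", 1.0)),
            spacing_y=float(spacing_y if spacing_y is not None else meta.get("spacing_y", 1.0)),
        )


@dataclass
class WeightMap:
    """2-D grid of dimensionless weights in ``[0, 1]``."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class RetinalGeometry:
    """Eye geometry anchoring the en-face coordinate frame.

    ``fovea_xy`` and ``onh_xy`` are pixel coordinates ``(x, y)``.
    ``onh_radius_deg`` is the radius of the optic-nerve-head entry circle
    (default 4 degrees); ``um_per_deg`` the retinal scale (1 degree of
    scanning angle = 300 micrometres by default).
    """

    fovea_xy: tuple
    onh_xy: tuple
    onh_radius_deg: float = 4.0
    um_per_deg: float = 300.0
    spacing_x: float = 1.0
    spacing_y: float = 1.0

    def __post_init__(self):
        self.fovea_xy = (float(self.fovea_xy[0]), float(self.fovea_xy[1]))
        self.onh_xy = (float(self.onh_xy[0]), float(self.onh_xy[1]))
        if self.onh_radius_deg <= 0:
            raise ValueError("onh_radius_deg must be positive")
        if self.um_per_deg <= 0:
            raise ValueError("um_per_deg must be positive")
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.fovea_xy == self.onh_xy:
            raise ValueError("fovea and ONH centers must differ")

    # physical-frame helpers ------------------------------------------------

    def to_um(self, xy_px):
        """Pixel coordinates (x, y) -> micrometre coordinates."""
        xy = np.asarray(xy_px, dtype=float)
        return xy * np.array([self.spacing_x, self.spacing_y])

    def to_px(self, xy_um):
        xy = np.asarray(xy_um, dtype=float)
        return xy / np.array([self.spacing_x, self.spacing_y])

    @property
    def fovea_um(self):
        return self.to_um(self.fovea_xy)

    @property
    def onh_um(self):
        return self.to_um(self.onh_xy)

    @property
    def onh_radius_um(self):
        return self.onh_radius_deg * self.um_per_deg

    def eccentricity_deg(self, x_px, y_px):
        """Distance from the ONH center, in degrees, at pixel positions."""
        dx = (np.asarray(x_px, dtype=float) - self.onh_xy[0]) * self.spacing_x
        dy = (np.asarray(y_px, dtype=float) - self.onh_xy[1]) * self.spacing_y
        return np.hypot(dx, dy) / self.um_per_deg

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "fovea_xy": list(self.fovea_xy),
                    "onh_xy": list(self.onh_xy),
                    "onh_radius_deg": self.onh_radius_deg,
                    "um_per_deg": self.um_per_deg,
                    "spacing_um": [self.spacing_x, self.spacing_y],
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path) -> "RetinalGeometry":
        with open(path) as fh:
            d = json.load(fh)
        sx, sy = d.get("spacing_um", [1.0, 1.0])
        return cls(
            fovea_xy=tuple(d["fovea_xy"]),
            onh_xy=tuple(d["onh_xy"]),
            onh_radius_deg=d.get("onh_radius_deg", 4.0),
            um_per_deg=d.get("um_per_deg", 300.0),
            spacing_x=sx,
            spacing_y=sy,
        )


def rotate_map(m: AxialAngleMap, alpha: float, center) -> AxialAngleMap:
    """Rotate an orientation map by ``alpha`` radians about ``center`` (x, y).

    The grid is resampled by the rotation *and* each orientation value is
    incremented by ``alpha`` (mod pi): rotating an orientation field moves
    the lines and turns them.  Resampling is bilinear on the doubled-angle
    components; the validity mask is transported conservatively (a target
    pixel is valid only if all contributing source pixels were).
    """
    cy, cx = float(center[1]), float(center[0])
    h, w = m.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    ca, sa = np.cos(-alpha), np.sin(-alpha)
    # inverse mapping: output pixel -> source position
    dx, dy = xx - cx, yy - cy
    src_x = cx + ca * dx - sa * dy
    src_y = cy + sa * dx + ca * dy
    coords = np.stack([src_y, src_x])
    s, c = m.components()
    si = ndimage.map_coordinates(s, coords, order=1, mode="constant", cval=0.0)
    ci = ndimage.map_coordinates(c, coords, order=1, mode="constant", cval=0.0)
    vi = ndimage.map_coordinates(
        m.valid.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    # angle increment: rotate the doubled-angle vector by 2*alpha
    c2, s2 = np.cos(2 * alpha), np.sin(2 * alpha)
    s_out = si * c2 + ci * s2
    c_out = ci * c2 - si * s2
    valid = vi > 0.999
    return AxialAngleMap(
        values=np.where(valid, components_to_angle(s_out, c_out), 0.0),
        valid=valid,
        spacing_x=m.spacing_x,
        spacing_y=m.spacing_y,
    )


class FieldSampler:
    """Fast scalar bilinear sampling of an :class:`AxialAngleMap`.

    Snapshot-based: interpolates the doubled-angle components; a sample
    is valid only when every contributing pixel is valid.  Used by the
    tracer, where per-step calls dominate the runtime.
    """

    def __init__(self, m: AxialAngleMap):
        self.s, self.c = m.components()
        self.v = m.valid.astype(float)
        self.h, self.w = m.shape

    def __call__(self, x, y):
        """Return ``(angle, ok)``; ``ok`` False outside the grid or on the
        edge of the valid set."""
        if not (0.0 <= x <= self.w - 1 and 0.0 <= y <= self.h - 1):
            return 0.0, False
        x0 = min(int(x), self.w - 2) if self.w > 1 else 0
        y0 = min(int(y), self.h - 2) if self.h > 1 else 0
        fx, fy = x - x0, y - y0
        w00 = (1 - fx) * (1 - fy)
        w01 = fx * (1 - fy)
        w10 = (1 - fx) * fy
        w11 = fx * fy
        v = self.v
        vi = (
            w00 * v[y0, x0]
            + w01 * v[y0, x0 + 1]
            + w10 * v[y0 + 1, x0]
            + w11 * v[y0 + 1, x0 + 1]
        )
        if vi < 0.999:
            return 0.0, False
        s = self.s
        c = self.c
        si = (
            w00 * s[y0, x0]
            + w01 * s[y0, x0 + 1]
            + w10 * s[y0 + 1, x0]
            + w11 * s[y0 + 1, x0 + 1]
        )
        ci = (
            w00 * c[y0, x0]
            + w01 * c[y0, x0 + 1]
            + w10 * c[y0 + 1, x0]
            + w11 * c[y0 + 1, x0 + 1]
        )
        return 0.5 * math.atan2(si, ci) % math.pi, True


def masked_window_mean(values, mask, size):
    """Sliding-window mean of ``values`` over pixels where ``mask`` is true.

    Pixels outside the mask contribute nothing.  Returns ``(mean, coverage)``
    where ``coverage`` is the fraction of in-mask pixels per window; the
    mean is 0 where the window holds no in-mask pixel.
    """
    mask_f = np.asarray(mask, dtype=float)
    num = ndimage.uniform_filter(np.where(mask, values, 0.0), size=size, mode="constant")
    den = ndimage.uniform_filter(mask_f, size=size, mode="constant")
    mean = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
    return mean, den
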