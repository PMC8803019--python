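"""Parametric average-trajectory model of retinal nerve fiber bundles.

The model describes the path of an average nerve fiber bundle in a polar
frame centered on the optic nerve head (ONH) as

    phi(phi0, r) = phi0 + b(phi0) * (r - r0)**c(phi0)

where ``r`` is the eccentricity from the ONH center in degrees, ``r0`` the
radius of the starting circle (4 degrees), and ``phi0`` the angular
position where the trajectory meets that circle.  ``b`` and ``c`` are
smooth (tanh) functions of ``phi0``, fitted separately for the superior
(``phi0`` in (0, 180), b > 0) and inferior (``phi0`` in (-180, 0), b < 0)
hemifields.

Model frame
-----------
Degrees, fovea at the origin, ONH center at (+15, 0).  The polar angle
``phi`` is measured counterclockwise from the +x axis, i.e. from the
*nasal* horizontal: the fovea sits at ``phi = 180`` on the ONH-centered
circle of radius 15, and the temporal raphe lies along ``phi = +-180``.
Under this convention b > 0 (superior) / b < 0 (inferior) drives both
hemifields' trajectories toward the raphe, as the model intends.  Left
eyes are mirrored into this right-eye frame before fitting and results
are mirrored back.

Fitting to an individual eye uses a similarity transform: the fovea is
matched by translation, then the ONH center by rotation and scaling about
the fixed fovea.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .core import AxialAngleMap, RetinalGeometry, components_to_angle, fold_axial

__all__ = [
    "ONH_ECCENTRICITY_DEG",
    "TrajectoryParams",
    "ModelFit",
    "model_constants",
    "trajectory",
    "trajectory_tangent",
    "fit_to_eye",
    "rasterize_model",
    "find_phi0",
    "trajectory_polyline_px",
]

#: Eccentricity of the ONH center from the fovea in the canonical model frame.
ONH_ECCENTRICITY_DEG = 15.0

_MODEL_ONH = np.array([ONH_ECCENTRICITY_DEG, 0.0])


def model_constants(phi0, hemifield):
    """Model coefficients ``(b, c)`` at starting angle ``phi0`` (degrees).

    Superior hemifield (``phi0`` in (0, 180))::

        c      = 1.9 + 1.4 * tanh((phi0 - 121) / 14)
        ln(b)  = -1.9 + 3.9 * tanh(-(phi0 - 121) / 14)

    Inferior hemifield (``phi0`` in (-180, 0))::

        c      = 1.0 + 0.5 * tanh((-phi0 - 90) / 25)
        ln(-b) = 0.7 + 1.5 * tanh(-(-phi0 - 90) / 25)

    Returns ``b`` positive for superior, negative for inferior; ``c`` is
    always positive.
    """
    phi0 = float(phi0)
    if hemifield == "superior":
        if not 0.0 < phi0 < 180.0:
            raise ValueError(f"superior hemifield requires phi0 in (0, 180), got {phi0}")
        c = 1.9 + 1.4 * np.tanh((phi0 - 121.0) / 14.0)
        b = np.exp(-1.9 + 3.9 * np.tanh(-(phi0 - 121.0) / 14.0))
    elif hemifield == "inferior":
        if not -180.0 < phi0 < 0.0:
            raise ValueError(f"inferior hemifield requires phi0 in (-180, 0), got {phi0}")
        c = 1.0 + 0.5 * np.tanh((-phi0 - 90.0) / 25.0)
        b = -np.exp(0.7 + 1.5 * np.tanh(-(-phi0 - 90.0) / 25.0))
    else:
        raise ValueError(f"unknown hemifield {hemifield!r}")
    return float(b), float(c)


@dataclass
class TrajectoryParams:
    """Coefficients of one average trajectory.

    ``phi0`` in degrees at the starting circle of radius ``r0`` (degrees);
    ``b`` (1/deg**c) and ``c`` (dimensionless) per :func:`model_constants`.
    """

    phi0: float
    b: float
    c: float
    r0: float = 4.0

    @classmethod
    def from_phi0(cls, phi0, r0=4.0) -> "TrajectoryParams":
        hemi = "superior" if phi0 > 0 else "inferior"
        b, c = model_constants(phi0, hemi)
        return cls(phi0=float(phi0), b=b, c=c, r0=float(r0))

    @property
    def hemifield(self):
        return "superior" if self.phi0 > 0 else "inferior"


def trajectory(params: TrajectoryParams, r):
    """Angular position ``phi`` (degrees) of the trajectory at eccentricity ``r``.

    ``phi(r0) = phi0`` exactly; for ``b != 0`` the angle moves monotonically
    toward the raphe with increasing eccentricity.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < params.r0 - 1e-12):
        raise ValueError("trajectory defined for r >= r0 only")
    dr = np.maximum(r - params.r0, 0.0)
    return params.phi0 + params.b * dr ** params.c


def trajectory_tangent(params: TrajectoryParams, r):
    """Axial tangent direction of the trajectory at ``r``, radians, model frame.

    The trajectory point in Cartesian model coordinates is
    ``P(r) = ONH + r * (cos phi(r), sin phi(r))``; the tangent is ``dP/dr``
    reduced modulo pi.  Requires ``r > r0`` (at the starting circle the
    derivative of ``(r - r0)**c`` is singular for c < 1).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= params.r0):
        raise ValueError("tangent defined for r > r0 only")
    dr = r - params.r0
    phi = np.deg2rad(params.phi0 + params.b * dr ** params.c)
    dphi = np.deg2rad(params.b * params.c * dr ** (params.c - 1.0))  # rad per deg of r
    tx = np.cos(phi) - r * np.sin(phi) * dphi
    ty = np.sin(phi) + r * np.cos(phi) * dphi
    return fold_axial(np.arctan2(ty, tx))


def trajectory_point(params: TrajectoryParams, r):
    """Cartesian model-frame point(s) of the trajectory at eccentricity ``r``."""
    r = np.asarray(r, dtype=float)
    phi = np.deg2rad(trajectory(params, r))
    return np.stack([_MODEL_ONH[0] + r * np.cos(phi), _MODEL_ONH[1] + r * np.sin(phi)], axis=-1)


@dataclass
class ModelFit:
    """Similarity transform placing the canonical model frame onto an eye.

    The fovea is matched by translation; the ONH center by rotation and
    scaling about the fovea.  ``mirrored`` marks left eyes folded into the
    right-eye frame.
    """

    geometry: RetinalGeometry
    rotation: float  # radians, image frame
    scale: float  # dimensionless
    mirrored: bool = False

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("degenerate fit: scale must be positive")

    # -- coordinate transforms (model degrees <-> image pixels) ------------

    def _rot(self):
        ca, sa = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[ca, -sa], [sa, ca]])

    def model_to_image_px(self, pts_deg):
        """Map (N, 2) model-frame points (degrees) to image pixel coordinates."""
        p = np.atleast_2d(np.asarray(pts_deg, dtype=float)).copy()
        if self.mirrored:
            p[:, 0] = -p[:, 0]
        g = self.geometry
        um = (self._rot() @ (p.T * (self.scale * g.um_per_deg))).T + g.fovea_um
        return um / np.array([g.spacing_x, g.spacing_y])

    def image_px_to_model(self, pts_px):
        """Inverse of :meth:`model_to_image_px`."""
        g = self.geometry
        um = np.atleast_2d(np.asarray(pts_px, dtype=float)) * np.array(
            [g.spacing_x, g.spacing_y]
        )
        p = (self._rot().T @ (um - g.fovea_um).T).T / (self.scale * g.um_per_deg)
        if self.mirrored:
            p[:, 0] = -p[:, 0]
        return p

    def model_angle_to_image(self, theta_rad):
        """Transport a model-frame (axial) angle into the image frame.

        Rotating the frame by alpha adds alpha to orientation values;
        mirroring maps theta to pi - theta.
        """
        theta = np.asarray(theta_rad, dtype=float)
        if self.mirrored:
            theta = np.pi - theta
        return fold_axial(theta + self.rotation)


def fit_to_eye(fovea_xy, onh_xy, geometry: RetinalGeometry, eye="auto") -> ModelFit:
    """Fit the model frame to an eye's fovea and ONH landmarks.

    ``eye`` is ``"right"``, ``"left"`` (mirrored into the right-eye frame)
    or ``"auto"`` (mirrored when the ONH lies to the left of the fovea,
    i.e. toward -x).  The transformed model fovea lands exactly on
    ``fovea_xy`` and the model ONH center on ``onh_xy``.
    """
    fovea_xy = (float(fovea_xy[0]), float(fovea_xy[1]))
    onh_xy = (float(onh_xy[0]), float(onh_xy[1]))
    if fovea_xy == onh_xy:
        raise ValueError("fovea and ONH landmarks coincide")
    geometry = RetinalGeometry(
        fovea_xy=fovea_xy,
        onh_xy=onh_xy,
        onh_radius_deg=geometry.onh_radius_deg,
        um_per_deg=geometry.um_per_deg,
        spacing_x=geometry.spacing_x,
        spacing_y=geometry.spacing_y,
    )
    delta = geometry.onh_um - geometry.fovea_um
    dist = float(np.hypot(*delta))
    if eye == "auto":
        mirrored = delta[0] < 0
    elif eye in ("right", "left"):
        mirrored = eye == "left"
    else:
        raise ValueError(f"unknown eye {eye!r}")
    rotation = float(np.arctan2(delta[1], delta[0]))
    if mirrored:
        rotation -= np.pi  # model ONH sits at (-15, 0) after mirroring
    scale = dist / (ONH_ECCENTRICITY_DEG * geometry.um_per_deg)
    return ModelFit(geometry=geometry, rotation=rotation, scale=scale, mirrored=mirrored)


def _trace_phi0_grid(traces_per_degree):
    step = 1.0 / float(traces_per_degree)
    sup = np.arange(step / 2.0, 180.0, step)
    return np.concatenate([sup, -sup])


def trajectory_polyline_px(fit: ModelFit, phi0, r_max, dr=0.25, r0=4.0):
    """Sample one model trajectory as an image-space pixel polyline.

    Returns ``(points_px (N,2), tangents_rad (N,), r_deg (N,))``, sampled
    from just outside the starting circle outward; the polyline is clipped
    where the angular position crosses the temporal raphe (|phi| > 180).
    """
    params = TrajectoryParams.from_phi0(phi0, r0=r0)
    rs = np.arange(r0 + dr, r_max + dr, dr)
    if rs.size == 0:
        return np.empty((0, 2)), np.empty(0), np.empty(0)
    phis = trajectory(params, rs)
    keep = np.abs(phis) <= 180.0
    if not keep.all():
        stop = int(np.argmin(keep))
        rs, phis = rs[:stop], phis[:stop]
    if rs.size == 0:
        return np.empty((0, 2)), np.empty(0), np.empty(0)
    pts = trajectory_point(params, rs)
    tang = trajectory_tangent(params, rs)
    return fit.model_to_image_px(pts), fit.model_angle_to_image(tang), rs


def rasterize_model(
    fit: ModelFit,
    shape,
    traces_per_degree=1.0,
    dr=0.25,
    gather_radius_deg=1.0,
    k_neighbors=12,
    r0=4.0,
) -> AxialAngleMap:
    """Rasterize the fitted model into an orientation map (phi_M).

    Traces are generated at ``traces_per_degree`` starting angles around
    the ONH and their tangent orientations scattered onto the pixel grid
    by inverse-distance weighting of the doubled-angle components within
    ``gather_radius_deg`` (model degrees) of each pixel.  Pixels farther
    than that from every trace sample are invalid.
    """
    h, w = int(shape[0]), int(shape[1])
    g = fit.geometry
    # eccentricity needed to cover the image corners, in model degrees
    corners_px = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    corners_model = fit.image_px_to_model(corners_px)
    r_max = float(np.max(np.linalg.norm(corners_model - _MODEL_ONH, axis=1))) + 2.0

    pts_all, ang_all = [], []
    for phi0 in _trace_phi0_grid(traces_per_degree):
        pts, tang, _ = trajectory_polyline_px(fit, phi0, r_max, dr=dr, r0=r0)
        if len(pts):
            pts_all.append(pts)
            ang_all.append(tang)
    pts_px = np.concatenate(pts_all)
    angles = np.concatenate(ang_all)

    # work in micrometres so the gather radius is isotropic
    sp = np.array([g.spacing_x, g.spacing_y])
    pts_um = pts_px * sp
    radius_um = gather_radius_deg * g.um_per_deg * fit.scale

    inside = (
        (pts_px[:, 0] > -gather_radius_deg * 5)
        & (pts_px[:, 0] < w + gather_radius_deg * 5)
        & (pts_px[:, 1] > -gather_radius_deg * 5)
        & (pts_px[:, 1] < h + gather_radius_deg * 5)
    )
    pts_um, angles = pts_um[inside], angles[inside]
    if len(pts_um) == 0:
        raise ValueError("no model trace samples fall inside the image")

    tree = cKDTree(pts_um)
    yy, xx = np.mgrid[0:h, 0:w]
    grid_um = np.stack([xx.ravel() * sp[0], yy.ravel() * sp[1]], axis=1)
    dists, idx = tree.query(grid_um, k=k_neighbors, distance_upper_bound=radius_um)
    if k_neighbors == 1:
        dists, idx = dists[:, None], idx[:, None]
    hit = np.isfinite(dists)
    idx_safe = np.where(hit, idx, 0)
    wgt = np.where(hit, 1.0 / (dists + 1e-3 * radius_um), 0.0)
    s2 = np.sin(2 * angles)[idx_safe]
    c2 = np.cos(2 * angles)[idx_safe]
    rs = np.sum(wgt * s2, axis=1)
    rc = np.sum(wgt * c2, axis=1)
    valid = hit.any(axis=1)
    values = components_to_angle(rs, rc)
    return AxialAngleMap(
        values=np.where(valid, values, 0.0).reshape(h, w),
        valid=valid.reshape(h, w),
        spacing_x=g.spacing_x,
        spacing_y=g.spacing_y,
    )


def find_phi0(fit: ModelFit, point_px, r0=4.0, scan_step=0.25):
    """Starting angle ``phi0`` of the model trajectory through an image point.

    Inverts ``phi(phi0, r_s) = phi_s`` for the point's ONH-centered polar
    coordinates in the model frame, scanning the hemifield implied by the
    point's angular position and refining the bracketing interval with a
    root finder.  Returns ``None`` when the point lies inside the starting
    circle or no trajectory reaches it.
    """
    p = fit.image_px_to_model(point_px)[0] - _MODEL_ONH
    r_s = float(np.hypot(*p))
    if r_s <= r0 + 1e-9:
        return None
    phi_s = float(np.degrees(np.arctan2(p[1], p[0])))
    if phi_s == 0.0:
        phi_s = 1e-9
    sign = 1.0 if phi_s > 0 else -1.0

    def g(phi0):
        params = TrajectoryParams.from_phi0(sign * abs(phi0), r0=r0)
        return float(trajectory(params, r_s)) - phi_s

    grid = np.arange(scan_step, 180.0, scan_step)
    vals = np.array([g(sign * x) for x in grid])
    sgn = np.sign(vals)
    crossings = np.nonzero(sgn[:-1] * sgn[1:] <= 0)[0]
    if len(crossings) == 0:
        return None
    # take the crossing whose phi0 is closest to the target angle
    i = crossings[np.argmin(np.abs(grid[crossings] - abs(phi_s)))]
    lo, hi = sign * grid[i], sign * grid[i + 1]
    try:
        root = brentq(g, min(lo, hi), max(lo, hi), xtol=1e-10)
    except ValueError:
        return None
    return float(root)
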