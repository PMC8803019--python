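"""Agreement statistics between trace sets.

Traces are compared in an ONH-centered polar frame.  The *entry angle*
(EA) of a trace is the angular position at which it crosses the ONH
entry circle (radius 4 degrees); agreement between raters (or between
repeated runs, which is formally the same question) is summarized per
Garway-Heath sector by

* EA range — the maximum pairwise circular difference,
* EA offset — the mean circular deviation from the circular mean EA,
* trace RMSE — root-mean-square arc-length difference (micrometres)
  against the reference trace along the shared radial support,
* EA ICC — intraclass correlation ICC(A,k): two-way random effects,
  absolute agreement, average of k raters, after wraparound
  compensation.

Entry angles are reported with 0 degrees at the temporal horizontal
through the ONH, increasing superiorly (right-eye convention).  All
statistics are differences of angles, so the reference direction affects
reported EAs but none of the agreement measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import RetinalGeometry
from .tracing import Trace

__all__ = [
    "PolarTrace",
    "AgreementReport",
    "VFGrid",
    "load_vf_grid",
    "to_polar",
    "circular_difference",
    "circular_mean",
    "entry_angle_stats",
    "icc_ak",
    "trace_rmse",
    "mean_polar_trace",
    "build_report",
]

GARWAY_HEATH_SECTORS = ("T", "ST", "IT", "SN", "IN", "N")


def circular_difference(a, b, period=360.0):
    """Signed wraparound-minimal difference ``a - b`` in (-period/2, period/2]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.where(d > period / 2, d - period, d)


def circular_mean(angles_deg):
    """Circular mean of full-circle angles in degrees.

    Raises when the resultant vector vanishes (mean undefined, e.g.
    angles spread symmetrically around the circle).
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    s, c = np.sum(np.sin(a)), np.sum(np.cos(a))
    if np.hypot(s, c) < 1e-9 * max(len(a), 1):
        raise ValueError("circular mean undefined: zero resultant vector")
    return float(np.degrees(np.arctan2(s, c)) % 360.0)


@dataclass
class PolarTrace:
    """A trace resampled on a fixed radial grid around the ONH center.

    ``r_deg`` is strictly increasing from the entry-circle radius
    outward in steps of ``radial_step``; ``angle_deg`` is the angular
    position, unwrapped along the trace (no 360-degree jumps).
    ``entry_angle`` (degrees in [0, 360)) is defined only when the trace
    reaches the entry circle; ``degenerate`` flags traces with no usable
    radial extent (e.g. circular arcs at fixed radius).
    """

    r_deg: np.ndarray
    angle_deg: np.ndarray
    entry_angle: float = None
    degenerate: bool = False

    @property
    def has_entry(self):
        return self.entry_angle is not None


def _entry_frame(geometry: RetinalGeometry):
    """Unit vectors (temporal, superior) of the EA reference frame."""
    nasal = geometry.onh_um - geometry.fovea_um
    nasal = nasal / np.linalg.norm(nasal)
    return -nasal


def to_polar(trace: Trace, geometry: RetinalGeometry, radial_step=0.1) -> PolarTrace:
    """Resample a trace into the ONH-centered polar frame.

    Points are converted to (eccentricity r in degrees, angular position
    in degrees from the temporal horizontal), the angle is unwrapped
    along the trace, and linearly interpolated onto the fixed radial
    grid ``r = onh_radius, onh_radius + step, ...`` out to the trace's
    maximum eccentricity.  The entry angle is the angle at the entry
    circle, defined only if the trace reaches it.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    d = trace.points_um(geometry) - geometry.onh_um
    r = np.hypot(d[:, 0], d[:, 1]) / geometry.um_per_deg
    temporal = _entry_frame(geometry)
    # angular position: 0 at the temporal horizontal, increasing toward
    # superior.  In the ONH-centered frame rotated so the nasal direction
    # lies along +x, a point at angle phi (counterclockwise from nasal)
    # sits at 180 - phi from temporal.
    rot = math.degrees(math.atan2(-temporal[1], -temporal[0]))
    ang = 180.0 - (np.degrees(np.arctan2(d[:, 1], d[:, 0])) - rot)
    ang = np.degrees(np.unwrap(np.deg2rad(ang)))

    # order ONH-end first so r runs outward, then enforce strict increase
    order = slice(None, None, -1) if r[0] > r[-1] else slice(None)
    r_o, a_o = r[order], ang[order]
    keep_r, keep_a = [], []
    rmax = -np.inf
    for ri, ai in zip(r_o, a_o):
        if ri > rmax + 1e-9:
            keep_r.append(ri)
            keep_a.append(ai)
            rmax = ri
    r0 = geometry.onh_radius_deg
    if len(keep_r) < 2 or keep_r[-1] - keep_r[0] < radial_step:
        return PolarTrace(
            r_deg=np.asarray(keep_r),
            angle_deg=np.asarray(keep_a) % 360.0,
            entry_angle=None,
            degenerate=True,
        )
    keep_r = np.asarray(keep_r)
    keep_a = np.asarray(keep_a)
    grid = np.arange(r0, keep_r[-1] + 1e-9, radial_step)
    grid = grid[(grid >= keep_r[0] - 1e-9)]
    angles = np.interp(grid, keep_r, keep_a)
    reaches = keep_r[0] <= r0 + trace.step_px * 0.5 * max(
        geometry.spacing_x, geometry.spacing_y
    ) / geometry.um_per_deg + 1e-9
    entry = float(np.interp(r0, keep_r, keep_a) % 360.0) if reaches else None
    return PolarTrace(r_deg=grid, angle_deg=angles, entry_angle=entry)


def entry_angle_stats(eas_deg):
    """(range, mean offset) of one group of entry angles, degrees.

    Range is the maximum pairwise circular distance; offset the mean
    circular distance of each EA from the group's circular mean.
    """
    eas = np.asarray(eas_deg, dtype=float)
    if eas.size < 2:
        raise ValueError("need at least two entry angles")
    diffs = np.abs(circular_difference(eas[:, None], eas[None, :]))
    rng = float(np.max(diffs))
    mu = circular_mean(eas)
    offset = float(np.mean(np.abs(circular_difference(eas, mu))))
    return rng, offset


def _unwrap_ea_matrix(matrix):
    """Wraparound compensation for an EA matrix (traces x raters).

    Each trace's EAs are unwrapped to within 180 degrees of that trace's
    circular mean; trace means are then aligned to a common branch so
    between-trace distances are circularly minimal.
    """
    m = np.asarray(matrix, dtype=float)
    out = np.empty_like(m)
    mus = np.empty(m.shape[0])
    for i, row in enumerate(m):
        mu = circular_mean(row)
        mus[i] = mu
        out[i] = mu + circular_difference(row, mu)
    mu_g = circular_mean(mus)
    shift = (mu_g + circular_difference(mus, mu_g)) - mus
    return out + shift[:, None]


def icc_ak(matrix_deg):
    """ICC(A,k) of an entry-angle matrix (rows = traces, cols = raters).

    Two-way random effects, absolute agreement, average of k raters:

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    from the two-way ANOVA mean squares (rows MSR, columns MSC,
    residual MSE), computed after wraparound compensation.
    """
    m = np.asarray(matrix_deg, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 traces and >= 2 raters")
    m = _unwrap_ea_matrix(m)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if ssr < 1e-12:
        raise ValueError("ICC undefined: zero between-trace variance")
    denom = msr + (msc - mse) / n
    if abs(denom) < 1e-30:
        raise ValueError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def trace_rmse(reference: PolarTrace, others, geometry: RetinalGeometry, min_overlap_deg=1.0):
    """Root-mean-square arc-length difference to the reference, micrometres.

    At each shared radial sample the wraparound-minimal angular
    difference is converted to arc length (angle * r * um_per_deg) and
    squared; the per-trace RMSE is averaged over ``others`` (pass a
    single-element list for the one-trace variant).
    """
    if isinstance(others, PolarTrace):
        others = [others]
    rmses = []
    for tr in others:
        lo = max(reference.r_deg[0], tr.r_deg[0])
        hi = min(reference.r_deg[-1], tr.r_deg[-1])
        if hi - lo < min_overlap_deg:
            raise ValueError("insufficient radial overlap between traces")
        step = reference.r_deg[1] - reference.r_deg[0]
        ia = np.nonzero((reference.r_deg >= lo - 1e-9) & (reference.r_deg <= hi + 1e-9))[0]
        ra = reference.r_deg[ia]
        a_ref = reference.angle_deg[ia]
        a_oth = np.interp(ra, tr.r_deg, tr.angle_deg)
        diff_deg = np.abs(circular_difference(a_ref, a_oth))
        arc_um = np.deg2rad(diff_deg) * ra * geometry.um_per_deg
        rmses.append(float(np.sqrt(np.mean(arc_um**2))))
    return float(np.mean(rmses))


def mean_polar_trace(traces, radial_step=0.1):
    """Per-radius circular average of several polar traces (the rater-mean
    reference trace).  Defined on the radial range shared by all."""
    lo = max(t.r_deg[0] for t in traces)
    hi = min(t.r_deg[-1] for t in traces)
    if hi <= lo:
        raise ValueError("traces share no radial support")
    grid = np.arange(lo, hi + 1e-9, radial_step)
    angs = np.stack([np.interp(grid, t.r_deg, t.angle_deg) for t in traces])
    a = np.deg2rad(angs)
    mean = np.degrees(np.arctan2(np.sin(a).mean(axis=0), np.cos(a).mean(axis=0)))
    mean = np.degrees(np.unwrap(np.deg2rad(mean)))
    eas = [t.entry_angle for t in traces if t.has_entry]
    entry = circular_mean(eas) if len(eas) == len(traces) else None
    return PolarTrace(r_deg=grid, angle_deg=mean, entry_angle=entry)


# ---------------------------------------------------------------------------
# 24-2 visual-field grid with Garway-Heath sector labels
# ---------------------------------------------------------------------------


@dataclass
class VFGrid:
    """The 52 non-blind-spot 24-2 visual-field test points.

    ``points`` columns: id, x_deg, y_deg (visual-field coordinates,
    right-eye convention, temporal field positive x, superior positive
    y) and sector (Garway-Heath: T, ST, IT, SN, IN, N).
    """

    points: pd.DataFrame

    def __post_init__(self):
        required = {"id", "x_deg", "y_deg", "sector"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"VF grid needs columns {sorted(required)}")
        bad = set(self.points["sector"]) - set(GARWAY_HEATH_SECTORS)
        if bad:
            raise ValueError(f"unknown sectors {sorted(bad)}")

    def __len__(self):
        return len(self.points)

    def seed_points_px(self, fit):
        """Map VF points into image pixels through a model fit.

        The retinal image is inverted vertically relative to the visual
        field (superior field projects onto inferior retina); the
        horizontal axis carries through (temporal field = nasal retina =
        +x of the model frame, where the blind spot at x = +15 lands on
        the ONH).  Returns an (N, 2) array aligned with ``points``.
        """
        model = np.stack(
            [self.points["x_deg"].to_numpy(), -self.points["y_deg"].to_numpy()], axis=1
        )
        return fit.model_to_image_px(model)


def load_vf_grid(path=None) -> VFGrid:
    """Load the bundled (or a user-supplied) VF grid / sector CSV."""
    if path is None:
        with resources.files("rnfbtrace.data").joinpath(
            "vf24_2_garway_heath.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return VFGrid(points=df)


@dataclass
class AgreementReport:
    """Per-sector and overall agreement statistics (Table-style layout)."""

    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def save(self, path_csv):
        self.to_frame().to_csv(path_csv, index=False)


def build_report(
    polar_traces_by_rater,
    vf: VFGrid,
    geometry: RetinalGeometry,
    reference: dict = None,
) -> AgreementReport:
    """Aggregate agreement statistics over raters, grouped by sector.

    ``polar_traces_by_rater`` maps rater name -> {vf point id ->
    PolarTrace}.  The reference trace per point is the per-radius
    circular mean over raters, or ``reference[point_id]`` when an
    external reference is supplied.  Sectors with fewer than 2 usable
    traces are flagged insufficient.
    """
    raters = sorted(polar_traces_by_rater)
    if len(raters) < 2 and reference is None:
        raise ValueError("need >= 2 raters or an external reference")
    sec_of = dict(zip(vf.points["id"], vf.points["sector"]))
    per_point = {}
    for pid in vf.points["id"]:
        traces = []
        for r in raters:
            t = polar_traces_by_rater[r].get(pid)
            if t is None or t.degenerate or not t.has_entry:
                traces = None
                break
            traces.append(t)
        if not traces:
            continue
        ref = reference[pid] if reference is not None else mean_polar_trace(traces)
        eas = [t.entry_angle for t in traces]
        try:
            rng, off = entry_angle_stats(eas)
        except ValueError:
            continue
        rmse = trace_rmse(ref, traces, geometry)
        per_point[pid] = {"sector": sec_of[pid], "eas": eas, "range": rng, "offset": off, "rmse": rmse}

    report = AgreementReport()
    groups = list(GARWAY_HEATH_SECTORS) + ["Overall"]
    for sector in groups:
        items = [
            v
            for v in per_point.values()
            if sector == "Overall" or v["sector"] == sector
        ]
        row = {"sector": sector, "n_traces": len(items)}
        if len(items) < 2:
            row["insufficient"] = True
            report.rows.append(row)
            continue
        for key, label in (("range", "ea_range"), ("offset", "ea_offset"), ("rmse", "trace_rmse_um")):
            vals = np.array([v[key] for v in items])
            row[f"{label}_mean"] = float(vals.mean())
            row[f"{label}_sd"] = float(vals.std(ddof=1))
        try:
            row["ea_icc"] = icc_ak(np.array([v["eas"] for v in items]))
        except ValueError:
            row["ea_icc"] = float("nan")
        row["insufficient"] = False
        report.rows.append(row)
    return report
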