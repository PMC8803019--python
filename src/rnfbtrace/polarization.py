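"""Depth-averaged Stokes-vector extraction of RNFL retardation and axis.

The retinal nerve fiber layer (RNFL) is birefringent while the layers
beneath it (GCL down to the OPL) are polarization-preserving, so the
cumulative retardation ``delta`` and optic-axis orientation ``theta``
measured *below* the RNFL characterize the RNFL itself.  Per A-scan the
normalized Stokes vector

    (Q, U, V) = (cos 2*delta,
                 sin 2*delta * cos(pi - 2*theta),
                 sin 2*delta * sin(pi - 2*theta))

is averaged over the depth window between the RNFL/GCL boundary and the
OPL/ONL boundary, re-normalized to the unit sphere, and inverted:

    delta_P = arccos(Q_R) / 2
    phi_P   = arctan(-V_R / U_R) / 2     (two-argument form, see note)

Averaging before normalization suppresses noise: the resultant shrinks
where the polarization state fluctuates in depth, which is also used as a
confidence measure.

Quadrant note: the printed single-argument arctangent of ``-V_R/U_R``
loses half the axis range.  We use ``atan2(V_R, -U_R) / 2`` — the same
ratio, with quadrant information kept — which returns exactly ``theta``
for a depth-constant volume of axis ``theta``.  The axis is in any case a
*relative* orientation; the global offset is calibrated during fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AxialAngleMap, fold_axial

__all__ = [
    "LayerBoundaries",
    "PSOCTStack",
    "PolarizationMaps",
    "average_stokes",
    "extract_polarization_maps",
    "load_psoct_h5",
    "save_psoct_h5",
]


@dataclass
class LayerBoundaries:
    """Per-pixel z indices of the segmented retinal surfaces.

    ``ilm`` (inner limiting membrane) <= ``rnfl_gcl`` (RNFL/GCL boundary)
    <= ``opl_onl`` (OPL/ONL boundary) < volume depth, everywhere.
    """

    ilm: np.ndarray
    rnfl_gcl: np.ndarray
    opl_onl: np.ndarray

    def __post_init__(self):
        self.ilm = np.asarray(self.ilm, dtype=int)
        self.rnfl_gcl = np.asarray(self.rnfl_gcl, dtype=int)
        self.opl_onl = np.asarray(self.opl_onl, dtype=int)
        if not (self.ilm.shape == self.rnfl_gcl.shape == self.opl_onl.shape):
            raise ValueError("boundary maps must share a shape")
        if np.any(self.ilm > self.rnfl_gcl) or np.any(self.rnfl_gcl > self.opl_onl):
            raise ValueError("boundaries must satisfy ILM <= RNFL/GCL <= OPL/ONL")

    def validate_depth(self, depth):
        if np.any(self.opl_onl >= depth):
            raise ValueError("OPL/ONL boundary exceeds volume depth")


@dataclass
class PSOCTStack:
    """Co-registered PS-OCT volumes: intensity, retardation, axis.

    Volumes are indexed ``[y, x, z]``; ``retardation`` in [0, pi/2] rad,
    ``axis`` axial in [0, pi) rad.
    """

    intensity: np.ndarray
    retardation: np.ndarray
    axis: np.ndarray
    boundaries: LayerBoundaries

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.retardation = np.asarray(self.retardation, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if not (self.intensity.shape == self.retardation.shape == self.axis.shape):
            raise ValueError("intensity, retardation and axis volumes must share a shape")
        if self.intensity.ndim != 3:
            raise ValueError("PSOCTStack volumes are 3-D [y, x, z]")
        self.boundaries.validate_depth(self.intensity.shape[2])


@dataclass
class PolarizationMaps:
    """En-face RNFL retardation ``delta_P`` (radians) and axis ``phi_P``."""

    retardation: np.ndarray
    axis: AxialAngleMap


def _stokes_components(retardation, axis):
    d2 = 2.0 * retardation
    t2 = np.pi - 2.0 * axis
    sin_d2 = np.sin(d2)
    return np.cos(d2), sin_d2 * np.cos(t2), sin_d2 * np.sin(t2)


def average_stokes(stack: PSOCTStack):
    """Depth-averaged normalized Stokes components ``(<Q>, <U>, <V>)``.

    Averaged over ``z in [rnfl_gcl, opl_onl)`` per pixel — the band of
    polarization-preserving tissue beneath the RNFL.  Returns
    ``(Q, U, V, n_samples)``; pixels with an empty band have
    ``n_samples == 0`` and zero components.
    """
    b = stack.boundaries
    q, u, v = _stokes_components(stack.retardation, stack.axis)
    h, w, depth = stack.retardation.shape
    z = np.arange(depth)
    in_band = (z[None, None, :] >= b.rnfl_gcl[:, :, None]) & (
        z[None, None, :] < b.opl_onl[:, :, None]
    )
    n = in_band.sum(axis=2)
    safe_n = np.maximum(n, 1)
    mq = np.sum(np.where(in_band, q, 0.0), axis=2) / safe_n
    mu = np.sum(np.where(in_band, u, 0.0), axis=2) / safe_n
    mv = np.sum(np.where(in_band, v, 0.0), axis=2) / safe_n
    return mq, mu, mv, n


def extract_polarization_maps(
    stack: PSOCTStack,
    norm_threshold=0.1,
    axis_min_amplitude=1e-6,
    spacing_x=1.0,
    spacing_y=1.0,
) -> PolarizationMaps:
    """RNFL retardation and axis-orientation maps from a PS-OCT stack.

    The averaged Stokes vector is re-normalized to unit length and
    inverted for ``delta_P`` and ``phi_P``.  Pixels are marked invalid
    when the band is empty, the averaged norm falls below
    ``norm_threshold`` (depolarized / inconsistent depth states), or the
    in-plane amplitude ``hypot(U, V)`` is below ``axis_min_amplitude``
    (no birefringence — the axis is undefined).
    """
    mq, mu, mv, n = average_stokes(stack)
    nrm = np.sqrt(mq**2 + mu**2 + mv**2)
    ok = (n > 0) & (nrm > norm_threshold)
    safe = np.where(nrm > 1e-300, nrm, 1.0)
    qr, ur, vr = mq / safe, mu / safe, mv / safe
    delta_p = np.where(ok, 0.5 * np.arccos(np.clip(qr, -1.0, 1.0)), 0.0)
    axis_ok = ok & (np.hypot(ur, vr) > axis_min_amplitude)
    phi_p = fold_axial(0.5 * np.arctan2(vr, -ur))
    axis = AxialAngleMap(
        values=np.where(axis_ok, phi_p, 0.0),
        valid=axis_ok,
        spacing_x=spacing_x,
        spacing_y=spacing_y,
    )
    return PolarizationMaps(retardation=delta_p, axis=axis)


# ---------------------------------------------------------------------------
# HDF5 interchange: datasets /intensity, /retardation, /axis ([y, x, z],
# z fastest) and /boundaries/{ilm, rnfl_gcl, opl_onl}.
# ---------------------------------------------------------------------------


def save_psoct_h5(path, stack: PSOCTStack):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=stack.intensity.astype(np.float32))
        f.create_dataset("retardation", data=stack.retardation.astype(np.float32))
        f.create_dataset("axis", data=stack.axis.astype(np.float32))
        grp = f.create_group("boundaries")
        grp.create_dataset("ilm", data=stack.boundaries.ilm.astype(np.int32))
        grp.create_dataset("rnfl_gcl", data=stack.boundaries.rnfl_gcl.astype(np.int32))
        grp.create_dataset("opl_onl", data=stack.boundaries.opl_onl.astype(np.int32))


def load_psoct_h5(path) -> PSOCTStack:
    import h5py

    with h5py.File(path, "r") as f:
        boundaries = LayerBoundaries(
            ilm=f["boundaries/ilm"][()],
            rnfl_gcl=f["boundaries/rnfl_gcl"][()],
            opl_onl=f["boundaries/opl_onl"][()],
        )
        return PSOCTStack(
            intensity=f["intensity"][()],
            retardation=f["retardation"][()],
            axis=f["axis"][()],
            boundaries=boundaries,
        )
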