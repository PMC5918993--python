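"""Helical axis fitting and inter-helix angles.

The axis of a helix segment is estimated from its Cα trace in two steps: an
initial direction from cross products of consecutive second differences of
the trace (unbiased for an ideal helix, including partial turns), then a
least-squares fit of a full helical curve (axis, origin, radius, phase,
twist, rise) to the Cα atoms.  The direction is signed N→C, so the
angle between two axes lives in [0, 180] degrees and distinguishes opening
from closing of a helix pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .structure import Selection, Structure, Trajectory, as_indices

__all__ = [
    "HelixAxis",
    "HelixPairAngle",
    "AngleSeries",
    "fit_helix_axis",
    "helix_pair_angle",
    "angle_series",
]

# perpendicular Ca scatter above which a segment no longer counts as helical
NON_HELICAL_FIT_RMS = 2.5  # Angstrom


@dataclass(frozen=True)
class HelixAxis:
    """A fitted helical axis: a point on the line, the N→C unit direction,
    and the perpendicular RMS scatter of the Cα atoms about the line."""

    origin: np.ndarray      # (3,)
    direction: np.ndarray   # (3,), unit, N -> C
    fit_rms: float          # Angstrom
    n_calpha: int

    @property
    def is_helical(self) -> bool:
        return self.fit_rms <= NON_HELICAL_FIT_RMS


@dataclass(frozen=True)
class HelixPairAngle:
    """Signed-direction angle between two helix axes, in degrees."""

    angle: float
    label: str = ""


def _calpha_positions(structure: Structure, selection) -> np.ndarray:
    idx = as_indices(structure, selection)
    names = structure.names
    ca = [i for i in idx if str(names[i]).strip().upper() == "CA"]
    return structure.coords[np.asarray(ca, dtype=int)] if ca else \
        np.empty((0, 3))


def _initial_direction(ca: np.ndarray) -> np.ndarray | None:
    """Axis estimate from cross products of consecutive second differences
    of the Cα trace.  The second differences of an ideal helix point
    radially inward, so each cross product lies exactly along the axis —
    the estimate is unbiased even for partial turns."""
    second = np.diff(np.diff(ca, axis=0), axis=0)
    cross = np.cross(second[:-1], second[1:])
    d = cross.sum(axis=0)
    norm = np.linalg.norm(d)
    return d / norm if norm > 1e-9 else None


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tmp = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, tmp)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def _refine_helix_curve(ca: np.ndarray, d0: np.ndarray,
                        c0: np.ndarray) -> np.ndarray:
    """Refine the axis by least-squares fitting an ideal helical curve
    (axis tilt, origin, radius, phase, twist and rise all free) to the Cα
    trace — the maximum-likelihood axis under isotropic coordinate noise."""
    from scipy.optimize import least_squares

    n = len(ca)
    i = np.arange(n)
    e1, e2 = _perp_frame(d0)
    rel = ca - c0
    t = rel @ d0
    rise0 = np.polyfit(i, t, 1)[0]
    perp = rel - np.outer(t, d0)
    radius0 = np.sqrt((perp ** 2).sum(axis=1)).mean()
    phase = np.unwrap(np.arctan2(perp @ e2, perp @ e1))
    twist0, phase0 = np.polyfit(i, phase, 1)

    def residuals(p):
        a, b, u1, u2, t0, r, ph, tw, h = p
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        f1, f2 = _perp_frame(d)
        c = c0 + u1 * e1 + u2 * e2
        pts = (c[None] + np.outer(r * np.cos(ph + i * tw), f1)
               + np.outer(r * np.sin(ph + i * tw), f2)
               + np.outer(t0 + i * h, d))
        return (pts - ca).ravel()

    p0 = np.array([0.0, 0.0, 0.0, 0.0, t[0], radius0, phase0, twist0,
                   rise0])
    sol = least_squares(residuals, p0, method="lm", max_nfev=200)
    a, b = sol.x[:2]
    d = d0 + a * e1 + b * e2
    return d / np.linalg.norm(d)


def fit_helix_axis_points(ca: np.ndarray) -> HelixAxis:
    """Fit an axis to an ordered Cα trace (N-terminal first)."""
    if ca.shape[0] < 5:
        raise GeometryError(
            f"helix axis fit needs >= 5 Calpha atoms, got {ca.shape[0]}")
    center = ca.mean(axis=0)
    centered = ca - center
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] <= 1e-10:
        raise GeometryError("degenerate (zero-variance) Calpha coordinates")
    direction = _initial_direction(ca)
    if direction is None:
        # winding-free (straight) trace: principal direction is the axis
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
    else:
        rel = ca - center
        perp = rel - np.outer(rel @ direction, direction)
        winding = np.sqrt((perp ** 2).sum(axis=1)).mean()
        if winding > 0.2:
            direction = _refine_helix_curve(ca, direction, center)
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    # perpendicular scatter of the raw Ca about the fitted line
    rel = ca - center
    perp = rel - np.outer(rel @ direction, direction)
    fit_rms = float(np.sqrt((perp ** 2).sum(axis=1).mean()))
    return HelixAxis(center, direction / np.linalg.norm(direction),
                     fit_rms, ca.shape[0])


def fit_helix_axis(structure: Structure, range_: Selection | str) -> HelixAxis:
    """Fit a helical axis to the Cα atoms of a residue-range selection."""
    ca = _calpha_positions(structure, range_)
    if ca.shape[0] < 5:
        raise GeometryError(
            f"selection {getattr(range_, 'expression', range_)!r} yields "
            f"{ca.shape[0]} Calpha atoms; >= 5 required")
    return fit_helix_axis_points(ca)


def helix_pair_angle(a: HelixAxis, b: HelixAxis,
                     label: str = "") -> HelixPairAngle:
    """Angle between the signed N→C directions, degrees in [0, 180]."""
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    return HelixPairAngle(float(np.degrees(np.arccos(cosang))), label)


@dataclass
class AngleSeries:
    """Per-frame inter-helix angle with summary statistics.

    Frames where either segment's fit scatter exceeds the non-helical
    threshold are recorded as NaN and excluded from mean/sd, with a count.
    """

    values: np.ndarray          # degrees; NaN where excluded
    label: str = ""

    @property
    def defined(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]

    @property
    def n_excluded(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def mean(self) -> float:
        return float(self.defined.mean())

    @property
    def sd(self) -> float:
        return float(self.defined.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)),
                             "angle_deg": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def angle_series(traj: Trajectory, range_a: Selection | str,
                 range_b: Selection | str, label: str = "") -> AngleSeries:
    """Inter-helix angle on every frame, with plain mean ± sd.

    A warning is emitted if any angle comes within 5° of the 0/180 wrap,
    where the plain (non-circular) mean becomes questionable.
    """
    top = traj.topology
    ia = as_indices(top, range_a)
    ib = as_indices(top, range_b)
    names = top.names
    ca_a = np.asarray([i for i in ia
                       if str(names[i]).strip().upper() == "CA"], dtype=int)
    ca_b = np.asarray([i for i in ib
                       if str(names[i]).strip().upper() == "CA"], dtype=int)
    values = np.full(traj.n_frames, np.nan)
    for f in range(traj.n_frames):
        try:
            axis_a = fit_helix_axis_points(traj.frames[f][ca_a])
            axis_b = fit_helix_axis_points(traj.frames[f][ca_b])
        except GeometryError:
            continue
        if not (axis_a.is_helical and axis_b.is_helical):
            continue
        values[f] = helix_pair_angle(axis_a, axis_b).angle
    defined = values[~np.isnan(values)]
    if defined.size and (defined.min() < 5.0 or defined.max() > 175.0):
        warnings.warn("angles within 5 deg of the 0/180 wrap; plain mean "
                      "may be biased")
    return AngleSeries(values, label)
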