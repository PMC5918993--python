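"""Accessible surface area and interface complementarity.

ASA uses deterministic Shrake–Rupley sphere sampling: each atom's van der
Waals sphere is inflated by the probe radius and covered with a Fibonacci
point lattice; the accessible fraction is the fraction of points outside
every other inflated sphere.

The buried area on complex formation is

    dASA = (ASA_A + ASA_B - ASA_AB) / 2

with the two parts taken in the conformation they have inside the complex
(a rigid-body definition; no relaxation of the separated parts).

The gap volume estimates the empty space enclosed between two interacting
parts.  This package defines it by a point-classification rule integrated on
a regular grid: a point p belongs to the gap region iff

    dA(p) > 0 and dB(p) > 0            (outside both vdW surfaces)
    dA(p) <= r_max and dB(p) <= r_max  (within gap-sphere reach of both)
    dA(p) + dB(p) >= 2 * r_min         (channel wide enough for the
                                        smallest allowed gap sphere)
    angle(uA(p), uB(p)) >= 120 deg     (the directions toward the two
                                        nearest surfaces oppose: p lies
                                        between the parts, not beside them)

where dX(p) is the distance from p to part X's van der Waals surface,
uX(p) the direction to its nearest atom, and [r_min, r_max] the allowed
gap-sphere radius band.  The same predicate is
integrable by Monte-Carlo sampling, which the test suite uses as an
independent oracle for the grid quadrature.

Gap index = gap volume / dASA (units: Angstrom).  Values of 1–5 are typical
for protein–protein interfaces; lower means better shape complementarity.
Hydrogens are excluded by default (heavy-atom radii convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SelectionError, UndefinedGapIndexError
from .structure import Selection, Structure, Trajectory, as_indices

__all__ = [
    "SurfaceParams",
    "InterfaceMetrics",
    "InterfaceSeries",
    "sasa",
    "delta_asa",
    "gap_volume",
    "gap_index",
    "interface_series",
    "fibonacci_sphere",
]


@dataclass(frozen=True)
class SurfaceParams:
    """Numerical parameters of the surface and gap computations.

    probe_radius: solvent probe (water: 1.4 A).
    sample_points_per_atom: Shrake-Rupley lattice size.
    grid_spacing: gap-volume quadrature cell edge (A).
    min_gap_sphere / max_gap_sphere: allowed gap-sphere radius band (A).
    delta_asa_threshold: below this buried area (A^2) the gap index is
        reported as undefined rather than dividing by ~0.
    include_hydrogens: include H atoms in surface/gap geometry.
    """

    probe_radius: float = 1.4
    sample_points_per_atom: int = 960
    grid_spacing: float = 0.75
    min_gap_sphere: float = 1.0
    max_gap_sphere: float = 5.0
    delta_asa_threshold: float = 1.0
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if not self.min_gap_sphere < self.max_gap_sphere:
            raise ValueError("min_gap_sphere must be < max_gap_sphere")

    def metadata(self) -> dict:
        return {
            "probe_radius": self.probe_radius,
            "sample_points_per_atom": self.sample_points_per_atom,
            "grid_spacing": self.grid_spacing,
            "min_gap_sphere": self.min_gap_sphere,
            "max_gap_sphere": self.max_gap_sphere,
            "delta_asa_threshold": self.delta_asa_threshold,
            "include_hydrogens": self.include_hydrogens,
        }


@dataclass(frozen=True)
class InterfaceMetrics:
    """ASA of the parts and complex, buried area, gap volume and gap index."""

    asa_A: float        # A^2, part A isolated
    asa_B: float        # A^2, part B isolated
    asa_AB: float       # A^2, complex
    delta_asa: float    # A^2
    gap_volume: float   # A^3
    gap_index: float | None  # A; None when delta_asa below threshold

    @property
    def complementarity_band(self) -> str:
        """Qualitative band on the conventional 1-5 gap-index scale."""
        if self.gap_index is None:
            return "undefined"
        if self.gap_index < 2.0:
            return "tight"
        if self.gap_index <= 5.0:
            return "typical"
        return "loose"

    def as_dict(self) -> dict:
        return {
            "asa_A": self.asa_A, "asa_B": self.asa_B, "asa_AB": self.asa_AB,
            "delta_asa": self.delta_asa, "gap_volume": self.gap_volume,
            "gap_index": self.gap_index,
        }


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point lattice."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _heavy(structure: Structure, idx: np.ndarray,
           params: SurfaceParams) -> np.ndarray:
    if params.include_hydrogens:
        return idx
    elements = np.char.upper(structure.elements.astype(str))
    return idx[elements[idx] != "H"]


def sasa(structure: Structure, selection: Selection | str | None = None,
         params: SurfaceParams = SurfaceParams(),
         context: Selection | str | None = None
         ) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area of the selected atoms.

    By default occlusion is computed among the selected atoms only, so the
    selection defines the molecular entity whose surface is measured.  Pass
    ``context`` to add further occluding atoms without reporting their area
    (e.g. the receptor, when measuring how exposed a bound ligand remains).
    Returns ``(total, per_atom)`` in A^2; per-atom values sum to the total.
    """
    idx = _heavy(structure, as_indices(structure, selection), params)
    if idx.size == 0:
        raise SelectionError("sasa: empty selection")
    if context is not None:
        ctx = _heavy(structure, as_indices(structure, context), params)
        occ_idx = np.unique(np.concatenate([idx, ctx]))
    else:
        occ_idx = idx
    coords = structure.coords[idx]
    occ_coords = structure.coords[occ_idx]
    radii = structure.radii[idx] + params.probe_radius
    occ_radii = structure.radii[occ_idx] + params.probe_radius
    # map each measured atom to its position in the occluder table so the
    # atom never occludes itself
    self_pos = np.searchsorted(occ_idx, idx)
    points = fibonacci_sphere(params.sample_points_per_atom)
    n = idx.size
    per_atom = np.zeros(n)
    # neighbor lists via one distance matrix (systems here are small)
    d2 = ((coords[:, None, :] - occ_coords[None, :, :]) ** 2).sum(axis=2)
    reach = (radii[:, None] + occ_radii[None, :]) ** 2
    for i in range(n):
        neighbors = np.flatnonzero((d2[i] < reach[i]) &
                                   (np.arange(occ_idx.size) != self_pos[i]))
        sphere = coords[i] + radii[i] * points
        if neighbors.size:
            diff = sphere[:, None, :] - occ_coords[neighbors][None, :, :]
            buried = (diff ** 2).sum(axis=2) < \
                (occ_radii[neighbors] ** 2)[None, :]
            accessible = ~buried.any(axis=1)
        else:
            accessible = np.ones(len(sphere), dtype=bool)
        per_atom[i] = (4.0 * np.pi * radii[i] ** 2 *
                       accessible.mean())
    full = np.zeros(len(structure))
    full[idx] = per_atom
    return float(per_atom.sum()), full


def _disjoint(structure: Structure, part_a, part_b):
    ia = as_indices(structure, part_a)
    ib = as_indices(structure, part_b)
    if np.intersect1d(ia, ib).size:
        raise SelectionError("part_A and part_B overlap")
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("interface parts must be non-empty")
    return ia, ib


def delta_asa(complex_: Structure, part_A, part_B,
              params: SurfaceParams = SurfaceParams()) -> float:
    """Buried area on complexation: (ASA_A + ASA_B - ASA_AB) / 2.

    Part ASAs are computed on each part in isolation, in the conformation it
    has inside the complex; the complex ASA is computed on the union.
    """
    ia, ib = _disjoint(complex_, part_A, part_B)
    asa_a, _ = sasa(complex_, ia, params)
    asa_b, _ = sasa(complex_, ib, params)
    union = np.sort(np.concatenate([ia, ib]))
    asa_ab, _ = sasa(complex_, union, params)
    return (asa_a + asa_b - asa_ab) / 2.0


def _surface_distance(points: np.ndarray, coords: np.ndarray,
                      radii: np.ndarray, chunk: int = 65536
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each point to the union-of-spheres surface (negative
    inside) and the index of the nearest sphere."""
    out = np.empty(len(points))
    nearest = np.empty(len(points), dtype=int)
    for start in range(0, len(points), chunk):
        block = points[start:start + chunk]
        d = np.sqrt(((block[:, None, :] - coords[None, :, :]) ** 2
                     ).sum(axis=2)) - radii[None, :]
        nearest[start:start + chunk] = d.argmin(axis=1)
        out[start:start + chunk] = d.min(axis=1)
    return out, nearest


# a gap point's directions toward the two parts must be at least this far
# apart (120 deg): the point lies *between* the parts, not beside them
_BETWEEN_COS = -0.5


def _gap_mask(points: np.ndarray, ca: np.ndarray, ra: np.ndarray,
              cb: np.ndarray, rb: np.ndarray,
              params: SurfaceParams) -> np.ndarray:
    da, na = _surface_distance(points, ca, ra)
    db, nb = _surface_distance(points, cb, rb)
    ua = ca[na] - points
    ub = cb[nb] - points
    norms = np.linalg.norm(ua, axis=1) * np.linalg.norm(ub, axis=1)
    cosab = (ua * ub).sum(axis=1) / np.maximum(norms, 1e-12)
    return ((da > 0) & (db > 0) &
            (da <= params.max_gap_sphere) & (db <= params.max_gap_sphere) &
            (da + db >= 2.0 * params.min_gap_sphere) &
            (cosab <= _BETWEEN_COS))


def _gap_box(ca, ra, cb, rb, params):
    pad_a = ra.max() + params.max_gap_sphere
    pad_b = rb.max() + params.max_gap_sphere
    lo = np.maximum(ca.min(axis=0) - pad_a, cb.min(axis=0) - pad_b)
    hi = np.minimum(ca.max(axis=0) + pad_a, cb.max(axis=0) + pad_b)
    return lo, hi


def gap_volume(complex_: Structure, part_A, part_B,
               params: SurfaceParams = SurfaceParams()) -> float:
    """Volume (A^3) of the gap region enclosed between the two parts,
    integrated on a regular grid of the configured spacing."""
    ia, ib = _disjoint(complex_, part_A, part_B)
    ia = _heavy(complex_, ia, params)
    ib = _heavy(complex_, ib, params)
    ca, ra = complex_.coords[ia], complex_.radii[ia]
    cb, rb = complex_.coords[ib], complex_.radii[ib]
    lo, hi = _gap_box(ca, ra, cb, rb, params)
    h = params.grid_spacing
    if np.any(hi <= lo):
        axes = []
    else:
        axes = [np.arange(lo[k] + h / 2, hi[k], h) for k in range(3)]
    if not axes or any(len(ax) == 0 for ax in axes):
        warnings.warn("gap region is empty (parts separated beyond "
                      "gap-sphere reach)")
        return 0.0
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    mask = _gap_mask(points, ca, ra, cb, rb, params)
    volume = float(mask.sum()) * h ** 3
    if volume == 0.0:
        warnings.warn("gap region is empty (parts either separated beyond "
                      "gap-sphere reach or fully interpenetrating)")
    return volume


def gap_index(complex_: Structure, part_A, part_B,
              params: SurfaceParams = SurfaceParams()) -> InterfaceMetrics:
    """Full interface characterization: ASAs, dASA, gap volume, gap index."""
    ia, ib = _disjoint(complex_, part_A, part_B)
    asa_a, _ = sasa(complex_, ia, params)
    asa_b, _ = sasa(complex_, ib, params)
    union = np.sort(np.concatenate([ia, ib]))
    asa_ab, _ = sasa(complex_, union, params)
    dasa = (asa_a + asa_b - asa_ab) / 2.0
    volume = gap_volume(complex_, ia, ib, params)
    if dasa < params.delta_asa_threshold:
        raise UndefinedGapIndexError(
            f"buried area {dasa:.3g} A^2 is below the definedness threshold "
            f"{params.delta_asa_threshold} A^2; gap index would blow up"
        )
    return InterfaceMetrics(asa_a, asa_b, asa_ab, dasa, volume,
                            volume / dasa)


@dataclass
class InterfaceSeries:
    """Per-frame interface metrics plus the summary statistics reported for
    trajectory tables (mean and sd over frames with a defined gap index)."""

    frames: list[int]
    metrics: list[InterfaceMetrics | None]   # None where undefined
    params: SurfaceParams

    @property
    def n_defined(self) -> int:
        return sum(m is not None for m in self.metrics)

    @property
    def n_undefined(self) -> int:
        return sum(m is None for m in self.metrics)

    def summary(self) -> dict:
        defined = [m for m in self.metrics if m is not None]
        out: dict = {"n_defined": self.n_defined,
                     "n_undefined": self.n_undefined,
                     "params": self.params.metadata()}
        for key in ("delta_asa", "gap_volume", "gap_index"):
            vals = np.array([getattr(m, key) for m in defined], dtype=float)
            out[key] = {"mean": float(vals.mean()) if vals.size else None,
                        "sd": float(vals.std(ddof=0)) if vals.size else None}
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, m in zip(self.frames, self.metrics):
            row = {"frame": f}
            row.update(m.as_dict() if m is not None else
                       {k: np.nan for k in ("asa_A", "asa_B", "asa_AB",
                                            "delta_asa", "gap_volume",
                                            "gap_index")})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def interface_series(traj: Trajectory, part_A, part_B,
                     params: SurfaceParams = SurfaceParams(),
                     stride: int = 1) -> InterfaceSeries:
    """Interface metrics on every ``stride``-th frame; frames whose gap
    index is undefined are kept in the table but excluded from (and counted
    next to) the summary statistics."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ia, ib = _disjoint(traj.topology, part_A, part_B)
    frames, metrics = [], []
    for f in range(0, traj.n_frames, stride):
        structure = traj.topology.with_coords(traj.frames[f])
        frames.append(f)
        try:
            metrics.append(gap_index(structure, ia, ib, params))
        except UndefinedGapIndexError:
            metrics.append(None)
    return InterfaceSeries(frames, metrics, params)
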