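"""Optimal superposition and flexibility metrics.

Implements weighted Kabsch superposition (SVD with determinant correction,
so an improper rotation is never returned), iterative average structures,
RMSD time series with normalized histograms, RMSF profiles about the
converged average, and the two per-residue difference maps used to compare
systems: displacement between average structures and change in RMSF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DataError, GeometryError, MappingError
from .structure import Selection, Structure, Trajectory, as_indices

__all__ = [
    "SuperpositionResult",
    "RMSDSeries",
    "RMSFProfile",
    "DifferenceMap",
    "superpose",
    "align_frames",
    "average_structure",
    "rmsd_series",
    "rmsf",
    "difference_map",
    "kabsch",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """A rigid transform ``y = R x + t`` minimizing the weighted RMSD, plus
    the RMSD over the fitted atoms after the transform."""

    rotation: np.ndarray     # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float              # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _check_fit_points(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise GeometryError(f"superposition needs >= 3 atoms, got {x.shape[0]}")
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise GeometryError("fit atoms are (nearly) collinear; "
                            "rotation is not determined")


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None,
           check: bool = True) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``y = R x + t``.  The determinant of R is
    forced to +1 (reflections are corrected via the smallest singular
    direction, the standard Kabsch treatment).
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise GeometryError(f"shape mismatch {x.shape} vs {y.shape}")
    if weights is None:
        w = np.ones(x.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    if check:
        _check_fit_points(x)
    wsum = w.sum()
    cx = (w[:, None] * x).sum(axis=0) / wsum
    cy = (w[:, None] * y).sum(axis=0) / wsum
    xc = x - cx
    yc = y - cy
    h = xc.T @ (w[:, None] * yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, d])
    rot = vt.T @ dmat @ u.T
    t = cy - rot @ cx
    diff = xc @ rot.T - yc
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum() / wsum))
    return rot, t, rmsd


def _resolve_weights(weights, structure: Structure | None,
                     idx: np.ndarray) -> np.ndarray | None:
    if weights is None or weights == "uniform":
        return None
    if isinstance(weights, str):
        if weights != "mass":
            raise ValueError(f"weights must be 'uniform', 'mass' or an array, "
                             f"got {weights!r}")
        if structure is None:
            raise ValueError("mass weighting needs a Structure input")
        return structure.masses[idx]
    return np.asarray(weights, dtype=float)


def _coords_of(obj) -> tuple[np.ndarray, Structure | None]:
    if isinstance(obj, Structure):
        return obj.coords, obj
    return np.asarray(obj, dtype=float), None


def superpose(mobile, reference, fit_selection: Selection | str | None = None,
              weights="uniform") -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Both arguments may be :class:`Structure` or plain ``(n, 3)`` arrays; the
    fit (and the reported RMSD) uses ``fit_selection`` resolved on the
    structures, or all atoms.
    """
    xc, xs = _coords_of(mobile)
    yc, ys = _coords_of(reference)
    ref_struct = xs or ys
    if fit_selection is not None and ref_struct is None:
        raise ValueError("fit_selection requires a Structure input")
    idx = as_indices(ref_struct, fit_selection) if ref_struct is not None \
        else np.arange(xc.shape[0])
    w = _resolve_weights(weights, xs or ys, idx)
    rot, t, rmsd = kabsch(xc[idx], yc[idx], w)
    return SuperpositionResult(rot, t, rmsd)


def align_frames(frames: np.ndarray, reference: np.ndarray,
                 fit_idx: np.ndarray,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto ``reference`` fitting on ``fit_idx``;
    returns the transformed full-atom frame stack."""
    out = np.empty_like(frames)
    ref = reference[fit_idx]
    for i, frame in enumerate(frames):
        rot, t, _ = kabsch(frame[fit_idx], ref, weights, check=(i == 0))
        out[i] = frame @ rot.T + t
    return out


def _iterative_average(frames: np.ndarray, fit_idx: np.ndarray,
                       weights: np.ndarray | None, tol: float,
                       max_iter: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate (align all frames on current mean, recompute mean) until the
    mean moves less than ``tol`` (RMS over fit atoms).

    Returns ``(align_target, mean, aligned)``: the reference the final
    alignment pass used, the empirical mean of that aligned stack, and the
    stack itself — keeping the three mutually consistent matters for the
    covariance analysis, whose projections must reproduce training exactly.
    """
    ref = frames[0].copy()
    shift = np.inf
    for _ in range(max_iter):
        aligned = align_frames(frames, ref, fit_idx, weights)
        mean = aligned.mean(axis=0)
        shift = float(np.sqrt(
            ((mean[fit_idx] - ref[fit_idx]) ** 2).sum(axis=1).mean()))
        if shift < tol:
            return ref, mean, aligned
        ref = mean
    raise ConvergenceError(
        f"average structure did not converge in {max_iter} iterations "
        f"(last mean shift {shift:.2e} A)"
    )


def average_structure(traj: Trajectory,
                      fit_selection: Selection | str | None = None,
                      tol: float = 1e-4, max_iter: int = 100,
                      weights="uniform") -> Structure:
    """Converged iterative-superposition average structure of a trajectory."""
    if traj.n_frames < 2:
        raise DataError("average structure needs >= 2 frames")
    fit_idx = as_indices(traj.topology, fit_selection)
    w = _resolve_weights(weights, traj.topology, fit_idx)
    _, mean, _ = _iterative_average(traj.frames, fit_idx, w, tol, max_iter)
    return traj.topology.with_coords(mean)


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

@dataclass
class RMSDSeries:
    """Per-frame RMSD (Angstrom) plus a unit-area histogram."""

    values: np.ndarray
    hist_density: np.ndarray
    hist_edges: np.ndarray
    fit_selection: str | None
    measure_selection: str | None

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)),
                             "rmsd": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rmsd_series(traj: Trajectory, reference: Structure,
                fit_selection: Selection | str | None = None,
                measure_selection: Selection | str | None = None,
                bin_width: float = 0.1) -> RMSDSeries:
    """Per-frame RMSD to a reference.

    Frames are fitted on ``fit_selection`` and the RMSD is measured on
    ``measure_selection`` (defaults to the fit selection) *after* the fitted
    transform — fitting and measuring on different atom sets is what
    ligand-mobility analysis needs.
    """
    fit_idx = as_indices(traj.topology, fit_selection)
    measure_idx = (as_indices(traj.topology, measure_selection)
                   if measure_selection is not None else fit_idx)
    ref_fit = reference.coords[fit_idx]
    ref_measure = reference.coords[measure_idx]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        rot, t, _ = kabsch(frame[fit_idx], ref_fit, check=(i == 0))
        moved = frame[measure_idx] @ rot.T + t
        values[i] = np.sqrt(((moved - ref_measure) ** 2).sum(axis=1).mean())
    top = max(values.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    return RMSDSeries(values, density, edges,
                      getattr(fit_selection, "expression", fit_selection),
                      getattr(measure_selection, "expression",
                              measure_selection))


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass
class RMSFProfile:
    """Root-mean-square fluctuation about the converged average structure.

    ``values`` is per-atom (over the measured atoms) or per-residue when
    aggregated; ``keys`` identifies each entry (atom index, or (chain,
    residue) pair).
    """

    values: np.ndarray
    keys: list
    aggregate: str                   # "atom" | "residue"
    reference: Structure             # the average structure
    fit_selection: str | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.aggregate == "residue":
            chains = [k[0] for k in self.keys]
            resids = [k[1] for k in self.keys]
            return pd.DataFrame({"chain": chains, "residue": resids,
                                 "rmsf": self.values})
        return pd.DataFrame({"atom": self.keys, "rmsf": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rmsf(traj: Trajectory, fit_selection: Selection | str | None = None,
         aggregate: str = "atom",
         measure_selection: Selection | str | None = None,
         tol: float = 1e-4, max_iter: int = 100) -> RMSFProfile:
    """RMSF of each atom (or residue) about the iterative average structure.

    Frames are superposed on ``fit_selection``; fluctuations are reported
    for ``measure_selection`` (default: all atoms).  Residue aggregation
    takes the root mean square over each residue's measured atoms.
    """
    if traj.n_frames < 2:
        raise DataError("RMSF needs >= 2 frames")
    if aggregate not in ("atom", "residue"):
        raise ValueError(f"aggregate must be 'atom' or 'residue', got "
                         f"{aggregate!r}")
    top = traj.topology
    fit_idx = as_indices(top, fit_selection)
    _, mean, aligned = _iterative_average(traj.frames, fit_idx, None, tol,
                                          max_iter)
    measure_idx = (as_indices(top, measure_selection)
                   if measure_selection is not None
                   else np.arange(len(top)))
    dev = aligned[:, measure_idx] - mean[measure_idx]
    msf = (dev ** 2).sum(axis=2).mean(axis=0)   # per-atom mean square
    reference = top.with_coords(mean)
    expr = getattr(fit_selection, "expression", fit_selection)
    if aggregate == "atom":
        return RMSFProfile(np.sqrt(msf), list(measure_idx), "atom",
                           reference, expr)
    keys: list[tuple[str, int]] = []
    groups: dict[tuple[str, int], list[int]] = {}
    for pos, ai in enumerate(measure_idx):
        a = top.atoms[ai]
        key = (a.chain_id, a.residue_id)
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(pos)
    values = np.array([np.sqrt(msf[groups[k]].mean()) for k in keys])
    return RMSFProfile(values, keys, "residue", reference, expr)


# ---------------------------------------------------------------------------
# Difference maps
# ---------------------------------------------------------------------------

DISPLACEMENT_BOUNDS = (0.0, 4.0)     # display scale, Angstrom
DELTA_RMSF_BOUNDS = (-1.2, 1.2)      # display scale, Angstrom


@dataclass
class DifferenceMap:
    """Per-residue scalar map comparing two systems.

    ``kind`` is ``"displacement"`` (distance between average structures,
    >= 0) or ``"delta_rmsf"`` (may be negative).  ``display_bounds`` records
    the conventional color-scale bounds for each kind.
    """

    kind: str
    residue_keys: list
    values: np.ndarray
    display_bounds: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [k[0] for k in self.residue_keys],
            "residue": [k[1] for k in self.residue_keys],
            "value": self.values,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _common_atoms(a: Structure, b: Structure):
    """Indices of atoms shared by the two structures, matched on
    (chain, residue id, atom name), in a's order."""
    table_b = {(at.chain_id, at.residue_id, at.name): i
               for i, at in enumerate(b.atoms)}
    ia, ib = [], []
    for i, at in enumerate(a.atoms):
        j = table_b.get((at.chain_id, at.residue_id, at.name))
        if j is not None:
            ia.append(i)
            ib.append(j)
    if not ia:
        raise MappingError("structures share no (chain, residue, atom) keys")
    return np.asarray(ia), np.asarray(ib)


def difference_map(a, b, fit_selection: Selection | str | None = None,
                   tol: float = 1e-4, max_iter: int = 100) -> DifferenceMap:
    """Per-residue difference between two systems.

    With two trajectories (or average structures): the displacement map —
    superpose b's average onto a's on ``fit_selection`` and report, per
    residue, the mean distance between matched atoms.  With two
    :class:`RMSFProfile` inputs: the change in flexibility RMSF(b) − RMSF(a),
    matched per residue.
    """
    if isinstance(a, RMSFProfile) and isinstance(b, RMSFProfile):
        pa, pb = a, b
        if pa.aggregate != "residue":
            pa = _reaggregate(pa)
        if pb.aggregate != "residue":
            pb = _reaggregate(pb)
        index_b = {k: v for k, v in zip(pb.keys, pb.values)}
        keys = [k for k in pa.keys if k in index_b]
        if not keys:
            raise MappingError("RMSF profiles share no residues")
        av = {k: v for k, v in zip(pa.keys, pa.values)}
        values = np.array([index_b[k] - av[k] for k in keys])
        return DifferenceMap("delta_rmsf", keys, values, DELTA_RMSF_BOUNDS)

    sa = a if isinstance(a, Structure) else average_structure(
        a, fit_selection, tol, max_iter)
    sb = b if isinstance(b, Structure) else average_structure(
        b, fit_selection, tol, max_iter)
    ia, ib = _common_atoms(sa, sb)
    # fit on the requested selection restricted to the shared atoms
    fit_a = as_indices(sa, fit_selection)
    shared_fit = np.isin(ia, fit_a)
    if shared_fit.sum() < 3:
        raise MappingError("fewer than 3 shared atoms in the fit selection")
    rot, t, _ = kabsch(sb.coords[ib[shared_fit]],
                       sa.coords[ia[shared_fit]])
    moved_b = sb.coords[ib] @ rot.T + t
    dist = np.sqrt(((sa.coords[ia] - moved_b) ** 2).sum(axis=1))
    groups: dict[tuple[str, int], list[int]] = {}
    for pos, i in enumerate(ia):
        at = sa.atoms[i]
        groups.setdefault((at.chain_id, at.residue_id), []).append(pos)
    keys = list(groups)
    values = [dist[groups[k]].mean() for k in keys]
    return DifferenceMap("displacement", keys, np.asarray(values),
                         DISPLACEMENT_BOUNDS)


def _reaggregate(profile: RMSFProfile) -> RMSFProfile:
    """Aggregate an atom-level RMSF profile to residues (RMS over atoms)."""
    top = profile.reference
    keys: list[tuple[str, int]] = []
    groups: dict[tuple[str, int], list[float]] = {}
    for ai, v in zip(profile.keys, profile.values):
        a = top.atoms[ai]
        key = (a.chain_id, a.residue_id)
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(v ** 2)
    values = np.array([np.sqrt(np.mean(groups[k])) for k in keys])
    return RMSFProfile(values, keys, "residue", profile.reference,
                       profile.fit_selection)


def write_bfactor_pdb(path, structure: Structure,
                      residue_values: dict[tuple[str, int], float]) -> None:
    """Write ``structure`` with per-residue map values stuffed into the
    B-factor column, for visualization."""
    from .structure import _array_from_structure

    array = _array_from_structure(structure, structure.coords)
    bf = np.zeros(len(structure))
    for i, at in enumerate(structure.atoms):
        bf[i] = residue_values.get((at.chain_id, at.residue_id), 0.0)
    array.set_annotation("b_factor", bf)
    from biotite.structure.io.pdb import PDBFile
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))
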