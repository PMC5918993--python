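"""Essential dynamics: mass-weighted covariance analysis of a trajectory.

Frames are superposed on the converged iterative average over the analysis
selection (backbone heavy atoms N, Cα, C by default).  The covariance of the
mass-weighted, centered coordinates is diagonalized; eigenvectors are
collective modes, eigenvalues their variances (amu·Å²).  Covariance uses the
1/n normalization so that the variance of a mode projection equals its
eigenvalue exactly.  Projections, per-mode filtered trajectories (for mode
animation) and a per-mode variance/involvement report are provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .structure import Selection, Structure, Trajectory, as_indices
from .superpose import _iterative_average, kabsch

__all__ = [
    "PCAModel",
    "ModeProjection",
    "ModeReport",
    "fit_pca",
    "project",
    "filter_trajectory",
    "mode_report",
    "BACKBONE_SELECTION",
]

BACKBONE_SELECTION = "name N,CA,C"


@dataclass
class PCAModel:
    """Result of a covariance analysis over one atom selection.

    mean: (3s,) flattened empirical mean of the aligned selected coordinates.
    align_reference: (s, 3) coordinates the frames were superposed onto.
    eigenvalues: descending, amu·Å² (Å² with uniform weighting).
    eigenvectors: (k, 3s), orthonormal rows.
    sqrt_masses: per-atom weighting actually applied (1 for uniform).
    """

    mean: np.ndarray
    align_reference: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    atom_indices: np.ndarray
    sqrt_masses: np.ndarray
    topology: Structure
    weighting: str

    @property
    def n_atoms(self) -> int:
        return int(self.atom_indices.size)

    def fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else \
            np.zeros_like(self.eigenvalues)

    def save(self, path) -> None:
        payload = {
            "weighting": self.weighting,
            "mean": self.mean.tolist(),
            "align_reference": self.align_reference.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "atom_indices": self.atom_indices.tolist(),
            "sqrt_masses": self.sqrt_masses.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class ModeProjection:
    """Per-frame scalar coordinate along one mode (Å·amu^1/2)."""

    mode: int
    values: np.ndarray

    @property
    def variance(self) -> float:
        return float(self.values.var(ddof=0))


def _weighted_flat(frames_sel: np.ndarray, mean_sel: np.ndarray,
                   sqrt_m: np.ndarray) -> np.ndarray:
    centered = frames_sel - mean_sel
    weighted = centered * sqrt_m[None, :, None]
    return weighted.reshape(frames_sel.shape[0], -1)


def _align_to_model(traj: Trajectory, model: PCAModel) -> np.ndarray:
    """Superpose each frame's selected atoms onto the model's alignment
    reference; returns the aligned selected coordinates (n, s, 3)."""
    idx = model.atom_indices
    out = np.empty((traj.n_frames, idx.size, 3))
    for i, frame in enumerate(traj.frames):
        rot, t, _ = kabsch(frame[idx], model.align_reference,
                           check=(i == 0))
        out[i] = frame[idx] @ rot.T + t
    return out


def fit_pca(traj: Trajectory,
            selection: Selection | str | None = BACKBONE_SELECTION,
            weighting: str = "mass", tol: float = 1e-4,
            max_iter: int = 100) -> PCAModel:
    """Fit the covariance model on the selected atoms of a trajectory."""
    if traj.n_frames < 2:
        raise DataError("PCA needs >= 2 frames")
    if weighting not in ("mass", "uniform"):
        raise ValueError(f"weighting must be 'mass' or 'uniform', got "
                         f"{weighting!r}")
    top = traj.topology
    idx = as_indices(top, selection)
    ref, _, aligned = _iterative_average(traj.frames, idx, None, tol,
                                         max_iter)
    sel = aligned[:, idx]
    mean_sel = sel.mean(axis=0)
    sqrt_m = (np.sqrt(top.masses[idx]) if weighting == "mass"
              else np.ones(idx.size))
    flat = _weighted_flat(sel, mean_sel, sqrt_m)
    cov = flat.T @ flat / flat.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T   # rows are modes
    return PCAModel(
        mean=mean_sel.reshape(-1),
        align_reference=ref[idx],
        eigenvalues=evals,
        eigenvectors=evecs,
        atom_indices=idx,
        sqrt_masses=sqrt_m,
        topology=top,
        weighting=weighting,
    )


def project(traj: Trajectory, model: PCAModel, mode: int) -> ModeProjection:
    """Project a trajectory onto one mode.

    Frames are aligned to the model's reference, centered on the model mean,
    mass-weighted and dotted with the eigenvector.  For the fitting
    trajectory the sample variance of the projection equals the eigenvalue.
    """
    if not 0 <= mode < len(model.eigenvalues):
        raise IndexError(f"mode {mode} out of range "
                         f"(model has {len(model.eigenvalues)})")
    sel = _align_to_model(traj, model)
    flat = _weighted_flat(sel, model.mean.reshape(-1, 3),
                          model.sqrt_masses)
    return ModeProjection(mode, flat @ model.eigenvectors[mode])


def filter_trajectory(traj: Trajectory, model: PCAModel,
                      modes) -> Trajectory:
    """Reconstruct the trajectory keeping only the given modes.

    Each output frame is mean + Σ_k c_k(t) · (eigenvector_k unweighted);
    with all modes this reproduces the aligned trajectory exactly, with no
    modes every frame is the mean structure.  The output carries only the
    model's atoms.
    """
    modes = sorted(set(int(m) for m in modes))
    for m in modes:
        if not 0 <= m < len(model.eigenvalues):
            raise IndexError(f"mode {m} out of range")
    sel = _align_to_model(traj, model)
    flat = _weighted_flat(sel, model.mean.reshape(-1, 3), model.sqrt_masses)
    recon_w = np.zeros_like(flat)
    for m in modes:
        vec = model.eigenvectors[m]
        recon_w += np.outer(flat @ vec, vec)
    # undo the mass weighting and re-add the mean
    recon = recon_w.reshape(sel.shape) / model.sqrt_masses[None, :, None]
    recon = recon + model.mean.reshape(-1, 3)
    subset = model.topology.subset(model.atom_indices)
    return Trajectory(subset, recon, frame_period=traj.frame_period,
                      info={"filtered_modes": modes})


@dataclass
class ModeReport:
    """Fractional variance per mode and per-residue involvement.

    Involvement of residue r in mode k is the squared eigenvector weight on
    r's atoms; involvements of one mode sum to 1.
    """

    table: pd.DataFrame         # mode, eigenvalue, fraction
    involvement: pd.DataFrame   # index (chain, residue), one column per mode


def mode_report(model: PCAModel, n_modes: int = 5) -> ModeReport:
    n_modes = min(n_modes, len(model.eigenvalues))
    fractions = model.fractions()
    table = pd.DataFrame({
        "mode": np.arange(n_modes),
        "eigenvalue": model.eigenvalues[:n_modes],
        "fraction": fractions[:n_modes],
    })
    top = model.topology
    keys, groups = [], {}
    for pos, ai in enumerate(model.atom_indices):
        a = top.atoms[ai]
        key = (a.chain_id, a.residue_id)
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(pos)
    data = {}
    for k in range(n_modes):
        comps = model.eigenvectors[k].reshape(-1, 3)
        weight = (comps ** 2).sum(axis=1)
        data[f"mode_{k}"] = [weight[groups[key]].sum() for key in keys]
    involvement = pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(keys,
                                              names=["chain", "residue"]))
    return ModeReport(table, involvement)
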