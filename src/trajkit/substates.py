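"""Conformational substates and interaction occupancy.

Substate clustering uses GROMOS-style neighbor counting on the pairwise
RMSD graph: repeatedly take the unassigned frame with the most neighbors
within the cutoff as a cluster center, assign it and its neighbors, remove
them, and continue.  Ties break to the lowest frame index, so the procedure
is deterministic.

Contact occupancy supports three criteria — plain heavy-atom minimum
distance, hydrogen bonds (donor–acceptor distance plus D–H...A angle when
hydrogens are present), and ion coordination (ion to O/N distance).  All
cutoffs are compared inclusively (<=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContactSpecError, DataError, TrajkitError
from .structure import Selection, Structure, Trajectory, as_indices
from .superpose import kabsch

__all__ = [
    "SubstateAssignment",
    "ContactSpec",
    "OccupancySeries",
    "LigandMobility",
    "pairwise_rmsd",
    "cluster_substates",
    "substate_series",
    "contact_occupancy",
    "ligand_mobility",
]


def pairwise_rmsd(traj: Trajectory,
                  fit_selection: Selection | str | None = None,
                  measure_selection: Selection | str | None = None
                  ) -> np.ndarray:
    """Symmetric matrix of frame-to-frame RMSD.

    Each pair is optimally superposed on ``fit_selection`` and measured on
    ``measure_selection`` (default: the fit selection).  Vectorized with a
    batched 3x3 SVD per row.
    """
    top = traj.topology
    fit_idx = as_indices(top, fit_selection)
    measure_idx = (as_indices(top, measure_selection)
                   if measure_selection is not None else fit_idx)
    n = traj.n_frames
    fit = traj.frames[:, fit_idx]
    fit_centroids = fit.mean(axis=1, keepdims=True)
    cf = fit - fit_centroids                       # centered fit coords
    mrel = traj.frames[:, measure_idx] - fit_centroids
    out = np.zeros((n, n))
    for i in range(n - 1):
        js = np.arange(i + 1, n)
        h = np.einsum("jna,nb->jab", cf[js], cf[i])
        u, _, vt = np.linalg.svd(h)
        det = np.linalg.det(np.einsum("jab,jcb->jac", vt, u))
        d = np.ones((len(js), 3))
        d[:, 2] = np.sign(det)
        # R_j = V diag(d) U^T
        rot = np.einsum("jba,jb,jcb->jac", vt, d, u)
        moved = np.einsum("jna,jba->jnb", mrel[js], rot)
        diff = moved - mrel[i]
        out[i, js] = np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))
        out[js, i] = out[i, js]
    return out


@dataclass
class SubstateAssignment:
    """Frame-to-cluster labels plus per-cluster representatives.

    Clusters are ordered by size (descending); labels are dense 0..K-1.
    ``medoids`` holds, per cluster, the member frame with minimal summed
    RMSD to the rest of its cluster; ``averages`` the per-cluster average
    structures (members superposed on the medoid).
    """

    labels: np.ndarray
    sizes: list[int]
    medoids: list[int]
    averages: list[Structure]
    rmsd_cutoff: float
    fit_selection: str | None = None
    measure_selection: str | None = None
    rmsd_matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def cluster_substates(traj: Trajectory,
                      fit_selection: Selection | str | None = None,
                      measure_selection: Selection | str | None = None,
                      cutoff: float = 1.5,
                      frame_cap: int = 2000) -> SubstateAssignment:
    """GROMOS-style neighbor-counting clustering of trajectory frames."""
    if traj.n_frames < 2:
        raise DataError("clustering needs >= 2 frames")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if traj.n_frames > frame_cap:
        raise TrajkitError(
            f"{traj.n_frames} frames exceed the pairwise-matrix cap "
            f"({frame_cap}); stride the trajectory first")
    dist = pairwise_rmsd(traj, fit_selection, measure_selection)
    n = traj.n_frames
    neighbor = dist <= cutoff
    active = np.ones(n, dtype=bool)
    raw_labels = np.full(n, -1)
    clusters: list[np.ndarray] = []
    while active.any():
        counts = (neighbor & active[None, :]).sum(axis=1)
        counts[~active] = -1
        center = int(np.argmax(counts))   # argmax -> lowest index on ties
        members = np.flatnonzero(neighbor[center] & active)
        raw_labels[members] = len(clusters)
        clusters.append(members)
        active[members] = False
    order = sorted(range(len(clusters)),
                   key=lambda c: (-len(clusters[c]), c))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[l] for l in raw_labels])
    clusters = [clusters[old] for old in order]

    fit_idx = as_indices(traj.topology, fit_selection)
    medoids, averages, sizes = [], [], []
    for members in clusters:
        sub = dist[np.ix_(members, members)]
        medoid = int(members[np.argmin(sub.sum(axis=1))])
        medoids.append(medoid)
        sizes.append(len(members))
        ref = traj.frames[medoid]
        acc = np.zeros_like(ref)
        for f in members:
            rot, t, _ = kabsch(traj.frames[f][fit_idx], ref[fit_idx],
                               check=False)
            acc += traj.frames[f] @ rot.T + t
        averages.append(traj.topology.with_coords(acc / len(members)))
    return SubstateAssignment(
        labels, sizes, medoids, averages, cutoff,
        getattr(fit_selection, "expression", fit_selection),
        getattr(measure_selection, "expression", measure_selection),
        rmsd_matrix=dist,
    )


def substate_series(assignment: SubstateAssignment, traj: Trajectory,
                    reference: Structure) -> pd.DataFrame:
    """Per-frame RMSD to a reference, annotated with the cluster label."""
    from .superpose import rmsd_series

    if len(assignment.labels) != traj.n_frames:
        raise DataError("assignment does not match this trajectory")
    series = rmsd_series(traj, reference,
                         fit_selection=assignment.fit_selection,
                         measure_selection=assignment.measure_selection)
    return pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "rmsd": series.values,
        "label": assignment.labels,
    })


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactSpec:
    """One interaction criterion between two atom groups.

    criterion: 'distance' (heavy-atom minimum distance), 'hbond'
    (donor–acceptor distance + D–H...A angle when hydrogens are present) or
    'coordination' (ion to O/N distance).  Defaults: H-bond 3.5 A / 120°,
    coordination 2.6 A (the Mg–O convention).
    """

    group_a: str | Selection
    group_b: str | Selection
    criterion: str = "distance"
    cutoff: float = 3.5
    angle_min: float = 120.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.criterion not in ("distance", "hbond", "coordination"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class OccupancySeries:
    """Per-frame formed/broken state and minimum distance; occupancy is the
    mean of the booleans."""

    formed: np.ndarray
    min_distance: np.ndarray
    criterion: str
    cutoff: float
    fallback_distance_only: bool = False

    @property
    def occupancy(self) -> float:
        return float(self.formed.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.formed)),
                             "formed": self.formed.astype(int),
                             "min_distance": self.min_distance})


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def _find_hydrogens(top: Structure, donor_idx: np.ndarray,
                    coords: np.ndarray) -> dict[int, list[int]]:
    """Hydrogens covalently attached to each donor (distance < 1.25 A,
    same residue), judged on the supplied coordinate set."""
    elements = np.char.upper(top.elements.astype(str))
    h_idx = np.flatnonzero(elements == "H")
    attached: dict[int, list[int]] = {d: [] for d in donor_idx}
    if h_idx.size == 0:
        return attached
    for d in donor_idx:
        same_res = [h for h in h_idx
                    if top.atoms[h].residue_id == top.atoms[d].residue_id
                    and top.atoms[h].chain_id == top.atoms[d].chain_id]
        for h in same_res:
            if np.linalg.norm(coords[h] - coords[d]) < 1.25:
                attached[d].append(h)
    return attached


def contact_occupancy(traj: Trajectory, spec: ContactSpec) -> OccupancySeries:
    """Evaluate a contact criterion on every frame.

    All cutoffs are inclusive: a frame exactly at the cutoff counts as
    formed.  For 'hbond' with no hydrogens in the topology the evaluation
    falls back to the distance criterion and flags it.
    """
    top = traj.topology
    ia = as_indices(top, spec.group_a)
    ib = as_indices(top, spec.group_b)
    if ia.size == 0 or ib.size == 0:
        raise ContactSpecError("contact groups must be non-empty")
    elements = np.char.upper(top.elements.astype(str))

    if spec.criterion == "distance":
        ha = ia[elements[ia] != "H"]
        hb = ib[elements[ib] != "H"]
        formed = np.zeros(traj.n_frames, dtype=bool)
        mind = np.empty(traj.n_frames)
        for f, frame in enumerate(traj.frames):
            mind[f] = _min_dist(frame[ha], frame[hb])
            formed[f] = mind[f] <= spec.cutoff
        return OccupancySeries(formed, mind, spec.criterion, spec.cutoff)

    if spec.criterion == "coordination":
        acceptors = ib[np.isin(elements[ib], ("O", "N"))]
        if acceptors.size == 0:
            raise ContactSpecError("coordination needs O/N atoms in group_b")
        formed = np.zeros(traj.n_frames, dtype=bool)
        mind = np.empty(traj.n_frames)
        for f, frame in enumerate(traj.frames):
            mind[f] = _min_dist(frame[ia], frame[acceptors])
            formed[f] = mind[f] <= spec.cutoff
        return OccupancySeries(formed, mind, spec.criterion, spec.cutoff)

    # hbond
    donors = ia[np.isin(elements[ia], ("O", "N"))]
    if donors.size == 0:
        raise ContactSpecError("hbond needs N/O donor atoms in group_a")
    acceptors = ib[np.isin(elements[ib], ("O", "N"))]
    if acceptors.size == 0:
        raise ContactSpecError("hbond needs N/O acceptor atoms in group_b")
    attached = _find_hydrogens(top, donors, traj.frames[0])
    have_h = any(attached[d] for d in donors)
    formed = np.zeros(traj.n_frames, dtype=bool)
    mind = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        mind[f] = _min_dist(frame[donors], frame[acceptors])
        if not have_h:
            formed[f] = mind[f] <= spec.cutoff
            continue
        ok = False
        for d in donors:
            for a in acceptors:
                dist = np.linalg.norm(frame[d] - frame[a])
                if dist > spec.cutoff:
                    continue
                for h in attached[d]:
                    v1 = frame[d] - frame[h]
                    v2 = frame[a] - frame[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) *
                                               np.linalg.norm(v2))
                    angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if angle >= spec.angle_min:
                        ok = True
                        break
                if ok:
                    break
            if ok:
                break
        formed[f] = ok
    return OccupancySeries(formed, mind, spec.criterion, spec.cutoff,
                           fallback_distance_only=not have_h)


# ---------------------------------------------------------------------------
# Ligand mobility
# ---------------------------------------------------------------------------

@dataclass
class LigandMobility:
    """Positional mobility (receptor-frame RMSD of the ligand to its average
    pose) and internal flexibility (same after fitting on the ligand
    itself), each summarized mean ± sd."""

    positional: np.ndarray
    internal: np.ndarray

    @property
    def positional_mean(self) -> float:
        return float(self.positional.mean())

    @property
    def positional_sd(self) -> float:
        return float(self.positional.std(ddof=0))

    @property
    def internal_mean(self) -> float:
        return float(self.internal.mean())

    @property
    def internal_sd(self) -> float:
        return float(self.internal.std(ddof=0))


def ligand_mobility(traj: Trajectory, receptor_fit: Selection | str,
                    ligand: Selection | str) -> LigandMobility:
    """Mobility of a bound ligand.

    Positional: frames are superposed on the receptor; the ligand RMSD to
    its average pose in that frame of reference measures how much the
    ligand moves within its site.  Internal: superposing on the ligand
    itself leaves only its conformational flexibility.
    """
    from .superpose import average_structure, rmsd_series

    avg_receptor = average_structure(traj, receptor_fit)
    positional = rmsd_series(traj, avg_receptor, fit_selection=receptor_fit,
                             measure_selection=ligand).values
    avg_ligand = average_structure(traj, ligand)
    internal = rmsd_series(traj, avg_ligand, fit_selection=ligand,
                           measure_selection=ligand).values
    return LigandMobility(positional, internal)
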