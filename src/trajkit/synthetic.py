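"""Synthetic structures and trajectories with known ground truth.

The generator emulates, in miniature, the statistical structure every
analysis stage assumes:

* a two-domain system (chains A and B), each domain carrying a pair of
  α-helices at a configured mutual angle plus a planar grid of filler atoms
  forming a slab interface at a configured surface-to-surface separation;
* an optional small ligand (ring of C/O atoms) with two Mg²⁺ ions placed in
  the interface cleft;
* trajectories built as substate center (a Markov chain over rigid
  displacements of a target segment) + low-rank collective modes with
  prescribed variances + isotropic Gaussian noise, with an optional hinge
  schedule that re-opens one helix pair between configured angles.

Everything is driven by one explicitly seeded NumPy generator, so identical
configurations regenerate bit-identical output, and the returned
:class:`GroundTruth` records the state sequence, mode coefficients and hinge
schedule needed to score downstream recovery.

Geometry is deliberately schematic: there are no energetics and no sterics
beyond a minimum-distance construction check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import mass_of, radius_of
from .errors import ConfigError, ConstructionError
from .structure import Atom, Structure, Trajectory

__all__ = [
    "HelixParams",
    "LigandSpec",
    "GeneratorConfig",
    "GroundTruth",
    "build_ideal_helix",
    "build_two_domain_system",
    "generate_trajectory",
]

# default residue ranges for the four helices (two per domain); mirrors the
# numbering convention used for the analysis selections
HELIX_RANGES = {
    "a1": (408, 420),   # chain A, first helix
    "a2": (468, 475),   # chain A, second helix (the hinged one)
    "b1": (910, 918),   # chain B
    "b2": (978, 988),   # chain B (default substate target)
}


@dataclass(frozen=True)
class HelixParams:
    """Canonical α-helix geometry."""

    rise: float = 1.5       # A per residue
    twist: float = 100.0    # degrees per residue
    radius: float = 2.3     # A


@dataclass(frozen=True)
class LigandSpec:
    """A small ring-shaped ligand placed mid-cleft, plus coordination ions."""

    n_atoms: int = 8
    n_ions: int = 2
    ring_radius: float = 1.2   # A


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic system.

    Angles are the helix-pair opening angles per domain (degrees);
    ``interface_separation`` is the surface-to-surface slab gap (A).
    ``hinge_angles`` (if set) is a list of angles the A-domain pair cycles
    through with equal dwell.  ``substate_displacements`` are rigid offsets
    (A) of the target segment; the Markov ``transition_matrix`` rows must
    sum to 1.  ``mode_variances`` are collective-mode variances (A²·amu for
    the mass-weighted convention used by the covariance analysis).
    """

    seed: int = 0
    n_frames: int = 300
    frame_period: float = 1.0       # ns, metadata
    helix: HelixParams = field(default_factory=HelixParams)
    angle_a_deg: float = 26.0
    angle_b_deg: float = 50.0
    interface_separation: float = 2.6
    n_grid: int = 7
    grid_spacing: float = 4.0
    ligand: LigandSpec | None = None
    hinge_angles: list[float] | None = None
    substate_displacements: list | None = None
    transition_matrix: list | None = None
    substate_target: str = "helix_b2"
    mode_variances: list[float] = field(default_factory=list)
    mode_selection: str = "name N,CA,C"
    noise_sigma: float = 0.12
    noise_sigma_overrides: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.noise_sigma < 0 or any(v < 0 for v in
                                       self.noise_sigma_overrides.values()):
            raise ConfigError("noise sigmas must be >= 0")
        if any(v < 0 for v in self.mode_variances):
            raise ConfigError("mode variances must be >= 0")
        if self.substate_displacements is not None:
            k = len(self.substate_displacements)
            if self.transition_matrix is None:
                raise ConfigError("substates need a transition matrix")
            tm = np.asarray(self.transition_matrix, dtype=float)
            if tm.shape != (k, k):
                raise ConfigError(f"transition matrix must be {k}x{k}")
            if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError("transition matrix rows must sum to 1")
            if np.any(tm < 0):
                raise ConfigError("transition probabilities must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score downstream recovery without re-derivation."""

    states: np.ndarray | None            # (n_frames,) Markov state sequence
    mode_coefficients: np.ndarray | None  # (n_frames, k)
    mode_vectors: np.ndarray | None       # (k, n_atoms, 3), unweighted
    hinge_schedule: np.ndarray | None     # (n_frames,) angle in degrees
    seed: int = 0

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "states": None if self.states is None else self.states.tolist(),
            "mode_coefficients": (None if self.mode_coefficients is None
                                  else self.mode_coefficients.tolist()),
            "hinge_schedule": (None if self.hinge_schedule is None
                               else self.hinge_schedule.tolist()),
        }


# ---------------------------------------------------------------------------
# Structure builders
# ---------------------------------------------------------------------------

def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Minimal rotation taking +z to ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _atom(serial, name, element, resname, resid, chain) -> Atom:
    return Atom(serial, name, element, resname, resid, chain,
                mass_of(element, name), radius_of(element, name))


def build_ideal_helix(n: int, rise: float = 1.5, twist: float = 100.0,
                      radius: float = 2.3,
                      direction=(0.0, 0.0, 1.0),
                      origin=(0.0, 0.0, 0.0),
                      chain_id: str = "A", start_resid: int = 1,
                      resname: str = "ALA") -> Structure:
    """Canonical α-helix Cα trace with backbone N and C stubs.

    N and C are placed on the same helical curve at ∓ a third of a residue
    step, so backbone selections (``name N,CA,C``) resolve and consecutive
    backbone atoms are spaced plausibly.
    """
    if n < 5:
        raise ConfigError(f"helix needs >= 5 residues, got {n}")
    rot = _rotation_to(direction)
    origin = np.asarray(origin, dtype=float)
    tw = np.radians(twist)

    def point(i: float) -> np.ndarray:
        local = np.array([radius * np.cos(i * tw),
                          radius * np.sin(i * tw),
                          i * rise])
        return rot @ local + origin

    atoms, coords = [], []
    serial = 1
    for i in range(n):
        resid = start_resid + i
        for name, element, off in (("N", "N", -1 / 3),
                                   ("CA", "C", 0.0),
                                   ("C", "C", +1 / 3)):
            atoms.append(_atom(serial, name, element, resname, resid,
                               chain_id))
            coords.append(point(i + off))
            serial += 1
    return Structure(atoms, np.asarray(coords))


def _slab(n_grid: int, spacing: float, z: float, chain: str,
          start_resid: int) -> tuple[list[Atom], np.ndarray]:
    half = (n_grid - 1) / 2.0
    atoms, coords = [], []
    resid = start_resid
    for i in range(n_grid):
        for j in range(n_grid):
            atoms.append(_atom(resid, "FA", "C", "FIL", resid, chain))
            coords.append([(i - half) * spacing, (j - half) * spacing, z])
            resid += 1
    return atoms, np.asarray(coords)


def _helix_pair(chain: str, ranges: tuple, angle_deg: float, z: float,
                helix: HelixParams, flip: bool) -> list[Structure]:
    """Two helices in a plane parallel to the slab, diverging at the
    configured mutual angle; ``flip`` mirrors the pair to the -z side."""
    half = np.radians(angle_deg) / 2.0
    zsign = -1.0 if flip else 1.0
    out = []
    for (lo, hi), sign, y0 in ((ranges[0], +1.0, 7.0),
                               (ranges[1], -1.0, -7.0)):
        n = hi - lo + 1
        direction = np.array([np.cos(half), sign * np.sin(half), 0.0])
        origin = np.array([-10.0, y0, z * zsign])
        out.append(build_ideal_helix(
            n, helix.rise, helix.twist, helix.radius, direction, origin,
            chain_id=chain, start_resid=lo))
    return out


def _check_clashes(structure: Structure, min_dist: float = 1.5) -> None:
    coords = structure.coords
    n = len(structure)
    rid = structure.residue_ids
    chains = structure.chain_ids
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    same_chain = chains[:, None] == chains[None, :]
    near_residue = np.abs(rid[:, None] - rid[None, :]) <= 1
    bonded_like = same_chain & near_residue
    mask = ~bonded_like & (d2 < min_dist ** 2)
    np.fill_diagonal(mask, False)
    if mask.any():
        i, j = np.argwhere(mask)[0]
        raise ConstructionError(
            f"atoms {i} and {j} are {np.sqrt(d2[i, j]):.2f} A apart "
            f"(< {min_dist} A)")


def build_two_domain_system(config: GeneratorConfig) -> Structure:
    """Two pseudo-domains with a slab interface, helix pairs, and an
    optional ligand with ions in the cleft.

    The returned structure's ``info['layout']`` maps component names
    (``helix_a1`` … ``helix_b2``, ``slab_a``, ``slab_b``, ``ligand``,
    ``ions``) to atom-index lists, and records the hinge pivot/axis used by
    the trajectory generator.
    """
    config.validate()
    helix = config.helix
    r_fill = radius_of("C")
    sep = config.interface_separation
    z_b_slab = -(sep + 2 * r_fill)

    pieces: list[tuple[str, list[Atom], np.ndarray]] = []
    slab_a_atoms, slab_a_coords = _slab(config.n_grid, config.grid_spacing,
                                        0.0, "A", 1)
    pieces.append(("slab_a", slab_a_atoms, slab_a_coords))
    slab_b_atoms, slab_b_coords = _slab(config.n_grid, config.grid_spacing,
                                        z_b_slab, "B", 1)
    pieces.append(("slab_b", slab_b_atoms, slab_b_coords))

    pair_a = _helix_pair("A", (HELIX_RANGES["a1"], HELIX_RANGES["a2"]),
                         config.angle_a_deg, 8.0, helix, flip=False)
    pieces.append(("helix_a1", pair_a[0].atoms, pair_a[0].coords))
    pieces.append(("helix_a2", pair_a[1].atoms, pair_a[1].coords))
    pair_b = _helix_pair("B", (HELIX_RANGES["b1"], HELIX_RANGES["b2"]),
                         config.angle_b_deg, -z_b_slab + 8.0, helix,
                         flip=True)
    pieces.append(("helix_b1", pair_b[0].atoms, pair_b[0].coords))
    pieces.append(("helix_b2", pair_b[1].atoms, pair_b[1].coords))

    if config.ligand is not None:
        lig = config.ligand
        z_mid = -(r_fill + sep / 2.0)
        ring, coords = [], []
        for k in range(lig.n_atoms):
            theta = 2 * np.pi * k / lig.n_atoms
            element = "O" if k % 2 else "C"
            ring.append(_atom(600, f"L{k + 1}", element, "LIG", 600, "L"))
            coords.append([lig.ring_radius * np.cos(theta),
                           lig.ring_radius * np.sin(theta), z_mid])
        pieces.append(("ligand", ring, np.asarray(coords)))
        ions, icoords = [], []
        for k in range(lig.n_ions):
            # flank the ring within coordination reach of its oxygens
            x = (2.8 + 0.5 * (k // 2)) * (1 if k % 2 == 0 else -1)
            ions.append(_atom(601 + k, "MG", "MG", "MG", 601 + k, "L"))
            icoords.append([x, 0.0, z_mid])
        if ions:
            pieces.append(("ions", ions, np.asarray(icoords)))

    atoms: list[Atom] = []
    coords_list = []
    layout: dict = {}
    cursor = 0
    for name, piece_atoms, piece_coords in pieces:
        layout[name] = list(range(cursor, cursor + len(piece_atoms)))
        atoms.extend(piece_atoms)
        coords_list.append(piece_coords)
        cursor += len(piece_atoms)
    structure = Structure(atoms, np.vstack(coords_list))
    _check_clashes(structure)

    # hinge bookkeeping: helix a2 rotates about the slab normal through its
    # N-terminal end
    # helix a2 diverges toward -y, so opening the pair by +delta means
    # rotating it clockwise when viewed from +z: axis -z
    layout["hinge"] = {
        "target": "helix_a2",
        "pivot": structure.coords[layout["helix_a2"][0]].tolist(),
        "axis": [0.0, 0.0, -1.0],
        "base_angle": config.angle_a_deg,
    }
    structure.info["layout"] = layout
    structure.info["config"] = config
    return structure


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _rodrigues(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return (np.eye(3) + np.sin(angle_rad) * k +
            (1 - np.cos(angle_rad)) * (k @ k))


def _rigid_body_basis(coords: np.ndarray, sqrt_m: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the mass-weighted rigid-body subspace
    (3 translations + up to 3 infinitesimal rotations)."""
    n = coords.shape[0]
    com = (sqrt_m[:, None] ** 2 * coords).sum(0) / (sqrt_m ** 2).sum()
    rel = coords - com
    vecs = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = 1.0
        vecs.append((sqrt_m[:, None] * t).reshape(-1))
    for a in range(3):
        omega = np.zeros(3)
        omega[a] = 1.0
        r = np.cross(np.broadcast_to(omega, rel.shape), rel)
        vecs.append((sqrt_m[:, None] * r).reshape(-1))
    basis = []
    for v in vecs:
        for b in basis:
            v = v - np.dot(v, b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-10:
            basis.append(v / norm)
    return np.asarray(basis)


def _make_mode_vectors(base: Structure, support: np.ndarray, k: int,
                       rng: np.random.Generator) -> np.ndarray:
    """k collective-mode vectors, unit norm and mutually orthogonal in the
    mass-weighted metric, orthogonal to rigid-body motions of the support
    atoms; zero off the support.  Returns unweighted (k, n_atoms, 3)."""
    n = len(base)
    s = support.size
    sqrt_m = np.sqrt(base.masses[support])
    rigid = _rigid_body_basis(base.coords[support], sqrt_m)
    raw = rng.standard_normal((k, 3 * s))
    modes_w = []
    for v in raw:
        for b in rigid:
            v = v - np.dot(v, b) * b
        for b in modes_w:
            v = v - np.dot(v, b) * b
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ConfigError("could not build independent mode vectors")
        modes_w.append(v / norm)
    out = np.zeros((k, n, 3))
    for i, vw in enumerate(modes_w):
        out[i, support] = (vw.reshape(s, 3) / sqrt_m[:, None])
    return out


def _markov_states(tm: np.ndarray, n: int, start: int,
                   rng: np.random.Generator) -> np.ndarray:
    states = np.empty(n, dtype=int)
    states[0] = start
    for t in range(1, n):
        states[t] = rng.choice(tm.shape[0], p=tm[states[t - 1]])
    return states


def generate_trajectory(base: Structure, config: GeneratorConfig
                        ) -> tuple[Trajectory, GroundTruth]:
    """Sample a trajectory around ``base`` under the configured conditions.

    Frame construction order: hinge rotation → substate offset → collective
    modes → isotropic noise.  All randomness flows from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    n_atoms = len(base)
    layout = base.info.get("layout", {})

    # hinge schedule (square wave, equal dwell over the configured angles)
    hinge_schedule = None
    if config.hinge_angles:
        if "hinge" not in layout:
            raise ConfigError("base structure has no hinge layout")
        angles = np.asarray(config.hinge_angles, dtype=float)
        # equal-dwell square wave in 25-frame blocks
        idx = (np.arange(n_frames) // 25) % len(angles)
        hinge_schedule = angles[idx]

    # substate sequence
    states = None
    state_offsets = None
    if config.substate_displacements is not None:
        tm = np.asarray(config.transition_matrix, dtype=float)
        states = _markov_states(tm, n_frames, 0, rng)
        state_offsets = np.asarray(config.substate_displacements,
                                   dtype=float)
        target_name = config.substate_target
        if target_name not in layout:
            raise ConfigError(f"no layout component {target_name!r} for "
                              f"substate target")
        target_idx = np.asarray(layout[target_name], dtype=int)

    # collective modes
    mode_vectors = None
    coeffs = None
    if config.mode_variances:
        from .structure import resolve_selection
        sel = resolve_selection(base, config.mode_selection)
        k = len(config.mode_variances)
        mode_vectors = _make_mode_vectors(base, sel.resolved_indices, k, rng)
        sd = np.sqrt(np.asarray(config.mode_variances, dtype=float))
        coeffs = rng.standard_normal((n_frames, k)) * sd[None, :]

    # per-atom noise scale
    sigma = np.full(n_atoms, config.noise_sigma)
    for chain, s in config.noise_sigma_overrides.items():
        mask = base.chain_ids == chain
        sigma[mask] = s

    frames = np.empty((n_frames, n_atoms, 3))
    for t in range(n_frames):
        coords = base.coords.copy()
        if hinge_schedule is not None:
            hinge = layout["hinge"]
            delta = np.radians(hinge_schedule[t] - hinge["base_angle"])
            if abs(delta) > 1e-12:
                target = np.asarray(layout[hinge["target"]], dtype=int)
                pivot = np.asarray(hinge["pivot"])
                rot = _rodrigues(np.asarray(hinge["axis"]), delta)
                coords[target] = (coords[target] - pivot) @ rot.T + pivot
        if states is not None:
            coords[target_idx] += state_offsets[states[t]]
        if coeffs is not None:
            for m in range(mode_vectors.shape[0]):
                coords += coeffs[t, m] * mode_vectors[m]
        coords += rng.standard_normal((n_atoms, 3)) * sigma[:, None]
        frames[t] = coords

    traj = Trajectory(base, frames, frame_period=config.frame_period,
                      info={"seed": config.seed})
    truth = GroundTruth(states=states, mode_coefficients=coeffs,
                        mode_vectors=mode_vectors,
                        hinge_schedule=hinge_schedule, seed=config.seed)
    return traj, truth
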