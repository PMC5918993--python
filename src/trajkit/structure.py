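"""Structures, trajectories and atom selections.

The atom table is deliberately minimal: serial, name, element, residue
(name/id), chain, mass and van der Waals radius.  Coordinates live in a
separate ``(n_atoms, 3)`` float array (Angstrom throughout; no internal unit
conversion).  A :class:`Trajectory` is an ordered stack of such coordinate
arrays over a single topology.

PDB input/output goes through :mod:`biotite.structure.io.pdb` (fixed-column
dialect, single- and multi-MODEL).  Masses and radii are assigned from the
element tables in :mod:`trajkit.elements`, with per-call overrides.

Selections use a small expression language of ``and``-conjoined predicates::

    resid 408-420,468-475 and name CA and chain A

Recognised predicates: ``chain``, ``resid`` (single ids, comma lists and
``lo-hi`` ranges), ``name``, ``resname``, ``element``, and the keyword
``all``.  Conjunction order never changes the result.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .elements import mass_of, radius_of
from .errors import (
    PDBParseError,
    RangeError,
    SelectionError,
    SelectionSyntaxError,
    TopologyError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "read_pdb",
    "write_pdb",
    "resolve_selection",
    "discard_equilibration",
]

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass(frozen=True)
class Atom:
    """One row of the atom table."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    mass: float      # Da
    radius: float    # Angstrom, van der Waals

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"atom {self.name}: mass must be > 0")
        if not self.radius > 0:
            raise ValueError(f"atom {self.name}: radius must be > 0")


@dataclass
class Structure:
    """An atom table plus one coordinate set (Angstrom)."""

    atoms: list[Atom]
    coords: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._arrays: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.atoms)

    # -- cached column views -------------------------------------------------
    def _column(self, key: str) -> np.ndarray:
        if key not in self._arrays:
            self._arrays[key] = np.asarray(
                [getattr(a, key) for a in self.atoms]
            )
        return self._arrays[key]

    @property
    def masses(self) -> np.ndarray:
        return self._column("mass").astype(float)

    @property
    def radii(self) -> np.ndarray:
        return self._column("radius").astype(float)

    @property
    def names(self) -> np.ndarray:
        return self._column("name")

    @property
    def elements(self) -> np.ndarray:
        return self._column("element")

    @property
    def residue_ids(self) -> np.ndarray:
        return self._column("residue_id").astype(int)

    @property
    def residue_names(self) -> np.ndarray:
        return self._column("residue_name")

    @property
    def chain_ids(self) -> np.ndarray:
        return self._column("chain_id")

    # ------------------------------------------------------------------------
    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same atom table, new coordinates (no copy of the table)."""
        return Structure(self.atoms, np.asarray(coords, dtype=float),
                         info=dict(self.info))

    def subset(self, indices: np.ndarray | list[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure([self.atoms[i] for i in idx], self.coords[idx])

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_id) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_id), None)
        return list(seen)


@dataclass
class Trajectory:
    """Ordered coordinate frames over one topology.

    ``frame_period`` is metadata only (ns per frame); no kinetic analysis
    depends on it.
    """

    topology: Structure
    frames: np.ndarray           # (n_frames, n_atoms, 3)
    frame_period: float = 1.0    # ns
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, n_atoms, 3) array "
                             "with at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression and the matching indices
    (strictly increasing, in topology order)."""

    expression: str
    resolved_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.resolved_indices, dtype=int)
        object.__setattr__(self, "resolved_indices", idx)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("resolved_indices must be strictly increasing")

    @property
    def indices(self) -> np.ndarray:
        return self.resolved_indices

    def __len__(self) -> int:
        return int(self.resolved_indices.size)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

_PREDICATES = ("chain", "resid", "name", "resname", "element")


def _parse_resid_ranges(token: str) -> list[tuple[int, int]]:
    ranges = []
    for part in token.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.fullmatch(r"(-?\d+)\s*-\s*(-?\d+)", part)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
        elif re.fullmatch(r"-?\d+", part):
            lo = hi = int(part)
        else:
            raise SelectionSyntaxError(f"bad resid token {part!r}")
        if hi < lo:
            raise SelectionSyntaxError(f"empty resid range {part!r}")
        ranges.append((lo, hi))
    if not ranges:
        raise SelectionSyntaxError(f"empty resid argument {token!r}")
    return ranges


def _term_mask(structure: Structure, term: str) -> np.ndarray:
    words = term.split(None, 1)
    keyword = words[0].lower()
    if keyword == "all":
        if len(words) > 1:
            raise SelectionSyntaxError(f"unexpected token {words[1]!r} after 'all'")
        return np.ones(len(structure), dtype=bool)
    if keyword not in _PREDICATES:
        raise SelectionSyntaxError(f"unknown predicate {words[0]!r}")
    if len(words) < 2 or not words[1].strip():
        raise SelectionSyntaxError(f"predicate {keyword!r} needs an argument")
    arg = words[1].strip()
    if keyword == "resid":
        mask = np.zeros(len(structure), dtype=bool)
        rid = structure.residue_ids
        for lo, hi in _parse_resid_ranges(arg):
            mask |= (rid >= lo) & (rid <= hi)
        return mask
    values = {v.strip().upper() for v in arg.split(",") if v.strip()}
    if not values:
        raise SelectionSyntaxError(f"predicate {keyword!r} needs an argument")
    column = {
        "chain": structure.chain_ids,
        "name": structure.names,
        "resname": structure.residue_names,
        "element": structure.elements,
    }[keyword]
    upper = np.char.upper(column.astype(str))
    return np.isin(upper, sorted(values))


def resolve_selection(structure: Structure, expression: str,
                      allow_empty: bool = False) -> Selection:
    """Resolve a selection expression against a structure.

    Raises :class:`SelectionSyntaxError` on a malformed expression and
    :class:`SelectionError` if nothing matches (unless ``allow_empty``).
    """
    if not expression or not expression.strip():
        raise SelectionSyntaxError("empty selection expression")
    mask = np.ones(len(structure), dtype=bool)
    for term in re.split(r"\s+and\s+", expression.strip()):
        if not term.strip():
            raise SelectionSyntaxError("dangling 'and' in expression")
        mask &= _term_mask(structure, term.strip())
    indices = np.flatnonzero(mask)
    if indices.size == 0 and not allow_empty:
        raise SelectionError(
            f"selection {expression!r} matched no atoms "
            f"(pass allow_empty=True if intentional)"
        )
    return Selection(expression, indices)


def as_indices(structure: Structure,
               sel: "Selection | str | np.ndarray | None") -> np.ndarray:
    """Normalize a selection-like argument to an index array (None = all)."""
    if sel is None:
        return np.arange(len(structure))
    if isinstance(sel, Selection):
        return sel.resolved_indices
    if isinstance(sel, str):
        return resolve_selection(structure, sel).resolved_indices
    return np.asarray(sel, dtype=int)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _diagnose_pdb(path: Path) -> None:
    """Scan ATOM/HETATM records for malformed fixed-column fields so parse
    failures can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fragment = line[lo:hi].strip()
                try:
                    float(fragment)
                except ValueError:
                    raise PDBParseError(
                        f"{path}, line {lineno}: malformed {what} coordinate "
                        f"field {fragment!r}"
                    ) from None
            try:
                int(line[22:26].strip() or "0")
            except ValueError:
                raise PDBParseError(
                    f"{path}, line {lineno}: malformed residue number "
                    f"{line[22:26].strip()!r}"
                ) from None


def _atoms_from_array(array: bst.AtomArray,
                      masses: dict[str, float] | None,
                      radii: dict[str, float] | None) -> list[Atom]:
    atoms = []
    for i in range(array.array_length()):
        element = str(array.element[i])
        name = str(array.atom_name[i])
        atoms.append(Atom(
            serial=i + 1,
            name=name,
            element=element,
            residue_name=str(array.res_name[i]),
            residue_id=int(array.res_id[i]),
            chain_id=str(array.chain_id[i]),
            mass=mass_of(element, name, masses),
            radius=radius_of(element, name, radii),
        ))
    return atoms


def read_pdb(path: str | Path, model_policy: str = "first",
             masses: dict[str, float] | None = None,
             radii: dict[str, float] | None = None):
    """Read a PDB file.

    ``model_policy='first'`` returns a :class:`Structure` from the first
    MODEL; ``'all'`` returns a :class:`Trajectory` with one frame per MODEL
    (atom tables of all MODELs must match).  Alternate locations keep the
    highest-occupancy conformer (ties: first encountered).
    """
    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got "
                         f"{model_policy!r}")
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # find the offending line if we can
        _diagnose_pdb(path)
        raise PDBParseError(f"{path}: {exc}") from exc

    if model_policy == "first":
        try:
            array = pdb.get_structure(model=1, altloc="occupancy")
        except Exception as exc:
            _diagnose_pdb(path)
            raise PDBParseError(f"{path}: {exc}") from exc
        if array.array_length() == 0:
            raise PDBParseError(f"{path}: no ATOM/HETATM records")
        atoms = _atoms_from_array(array, masses, radii)
        return Structure(atoms, np.asarray(array.coord, dtype=float))

    try:
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:
        _diagnose_pdb(path)
        raise TopologyError(
            f"{path}: MODEL blocks do not share one atom table ({exc})"
        ) from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    atoms = _atoms_from_array(stack[0], masses, radii)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model file read as stack of one
        coords = coords[None]
    topology = Structure(atoms, coords[0])
    return Trajectory(topology, coords)


def _array_from_structure(structure: Structure,
                          coords: np.ndarray) -> bst.AtomArray:
    n = len(structure)
    array = bst.AtomArray(n)
    array.coord = np.asarray(coords, dtype=np.float32)
    array.chain_id = structure.chain_ids.astype("U4")
    array.res_id = structure.residue_ids
    array.res_name = structure.residue_names.astype("U5")
    array.atom_name = structure.names.astype("U6")
    array.element = np.char.upper(structure.elements.astype("U2"))
    array.set_annotation("hetero", np.zeros(n, dtype=bool))
    return array


def write_pdb(path: str | Path, obj: "Structure | Trajectory") -> None:
    """Write a Structure (single model) or Trajectory (multi-MODEL) as PDB."""
    pdb = PDBFile()
    if isinstance(obj, Trajectory):
        arrays = [_array_from_structure(obj.topology, f) for f in obj.frames]
        stack = bst.stack(arrays)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_array_from_structure(obj, obj.coords))
    pdb.write(str(path))


# ---------------------------------------------------------------------------

def discard_equilibration(traj: Trajectory,
                          fraction_or_frames: float | int) -> Trajectory:
    """Drop the leading equilibration segment and keep the trailing
    production segment.

    An integer argument is a frame count; a float in [0, 1) is a fraction of
    the trajectory.  The discard is recorded in ``info['discarded_frames']``.
    """
    n = traj.n_frames
    if isinstance(fraction_or_frames, float) and 0 <= fraction_or_frames < 1:
        k = int(round(fraction_or_frames * n))
    else:
        k = int(fraction_or_frames)
    if k < 0:
        raise RangeError(f"negative discard {k}")
    if k >= n:
        raise RangeError(f"discard of {k} frames >= trajectory length {n}")
    info = dict(traj.info)
    info["discarded_frames"] = k
    return Trajectory(traj.topology, traj.frames[k:],
                      frame_period=traj.frame_period, info=info)
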