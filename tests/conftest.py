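"""Shared fixtures: small random structures and trajectory factories."""

from __future__ import annotations

import numpy as np
import pytest

from trajkit.structure import Atom, Structure, Trajectory
from trajkit.elements import mass_of, radius_of

ELEMENTS = ["C", "N", "O", "S"]


def make_atom(i: int, name: str = "CA", element: str = "C",
              resid: int = 1, chain: str = "A",
              resname: str = "ALA") -> Atom:
    return Atom(i + 1, name, element, resname, resid, chain,
                mass_of(element, name), radius_of(element, name))


def random_structure(n: int, rng: np.random.Generator,
                     spread: float = 10.0) -> Structure:
    """n-atom structure with varied elements/residues and random coords."""
    atoms = []
    for i in range(n):
        element = ELEMENTS[i % len(ELEMENTS)]
        atoms.append(make_atom(i, name=f"{element}{i % 9}", element=element,
                               resid=i // 3 + 1))
    coords = rng.uniform(-spread, spread, (n, 3))
    return Structure(atoms, coords)


def chain_structure(n_residues: int, names=("N", "CA", "C"),
                    chain: str = "A", start: int = 1,
                    spacing: float = 3.8) -> Structure:
    """Extended pseudo-chain: one residue per rung, backbone names."""
    atoms, coords = [], []
    serial = 0
    for r in range(n_residues):
        for j, name in enumerate(names):
            element = "N" if name.startswith("N") else "C"
            atoms.append(make_atom(serial, name=name, element=element,
                                   resid=start + r, chain=chain))
            coords.append([r * spacing + 0.8 * j, 0.9 * j,
                           0.5 * (r % 3)])
            serial += 1
    return Structure(atoms, np.asarray(coords))


def static_trajectory(structure: Structure, n_frames: int) -> Trajectory:
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    return Trajectory(structure, frames)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
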