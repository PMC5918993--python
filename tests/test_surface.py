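"""Accessible surface area, buried area (dASA), gap volume and gap index."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trajkit.errors import SelectionError, UndefinedGapIndexError
from trajkit.structure import Structure, Trajectory
from trajkit.surface import (SurfaceParams, delta_asa, gap_index, gap_volume,
                             interface_series, sasa)

from conftest import make_atom, static_trajectory

PARAMS = SurfaceParams()


def sphere_structure(centers, element="C", radius_override=None):
    """Structure of bare spheres; optionally force one common radius."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    atoms = []
    for i in range(len(centers)):
        atom = make_atom(i, name=f"X{i}", element=element, resid=i + 1)
        if radius_override is not None:
            atom = type(atom)(atom.serial, atom.name, atom.element,
                              atom.residue_name, atom.residue_id,
                              atom.chain_id, atom.mass, radius_override)
        atoms.append(atom)
    return Structure(atoms, centers)


def slab_pair(separation: float, n: int = 7, spacing: float = 2.0):
    """Two parallel planar slabs of unit-ish spheres; surface-to-surface
    gap equals ``separation``."""
    half = (n - 1) / 2
    r = 1.7  # carbon vdw
    rows = []
    atoms = []
    k = 0
    for z, chain in ((0.0, "A"), (-(separation + 2 * r), "B")):
        for i in range(n):
            for j in range(n):
                atom = make_atom(k, name="XC", element="C", resid=k + 1)
                atom = type(atom)(atom.serial, atom.name, atom.element,
                                  atom.residue_name, atom.residue_id,
                                  chain, atom.mass, atom.radius)
                atoms.append(atom)
                rows.append([(i - half) * spacing, (j - half) * spacing, z])
                k += 1
    structure = Structure(atoms, np.asarray(rows))
    na = n * n
    return structure, np.arange(na), np.arange(na, 2 * na)


def two_sphere_accessible_area(r1, r2, d, probe):
    """Closed-form accessible area of two intersecting probe-inflated
    spheres (spherical-cap geometry)."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1 ** 2 + R2 ** 2)
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    x2 = d - x1
    h1 = R1 - x1
    h2 = R2 - x2
    return (4 * np.pi * R1 * R1 - 2 * np.pi * R1 * h1 +
            4 * np.pi * R2 * R2 - 2 * np.pi * R2 * h2)


# ---------------------------------------------------------------------------
# ASA
# ---------------------------------------------------------------------------

def test_single_sphere_matches_closed_form():
    structure = sphere_structure([[0.0, 0.0, 0.0]], radius_override=1.5)
    total, per_atom = sasa(structure, None, PARAMS)
    exact = 4 * np.pi * (1.5 + PARAMS.probe_radius) ** 2
    assert total == pytest.approx(exact, rel=0.01)
    assert per_atom.sum() == pytest.approx(total, rel=1e-12)


def test_distant_spheres_sum_isolated_areas():
    structure = sphere_structure([[0, 0, 0], [20, 0, 0]])
    total, _ = sasa(structure, None, PARAMS)
    alone, _ = sasa(sphere_structure([[0, 0, 0]]), None, PARAMS)
    assert total == pytest.approx(2 * alone, rel=1e-9)


@pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
def test_two_sphere_cap_formula_oracle(d):
    structure = sphere_structure([[0, 0, 0], [d, 0, 0]])
    total, _ = sasa(structure, None, PARAMS)
    r = structure.radii[0]
    exact = two_sphere_accessible_area(r, r, d, PARAMS.probe_radius)
    assert total == pytest.approx(exact, rel=0.01)


def test_per_atom_never_exceeds_isolated_sphere(rng):
    centers = rng.uniform(-4, 4, (12, 3))
    structure = sphere_structure(centers)
    _, per_atom = sasa(structure, None, PARAMS)
    caps = 4 * np.pi * (structure.radii + PARAMS.probe_radius) ** 2
    assert np.all(per_atom <= caps + 1e-9)


def test_asa_rigid_transform_invariant(rng):
    centers = rng.uniform(-4, 4, (10, 3))
    structure = sphere_structure(centers)
    total, _ = sasa(structure, None, PARAMS)
    rot = Rotation.from_euler("xyz", [31, -47, 112],
                              degrees=True).as_matrix()
    moved = structure.with_coords(centers @ rot.T + np.array([5, 6, -7.0]))
    total2, _ = sasa(moved, None, PARAMS)
    # the sampling lattice is fixed in space, so invariance holds only to
    # within quadrature noise
    assert total2 == pytest.approx(total, rel=0.01)


def test_context_occlusion_reduces_reported_area():
    structure = sphere_structure([[0, 0, 0], [3.0, 0, 0]])
    alone, _ = sasa(structure, [0], PARAMS)
    occluded, _ = sasa(structure, [0], PARAMS, context=[1])
    assert occluded < alone


def test_hydrogens_excluded_by_default():
    structure = sphere_structure([[0, 0, 0]], element="H")
    with pytest.raises(SelectionError):
        sasa(structure, None, PARAMS)


# ---------------------------------------------------------------------------
# delta ASA
# ---------------------------------------------------------------------------

def test_delta_asa_zero_for_separated_parts():
    structure = sphere_structure([[0, 0, 0], [30, 0, 0]])
    assert delta_asa(structure, [0], [1], PARAMS) == pytest.approx(0.0,
                                                                   abs=1e-9)


def test_delta_asa_matches_cap_burial():
    d = 3.0
    structure = sphere_structure([[0, 0, 0], [d, 0, 0]])
    value = delta_asa(structure, [0], [1], PARAMS)
    r = structure.radii[0]
    isolated = 4 * np.pi * (r + PARAMS.probe_radius) ** 2
    joint = two_sphere_accessible_area(r, r, d, PARAMS.probe_radius)
    exact = (2 * isolated - joint) / 2
    assert value == pytest.approx(exact, rel=0.01)


def test_delta_asa_symmetric_and_mirror_parts_equal():
    structure, ia, ib = slab_pair(3.0, n=4)
    ab = delta_asa(structure, ia, ib, PARAMS)
    ba = delta_asa(structure, ib, ia, PARAMS)
    assert ab == ba  # exact symmetry of Eq-style definition
    asa_a, _ = sasa(structure, ia, PARAMS)
    asa_b, _ = sasa(structure, ib, PARAMS)
    assert asa_a == pytest.approx(asa_b, rel=0.01)


def test_overlapping_parts_rejected():
    structure = sphere_structure([[0, 0, 0], [3, 0, 0]])
    with pytest.raises(SelectionError):
        delta_asa(structure, [0, 1], [1], PARAMS)


# ---------------------------------------------------------------------------
# gap volume (Monte-Carlo oracle)
# ---------------------------------------------------------------------------

def mc_gap_volume(structure, ia, ib, params, n_points=200_000, seed=7):
    """Independent Monte-Carlo integration of the documented gap-region
    predicate (plain re-implementation, no shared code path)."""
    rng = np.random.default_rng(seed)
    ca, ra = structure.coords[ia], structure.radii[ia]
    cb, rb = structure.coords[ib], structure.radii[ib]
    pad_a = ra.max() + params.max_gap_sphere
    pad_b = rb.max() + params.max_gap_sphere
    lo = np.maximum(ca.min(0) - pad_a, cb.min(0) - pad_b)
    hi = np.minimum(ca.max(0) + pad_a, cb.max(0) + pad_b)
    if np.any(hi <= lo):
        return 0.0
    pts = rng.uniform(lo, hi, (n_points, 3))
    box = np.prod(hi - lo)
    inside = 0
    for chunk in np.array_split(pts, 20):
        da_all = np.linalg.norm(chunk[:, None] - ca[None], axis=2) - ra
        db_all = np.linalg.norm(chunk[:, None] - cb[None], axis=2) - rb
        ja = da_all.argmin(1)
        jb = db_all.argmin(1)
        da = da_all.min(1)
        db = db_all.min(1)
        ua = ca[ja] - chunk
        ub = cb[jb] - chunk
        cosab = (ua * ub).sum(1) / (np.linalg.norm(ua, axis=1) *
                                    np.linalg.norm(ub, axis=1))
        keep = ((da > 0) & (db > 0) &
                (da <= params.max_gap_sphere) &
                (db <= params.max_gap_sphere) &
                (da + db >= 2 * params.min_gap_sphere) &
                (cosab <= -0.5))
        inside += int(keep.sum())
    return box * inside / n_points


def test_gap_volume_zero_when_unreachable():
    structure = sphere_structure([[0, 0, 0], [30, 0, 0]])
    with pytest.warns(UserWarning):
        v = gap_volume(structure, [0], [1], PARAMS)
    assert v == 0.0


def test_gap_volume_matches_monte_carlo_on_slabs():
    structure, ia, ib = slab_pair(3.0)
    grid = gap_volume(structure, ia, ib, PARAMS)
    mc = mc_gap_volume(structure, ia, ib, PARAMS)
    assert grid == pytest.approx(mc, rel=0.05)


def test_gap_volume_grid_convergence():
    structure, ia, ib = slab_pair(3.0)
    coarse = gap_volume(structure, ia, ib, PARAMS)
    fine = gap_volume(structure, ia, ib,
                      SurfaceParams(grid_spacing=PARAMS.grid_spacing / 2))
    assert fine == pytest.approx(coarse, rel=0.02)


def test_gap_metrics_monotone_as_slabs_approach():
    # larger probe so the shallow slab contact buries area at 4 A too
    params = SurfaceParams(probe_radius=2.5)
    indices = {}
    previous_volume = np.inf
    previous_index = np.inf
    for sep in (4.0, 3.0, 2.0):
        structure, ia, ib = slab_pair(sep)
        volume = gap_volume(structure, ia, ib, params)
        metrics = gap_index(structure, ia, ib, params)
        assert volume < previous_volume
        assert metrics.gap_index < previous_index
        assert metrics.gap_index == pytest.approx(
            metrics.gap_volume / metrics.delta_asa, rel=1e-12)
        previous_volume = volume
        previous_index = metrics.gap_index
        indices[sep] = metrics.gap_index
    # cross-check the ordering against the Monte-Carlo oracle route
    s_far, ia_f, ib_f = slab_pair(4.0)
    s_near, ia_n, ib_n = slab_pair(2.0)
    mc_far = mc_gap_volume(s_far, ia_f, ib_f, params)
    mc_near = mc_gap_volume(s_near, ia_n, ib_n, params)
    assert mc_near < mc_far


def test_gap_index_undefined_for_non_interacting_parts():
    structure = sphere_structure([[0, 0, 0], [30, 0, 0]])
    with pytest.warns(UserWarning):
        with pytest.raises(UndefinedGapIndexError):
            gap_index(structure, [0], [1], PARAMS)


# ---------------------------------------------------------------------------
# interface series
# ---------------------------------------------------------------------------

def test_interface_series_static_and_stride():
    structure, ia, ib = slab_pair(2.5, n=4)
    traj = static_trajectory(structure, 10)
    series = interface_series(traj, ia, ib, PARAMS, stride=2)
    assert len(series.frames) == 5
    summary = series.summary()
    assert summary["gap_index"]["sd"] == pytest.approx(0.0, abs=1e-9)
    assert summary["n_undefined"] == 0
    assert summary["params"]["grid_spacing"] == PARAMS.grid_spacing


def test_breathing_interface_mean_between_extremes():
    near, ia, ib = slab_pair(2.2, n=4)
    far = near.coords.copy()
    far[ib] -= np.array([0, 0, 0.4])
    frames = np.stack([near.coords, far] * 3)
    traj = Trajectory(near, frames)
    series = interface_series(traj, ia, ib, PARAMS, stride=1)
    values = [m.gap_index for m in series.metrics]
    mean = series.summary()["gap_index"]["mean"]
    assert min(values) <= mean <= max(values)
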