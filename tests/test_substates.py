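"""Substate clustering, contact occupancy and ligand mobility."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trajkit.errors import ContactSpecError, TrajkitError
from trajkit.structure import Structure, Trajectory
from trajkit.substates import (ContactSpec, cluster_substates,
                               contact_occupancy, ligand_mobility,
                               pairwise_rmsd, substate_series)
from trajkit.superpose import kabsch
from trajkit.synthetic import (GeneratorConfig, build_two_domain_system,
                               generate_trajectory)

from conftest import make_atom, random_structure, static_trajectory


def label_accuracy(truth: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of frames whose label matches under the best per-state
    mapping (majority vote)."""
    from collections import Counter
    mapping = {}
    for s in np.unique(truth):
        mapping[s] = Counter(labels[truth == s]).most_common(1)[0][0]
    return float(np.mean([mapping[s] == l for s, l in zip(truth, labels)]))


def three_state_trajectory(n_frames=500, seed=13):
    config = GeneratorConfig(
        seed=seed, n_frames=n_frames, n_grid=5,
        substate_displacements=[[0, 0, 0], [6, 0, 0], [0, 6, 0]],
        transition_matrix=[[0.94, 0.03, 0.03],
                           [0.03, 0.94, 0.03],
                           [0.03, 0.03, 0.94]])
    base = build_two_domain_system(config)
    traj, truth = generate_trajectory(base, config)
    return traj, truth


FIT = "chain B and resname FIL"
MEASURE = "chain B and resid 978-988 and name N,CA,C"


def test_identical_frames_single_cluster(rng):
    base = random_structure(10, rng)
    assignment = cluster_substates(static_trajectory(base, 8), cutoff=1.0)
    assert assignment.n_clusters == 1
    assert assignment.sizes == [8]
    assert np.all(assignment.labels == 0)


def test_two_alternating_conformations_two_clusters(rng):
    base = random_structure(10, rng)
    other = base.coords + rng.normal(0, 3.0, base.coords.shape)
    cutoff = kabsch(other, base.coords)[2] / 3.0
    frames = np.stack([base.coords, other] * 6)
    assignment = cluster_substates(Trajectory(base, frames), cutoff=cutoff)
    assert assignment.n_clusters == 2
    assert assignment.sizes == [6, 6]
    assert len(set(assignment.labels[::2])) == 1
    assert len(set(assignment.labels[1::2])) == 1


def test_three_state_markov_recovery():
    traj, truth = three_state_trajectory()
    assignment = cluster_substates(traj, FIT, MEASURE, cutoff=1.5)
    assert assignment.n_clusters >= 3
    assert label_accuracy(truth.states, assignment.labels) >= 0.95


def test_cluster_sizes_sum_and_order():
    traj, _ = three_state_trajectory(n_frames=200)
    assignment = cluster_substates(traj, FIT, MEASURE, cutoff=1.5)
    assert sum(assignment.sizes) == traj.n_frames
    assert assignment.sizes == sorted(assignment.sizes, reverse=True)
    assert sorted(set(assignment.labels)) == \
        list(range(assignment.n_clusters))


def test_frame_cap_instructs_striding(rng):
    base = random_structure(5, rng)
    traj = Trajectory(base, rng.normal(size=(30, 5, 3)))
    with pytest.raises(TrajkitError, match="stride"):
        cluster_substates(traj, cutoff=1.0, frame_cap=10)


def test_medoid_minimizes_summed_rmsd():
    traj, _ = three_state_trajectory(n_frames=60)
    assignment = cluster_substates(traj, FIT, MEASURE, cutoff=1.5)
    dist = assignment.rmsd_matrix
    for label, medoid in enumerate(assignment.medoids):
        members = np.flatnonzero(assignment.labels == label)
        sums = dist[np.ix_(members, members)].sum(axis=1)
        assert medoid == members[np.argmin(sums)]


def test_cluster_averages_near_generator_centers():
    traj, truth = three_state_trajectory(n_frames=400)
    assignment = cluster_substates(traj, FIT, MEASURE, cutoff=1.5)
    # cluster averages should be well separated: distance between cluster
    # average positions of the target segment ~ 6 A
    from trajkit.structure import resolve_selection
    target = resolve_selection(traj.topology, MEASURE).indices
    a0 = assignment.averages[0].coords[target]
    a1 = assignment.averages[1].coords[target]
    assert np.linalg.norm(a0.mean(0) - a1.mean(0)) > 4.0


def test_substate_series_labels_match(rng):
    base = random_structure(8, rng)
    other = base.coords + rng.normal(0, 3.0, base.coords.shape)
    frames = np.stack([base.coords, other] * 4)
    traj = Trajectory(base, frames)
    assignment = cluster_substates(traj, cutoff=0.5)
    table = substate_series(assignment, traj, base)
    assert set(table.columns) == {"frame", "rmsd", "label"}
    assert (table["label"][::2] == table["label"][0]).all()
    assert (table["label"][1::2] == table["label"][1]).all()


def test_pairwise_rmsd_matches_kabsch(rng):
    base = random_structure(7, rng)
    frames = base.coords[None] + rng.normal(0, 1.0, (6, 7, 3))
    traj = Trajectory(base, frames)
    matrix = pairwise_rmsd(traj)
    for i in range(6):
        for j in range(6):
            expected = kabsch(frames[j], frames[i])[2]
            assert matrix[i, j] == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def pair_structure(d: float, element_b="O"):
    atoms = [make_atom(0, name="C1", element="C", resid=1),
             make_atom(1, name="O1", element=element_b, resid=2)]
    coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    return Structure(atoms, coords)


def test_distance_cutoff_boundary_inclusive():
    structure = pair_structure(3.5)
    traj = static_trajectory(structure, 3)
    occ = contact_occupancy(traj, ContactSpec([0], [1], "distance", 3.5))
    assert occ.occupancy == 1.0
    just_outside = static_trajectory(pair_structure(3.5001), 3)
    occ2 = contact_occupancy(just_outside,
                             ContactSpec([0], [1], "distance", 3.5))
    assert occ2.occupancy == 0.0


def test_occupancy_seventy_percent_exact():
    structure = pair_structure(2.0)
    frames = np.repeat(structure.coords[None], 100, axis=0)
    frames[70:, 1, 0] = 10.0  # break the contact in 30 frames
    traj = Trajectory(structure, frames)
    occ = contact_occupancy(traj, ContactSpec([0], [1], "distance", 3.5))
    assert occ.occupancy == pytest.approx(0.70, abs=1e-12)


def hbond_system(angle_deg: float):
    """Donor O, its H, acceptor O with the D-H...A angle as requested."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([0.96, 0.0, 0.0])
    back = np.radians(180.0 - angle_deg)
    a = h + 1.95 * np.array([np.cos(back), np.sin(back), 0.0])
    atoms = [make_atom(0, name="OD", element="O", resid=1),
             make_atom(1, name="HD", element="H", resid=1),
             make_atom(2, name="OA", element="O", resid=2)]
    return Structure(atoms, np.stack([d, h, a]))


@pytest.mark.parametrize("angle,formed", [(165.0, True), (90.0, False)])
def test_hbond_angle_criterion(angle, formed):
    structure = hbond_system(angle)
    traj = static_trajectory(structure, 2)
    spec = ContactSpec([0, 1], [2], "hbond", cutoff=3.5, angle_min=120.0)
    occ = contact_occupancy(traj, spec)
    assert not occ.fallback_distance_only
    assert occ.occupancy == (1.0 if formed else 0.0)


def test_hbond_without_hydrogens_falls_back_flagged():
    atoms = [make_atom(0, name="O1", element="O", resid=1),
             make_atom(1, name="O2", element="O", resid=2)]
    structure = Structure(atoms, np.array([[0, 0, 0], [2.9, 0, 0.0]]))
    traj = static_trajectory(structure, 2)
    occ = contact_occupancy(traj, ContactSpec([0], [1], "hbond", 3.5))
    assert occ.fallback_distance_only
    assert occ.occupancy == 1.0


def test_hbond_without_donors_is_spec_error():
    structure = pair_structure(2.9)
    traj = static_trajectory(structure, 2)
    with pytest.raises(ContactSpecError):
        contact_occupancy(traj, ContactSpec([0], [1], "hbond", 3.5))


def test_coordination_criterion():
    atoms = [make_atom(0, name="MG", element="MG", resid=1),
             make_atom(1, name="O1", element="O", resid=2)]
    structure = Structure(atoms, np.array([[0, 0, 0], [2.4, 0, 0.0]]))
    occ = contact_occupancy(static_trajectory(structure, 2),
                            ContactSpec([0], [1], "coordination", 2.6))
    assert occ.occupancy == 1.0
    far = Structure(atoms, np.array([[0, 0, 0], [3.0, 0, 0.0]]))
    occ2 = contact_occupancy(static_trajectory(far, 2),
                             ContactSpec([0], [1], "coordination", 2.6))
    assert occ2.occupancy == 0.0


def test_occupancy_invariant_under_rigid_transform(rng):
    structure = pair_structure(3.0)
    frames = np.repeat(structure.coords[None], 10, axis=0)
    frames[5:, 1, 0] = 8.0
    traj = Trajectory(structure, frames)
    spec = ContactSpec([0], [1], "distance", 3.5)
    occ = contact_occupancy(traj, spec)
    rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    moved = Trajectory(structure, frames @ rot.T + np.array([1, 2, 3.0]))
    occ2 = contact_occupancy(moved, spec)
    assert occ.occupancy == occ2.occupancy
    np.testing.assert_allclose(occ.min_distance, occ2.min_distance,
                               atol=1e-9)


# ---------------------------------------------------------------------------
# ligand mobility
# ---------------------------------------------------------------------------

def ligand_system():
    config = GeneratorConfig(seed=17, n_frames=2, noise_sigma=0.0,
                             ligand=__import__("trajkit").LigandSpec(),
                             n_grid=5)
    return build_two_domain_system(config)


def test_rigidly_comoving_ligand_has_zero_positional_rmsd():
    base = ligand_system()
    traj = static_trajectory(base, 5)
    mob = ligand_mobility(traj, "name N,CA,C", "resname LIG")
    assert mob.positional_mean == pytest.approx(0.0, abs=1e-9)
    assert mob.internal_mean == pytest.approx(0.0, abs=1e-9)


def test_jittered_ligand_matches_sampling_oracle(rng):
    base = ligand_system()
    sigma, n = 0.2, 400
    frames = np.repeat(base.coords[None], n, axis=0)
    lig = [i for i, a in enumerate(base.atoms) if a.residue_name == "LIG"]
    frames[:, lig] += rng.normal(0, sigma, (n, len(lig), 3))
    traj = Trajectory(base, frames)
    mob = ligand_mobility(traj, "name N,CA,C", "resname LIG")
    expected = sigma * np.sqrt(3)
    assert mob.positional_mean == pytest.approx(expected, rel=0.10)
    assert mob.internal_mean > 0


def test_translated_ligand_internal_zero_positional_bimodal():
    base = ligand_system()
    shifted = base.coords.copy()
    lig = [i for i, a in enumerate(base.atoms) if a.residue_name == "LIG"]
    shifted[lig] += np.array([1.5, 0.0, 0.0])
    # 6:2 dwell so the two poses sit at different distances from the mean
    frames = np.stack([base.coords] * 6 + [shifted] * 2)
    traj = Trajectory(base, frames)
    mob = ligand_mobility(traj, "name N,CA,C", "resname LIG")
    assert mob.internal_mean == pytest.approx(0.0, abs=1e-9)
    values = np.unique(np.round(mob.positional, 6))
    assert len(values) == 2  # bimodal: two distinct poses
    np.testing.assert_allclose(sorted(values), [1.5 * 0.25, 1.5 * 0.75],
                               atol=1e-6)
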