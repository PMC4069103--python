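"""Trajectory I/O, superposition and RMSD/RMSF statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phstab.structio import (
    AtomRecord,
    DomainPartition,
    PDBFormatError,
    Selection,
    Trajectory,
    backbone_selection,
    calpha_selection,
    domain_residue_count,
    read_multimodel_pdb,
    rmsd_series,
    rmsf_profile,
    superpose,
    write_multimodel_pdb,
)

from conftest import make_topology


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def test_atom_record_rejects_nonpositive_residue_number():
    with pytest.raises(ValueError):
        AtomRecord("A", 0, "GLY", "CA", "C")


def test_trajectory_rejects_frame_atom_mismatch():
    topo = make_topology(3)
    with pytest.raises(ValueError, match="one position per topology atom"):
        Trajectory(topo, np.zeros((2, 4, 3)))


def test_partition_rejects_overlapping_and_inverted_ranges():
    with pytest.raises(ValueError, match="overlap"):
        DomainPartition({"D": [("B", 1, 10), ("B", 5, 20)]})
    with pytest.raises(ValueError, match="start"):
        DomainPartition({"D": [("B", 10, 5)]})


# ---------------------------------------------------------------------------
# multi-model PDB round trips
# ---------------------------------------------------------------------------

def _random_traj(rng, n_frames=3, n_atoms=5):
    topo = make_topology(n_atoms, resname="ALA", atom_name="CA")
    frames = rng.uniform(-50, 50, size=(n_frames, n_atoms, 3)).round(3)
    return Trajectory(topo, frames)


def test_single_model_pdb_reads_as_one_frame(tmp_path, rng):
    traj = _random_traj(rng, n_frames=1)
    path = tmp_path / "one.pdb"
    write_multimodel_pdb(traj, path)
    text = path.read_text()
    assert text.count("MODEL ") == 1 and text.count("ENDMDL") == 1
    back = read_multimodel_pdb(path)
    assert back.n_frames == 1 and back.n_atoms == 5


def test_multimodel_round_trip_preserves_coordinates(tmp_path, rng):
    traj = _random_traj(rng, n_frames=3)
    path = tmp_path / "three.pdb"
    write_multimodel_pdb(traj, path)
    back = read_multimodel_pdb(path)
    assert back.n_frames == 3
    np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)
    assert [a.residue_key for a in back.topology] == [a.residue_key for a in traj.topology]


def test_hetatm_waters_and_ions_survive_round_trip(tmp_path):
    topo = [
        AtomRecord("A", 1, "SER", "CA", "C"),
        AtomRecord("A", 2, "HOH", "O", "O"),
        AtomRecord("A", 3, "CA", "CA", "Ca"),
    ]
    traj = Trajectory(topo, np.arange(9.0).reshape(1, 3, 3))
    path = tmp_path / "het.pdb"
    write_multimodel_pdb(traj, path)
    back = read_multimodel_pdb(path)
    assert [a.residue_name for a in back.topology] == ["SER", "HOH", "CA"]


def test_roster_mismatch_names_offending_model(tmp_path, rng):
    traj = _random_traj(rng, n_frames=2)
    path = tmp_path / "bad.pdb"
    write_multimodel_pdb(traj, path)
    # drop one atom line from the second MODEL block
    lines = path.read_text().splitlines(keepends=True)
    second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
    atom_line = next(
        i for i, l in enumerate(lines[second_model:], start=second_model)
        if l.startswith(("ATOM", "HETATM"))
    )
    del lines[atom_line]
    path.write_text("".join(lines))
    with pytest.raises(PDBFormatError, match="model 2"):
        read_multimodel_pdb(path)


def test_write_requires_frames(rng):
    traj = _random_traj(rng, n_frames=1)
    traj.frames = traj.frames[:0]
    with pytest.raises(ValueError, match="no frames"):
        write_multimodel_pdb(traj, "/tmp/never.pdb")


def test_long_round_trip_stable(tmp_path, rng):
    traj = _random_traj(rng, n_frames=200, n_atoms=4)
    path = tmp_path / "long.pdb"
    write_multimodel_pdb(traj, path)
    back = read_multimodel_pdb(path)
    np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Kearsley quaternion eigenvalue method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    xm, ym, zm = (x - y).T
    xp, yp, zp = (x + y).T
    K = np.empty((4, 4))
    K[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    K[1, 1] = np.sum(xm**2 + yp**2 + zp**2)
    K[2, 2] = np.sum(xp**2 + ym**2 + zp**2)
    K[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    K[0, 1] = K[1, 0] = np.sum(yp * zm - ym * zp)
    K[0, 2] = K[2, 0] = np.sum(xm * zp - xp * zm)
    K[0, 3] = K[3, 0] = np.sum(xp * ym - xm * yp)
    K[1, 2] = K[2, 1] = np.sum(xm * ym - xp * yp)
    K[1, 3] = K[3, 1] = np.sum(xm * zm - xp * zp)
    K[2, 3] = K[3, 2] = np.sum(ym * zm - yp * zp)
    lam_min = np.linalg.eigvalsh(K)[0]
    return np.sqrt(max(lam_min, 0.0) / len(mobile))


def test_identical_sets_give_zero_rmsd_identity_rotation(rng):
    pts = rng.normal(size=(5, 3))
    res = superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)


def test_rigid_motion_recovered_exactly(rng):
    pts = rng.normal(size=(7, 3))
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
    res = superpose(pts, moved)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(res.apply(pts), moved, atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


@pytest.mark.parametrize("n_points", [4, 6, 10])
def test_superpose_matches_quaternion_oracle(rng, n_points):
    for _ in range(20):
        a = rng.normal(size=(n_points, 3))
        b = rng.normal(size=(n_points, 3))
        res = superpose(a, b)
        assert res.rmsd == pytest.approx(_quaternion_superpose_rmsd(a, b), abs=1e-8)
        # the reported transform attains the reported rmsd
        attained = np.sqrt(np.mean(np.sum((res.apply(a) - b) ** 2, axis=1)))
        assert attained == pytest.approx(res.rmsd, abs=1e-6)


def test_superpose_rejects_degenerate_input(rng):
    with pytest.raises(ValueError):
        superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
    line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
    with pytest.raises(ValueError, match="collinear"):
        superpose(line, line)


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

def test_identical_frames_give_zero_series(rng):
    topo = make_topology(5)
    frames = np.tile(rng.normal(size=(5, 3)), (4, 1, 1))
    traj = Trajectory(topo, frames)
    series = rmsd_series(traj, Selection())
    np.testing.assert_allclose(series.values, 0.0, atol=1e-9)


def test_single_displaced_atom_gives_d_over_sqrt_n(rng):
    n = 8
    topo = make_topology(n)
    ref = rng.normal(size=(n, 3))
    moved = ref.copy()
    d = 0.7
    moved[0] += np.array([d, 0, 0])
    traj = Trajectory(topo, np.stack([ref, moved]))
    fit_others = Selection(ranges=(("A", 2, n),))  # fit on the unmoved atoms
    series = rmsd_series(traj, Selection(), fit_others)
    assert series.values[1] == pytest.approx(d / np.sqrt(n), abs=1e-9)


def test_rmsd_series_matches_frame_by_frame_oracle(toy_trajectory):
    sel = Selection()
    series = rmsd_series(toy_trajectory, sel)
    ref = toy_trajectory.frames[0]
    for i in range(toy_trajectory.n_frames):
        fit = superpose(toy_trajectory.frames[i], ref)
        expected = np.sqrt(np.mean(np.sum((fit.apply(toy_trajectory.frames[i]) - ref) ** 2, axis=1)))
        assert series.values[i] == pytest.approx(expected, abs=1e-9)


def test_rmsd_invariant_under_rigid_motion_of_all_frames(toy_trajectory, rng):
    base = rmsd_series(toy_trajectory, Selection())
    R = Rotation.random(random_state=7).as_matrix()
    t = rng.normal(size=3) * 10
    moved = Trajectory(
        toy_trajectory.topology, toy_trajectory.frames @ R.T + t, toy_trajectory.frame_interval
    )
    series = rmsd_series(moved, Selection())
    np.testing.assert_allclose(series.values, base.values, atol=1e-6)


def test_empty_selection_rejected(toy_trajectory):
    with pytest.raises(ValueError):
        rmsd_series(toy_trajectory, Selection(chains=frozenset({"Z"})))


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def test_static_trajectory_has_zero_rmsf(rng):
    topo = make_topology(5)
    frame = rng.normal(size=(5, 3))
    traj = Trajectory(topo, np.tile(frame, (6, 1, 1)))
    profile = rmsf_profile(traj)
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in profile.values.values())


def test_alternating_atom_rmsf_is_d(rng):
    # one atom swings +/- d about its mean; many static anchors keep the
    # alignment essentially frozen
    n = 300
    d = 0.5
    topo = make_topology(n + 1)
    ref = rng.uniform(-20, 20, size=(n + 1, 3))
    frames = np.tile(ref, (10, 1, 1))
    frames[::2, -1, 0] = ref[-1, 0] + d
    frames[1::2, -1, 0] = ref[-1, 0] - d
    traj = Trajectory(topo, frames)
    profile = rmsf_profile(traj)
    assert profile[("A", n + 1)] == pytest.approx(d, rel=2e-2)
    assert profile[("A", 1)] == pytest.approx(0.0, abs=0.01)


def test_rmsf_matches_direct_definition_oracle(toy_trajectory):
    sel = calpha_selection()
    profile = rmsf_profile(toy_trajectory, sel, window_frames=8)
    idx = sel.resolve(toy_trajectory.topology)
    window = toy_trajectory.frames[-8:, idx, :]
    aligned = np.array([superpose(f, window[0]).apply(f) for f in window])
    mean = aligned.mean(axis=0)
    expected = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    for j, i in enumerate(idx):
        key = toy_trajectory.topology[i].residue_key
        assert profile[key] == pytest.approx(expected[j], abs=1e-9)


def test_rmsf_translation_invariant(toy_trajectory):
    base = rmsf_profile(toy_trajectory)
    moved = Trajectory(
        toy_trajectory.topology, toy_trajectory.frames + np.array([3.0, -2.0, 9.0])
    )
    shifted = rmsf_profile(moved)
    for key, val in base.items():
        assert shifted[key] == pytest.approx(val, abs=1e-8)


def test_rmsf_window_larger_than_trajectory_rejected(toy_trajectory):
    with pytest.raises(ValueError):
        rmsf_profile(toy_trajectory, window_frames=11)


# ---------------------------------------------------------------------------
# domain bookkeeping
# ---------------------------------------------------------------------------

def test_domain_residue_counts():
    partition = DomainPartition(
        {
            "B1": [("B", 1, 72), ("B", 146, 290), ("B", 452, 536)],
            "B2": [("B", 73, 145)],
            "single": [("B", 5, 5)],
        }
    )
    assert domain_residue_count(partition, "B1") == 302
    assert domain_residue_count(partition, "B2") == 73
    assert domain_residue_count(partition, "single") == 1
    with pytest.raises(KeyError):
        domain_residue_count(partition, "nope")


def test_selection_resolution_is_order_preserving():
    topo = make_topology(4) + [AtomRecord("B", 1, "ALA", "N", "N")]
    sel = backbone_selection([("A", 2, 3), ("B", 1, 1)])
    assert sel.resolve(topo).tolist() == [1, 2, 4]
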