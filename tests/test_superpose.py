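"""Kabsch superposition and the basic structural metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quatdyn as q
from quatdyn.errors import DegenerateGeometryError
from quatdyn.structure_model import Trajectory
from quatdyn.superpose import kabsch_fit, radius_of_gyration, rmsf

from conftest import make_model


def quaternion_fit_rmsd(mobile, target, weights=None):
    """Independent superposition oracle: Horn's quaternion eigenvalue method."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    x = mobile - (w @ mobile) / wsum
    y = target - (w @ target) / wsum
    s = (w[:, None] * x).T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    sq = (w * (x**2).sum(1)).sum() + (w * (y**2).sum(1)).sum()
    return np.sqrt(max(sq - 2.0 * lam, 0.0) / wsum)


def random_cloud(rng, n=10, scale=5.0):
    return scale * rng.standard_normal((n, 3))


def rotation_about_z(deg):
    a = np.radians(deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]
    )


def single_atom_trajectory(frames_xyz, mass_element="C"):
    model = make_model(
        [("CA", mass_element, "ALA", 80, "A")], [frames_xyz[0]]
    )
    return Trajectory(model, np.asarray(frames_xyz, float).reshape(-1, 1, 3))


class TestKabsch:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        pts = random_cloud(rng)
        fit = kabsch_fit(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-12)

    def test_recovers_90_degree_rotation(self):
        rng = np.random.default_rng(1)
        pts = random_cloud(rng)
        rot = rotation_about_z(90.0)
        fit = kabsch_fit(pts, pts @ rot.T)
        np.testing.assert_allclose(fit.rotation, rot, atol=1e-10)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            fit = kabsch_fit(random_cloud(rng), random_cloud(rng))
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(
                fit.rotation @ fit.rotation.T, np.eye(3), atol=1e-8
            )

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = random_cloud(rng)
            b = a @ rotation_about_z(rng.uniform(0, 180)).T
            b += 0.3 * rng.standard_normal(b.shape) + rng.uniform(-5, 5, 3)
            w = rng.uniform(0.1, 2.0, len(a))
            fit = kabsch_fit(a, b, weights=w)
            assert fit.rmsd == pytest.approx(
                quaternion_fit_rmsd(a, b, w), abs=1e-6
            )

    def test_symmetric_rmsd(self):
        rng = np.random.default_rng(4)
        a, b = random_cloud(rng), random_cloud(rng)
        assert kabsch_fit(a, b).rmsd == pytest.approx(
            kabsch_fit(b, a).rmsd, abs=1e-9
        )

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(line, line + 1.0)


class TestRmsdSeries:
    @pytest.fixture
    def toy_traj(self):
        base = np.array([[0.0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 0, 4]])
        frames = np.stack([base, base + np.array([1.0, 1.0, 1.0]), base * 1.1])
        model = make_model(
            [("CA", "C", "ALA", 80 + i, "A") for i in range(4)], base
        )
        return Trajectory(model, frames)

    def test_static_trajectory_is_zero(self, toy_traj):
        static = Trajectory(toy_traj.model, np.repeat(toy_traj.frames[:1], 3, axis=0))
        series = q.rmsd_series(static, static.frames[0])
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_fit_removes_pure_translation(self, toy_traj):
        series = q.rmsd_series(toy_traj, toy_traj.frames[0], fit=True)
        assert series[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_computed_value_without_fit(self, toy_traj):
        series = q.rmsd_series(toy_traj, toy_traj.frames[0], fit=False)
        # frame 1: every atom shifted by (1,1,1) → rmsd = sqrt(3)
        assert series[1] == pytest.approx(np.sqrt(3.0), abs=1e-9)
        # frame 2: per-atom displacement 0.1·|r_i|
        expected = np.sqrt(np.mean([0.0, 0.2**2, 0.3**2, 0.4**2]))
        assert series[2] == pytest.approx(expected, abs=1e-9)

    def test_fitted_never_exceeds_unfitted(self):
        rng = np.random.default_rng(8)
        base = random_cloud(rng, n=12)
        frames = base + 0.5 * rng.standard_normal((20, 12, 3))
        model = make_model(
            [("CA", "C", "ALA", 80 + i, "A") for i in range(12)], base
        )
        traj = Trajectory(model, frames)
        fitted = q.rmsd_series(traj, base, fit=True)
        unfitted = q.rmsd_series(traj, base, fit=False)
        assert np.all(fitted <= unfitted + 1e-9)

    def test_out_of_range_selection(self, toy_traj):
        with pytest.raises(IndexError):
            q.rmsd_series(toy_traj, toy_traj.frames[0], measure_selection=np.array([99]))


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        traj = single_atom_trajectory([[1.0, 2.0, 3.0]] * 10)
        np.testing.assert_allclose(q.rmsf(traj), 0.0, atol=1e-12)

    def test_two_point_oscillation_along_x(self):
        frames = [[+1.0, 0, 0], [-1.0, 0, 0]] * 25
        traj = single_atom_trajectory(frames)
        assert q.rmsf(traj)[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_gaussian_closed_form(self):
        rng = np.random.default_rng(12)
        sigma = 0.5
        frames = sigma * rng.standard_normal((10_000, 1, 3))
        traj = single_atom_trajectory([[0.0, 0, 0]])
        traj = Trajectory(traj.model, frames)
        expected = np.sqrt(3.0) * sigma
        assert q.rmsf(traj)[0] == pytest.approx(expected, rel=0.03)

    def test_invariant_under_rigid_motion_when_aligned(self):
        rng = np.random.default_rng(13)
        base = random_cloud(rng, n=8)
        frames = base + 0.2 * rng.standard_normal((50, 8, 3))
        model = make_model(
            [("CA", "C", "ALA", 80 + i, "A") for i in range(8)], base
        )
        plain = q.rmsf(Trajectory(model, frames), align=True)
        rot = rotation_about_z(40.0)
        moved = frames @ rot.T + np.array([10.0, -3.0, 7.0])
        transformed = q.rmsf(Trajectory(model, moved), align=True)
        np.testing.assert_allclose(plain, transformed, atol=1e-9)

    def test_window_is_half_open(self):
        frames = [[0.0, 0, 0]] * 5 + [[10.0, 0, 0]] * 5
        traj = single_atom_trajectory(frames)
        assert q.rmsf(traj, window=(0, 5))[0] == pytest.approx(0.0, abs=1e-12)


class TestRadiusOfGyration:
    def test_single_atom(self):
        assert radius_of_gyration(np.array([[1.0, 2, 3]]), np.array([12.0])) == 0.0

    def test_two_unit_masses_two_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_five_atom_direct_formula(self):
        rng = np.random.default_rng(21)
        coords = random_cloud(rng, n=5)
        masses = rng.uniform(1, 16, 5)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        expected = np.sqrt(
            (masses * ((coords - com) ** 2).sum(1)).sum() / masses.sum()
        )
        assert radius_of_gyration(coords, masses) == pytest.approx(
            expected, abs=1e-12
        )


class TestComDistance:
    def _traj(self, coords_frames, n_atoms):
        model = make_model(
            [("CA", "C", "ALA", 80 + i, "A") for i in range(n_atoms)],
            coords_frames[0],
        )
        return Trajectory(model, np.asarray(coords_frames, float))

    def test_coincident_groups(self):
        frames = [[[0.0, 0, 0], [2, 0, 0]]] * 3
        traj = self._traj(frames, 2)
        series = q.com_distance_series(
            traj, np.array([0, 1]), np.array([0, 1])
        )
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_three_four_five_triangle(self):
        frames = [[[0.0, 0, 0], [3.0, 4.0, 0]]]
        traj = self._traj(frames, 2)
        series = q.com_distance_series(
            traj, np.array([0]), np.array([1]), masses=np.ones(2)
        )
        assert series[0] == pytest.approx(5.0)

    def test_generator_monomer_com_distance(self, default_run):
        _, model, traj, truth = default_run
        hexamer = model.select("protein")
        for chain in "ABCDEF":
            monomer = model.select(f"protein and chain {chain}")
            series = q.com_distance_series(traj, hexamer, monomer)
            assert series.mean() == pytest.approx(
                truth.monomer_com_distance, rel=0.01
            )


@settings(max_examples=25, deadline=None)
@given(
    angle=st.floats(-179.0, 179.0),
    tx=st.floats(-20, 20),
    seed=st.integers(0, 2**16),
)
def test_fit_undoes_any_rigid_transform(angle, tx, seed):
    """Property: a rigidly transformed copy always fits back to RMSD 0."""
    rng = np.random.default_rng(seed)
    pts = random_cloud(rng, n=6)
    rot = rotation_about_z(angle)
    moved = pts @ rot.T + np.array([tx, 1.0, -2.0])
    assert kabsch_fit(pts, moved).rmsd == pytest.approx(0.0, abs=1e-8)
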