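"""Quasi-harmonic entropy: closed forms, sampling, and rigid-body removal."""

import math

import numpy as np
import pytest
from scipy import constants as codata

import quatdyn as q
from quatdyn.covariance_pca import CovarianceResult
from quatdyn.qh_entropy import (
    entropy_difference,
    mass_weighted_covariance,
    qh_corrected_entropy,
    schlitter_entropy,
)
from quatdyn.structure_model import Trajectory

from conftest import make_model


def closed_form_schlitter(variances_amu_A2, temperature):
    """Independent evaluation of (R/2)·Σ ln(1 + kTe²/ħ²·σ²) in kJ/(mol·K).

    Constants are pulled directly from scipy.constants here, separately
    from the package's own constants module.
    """
    scale = (
        codata.k
        * temperature
        * math.e**2
        / codata.hbar**2
        * codata.atomic_mass
        * 1e-20
    )
    return (
        0.5
        * codata.R
        * sum(math.log1p(scale * v) for v in np.atleast_1d(variances_amu_A2))
        / 1000.0
    )


def mw_cov_from_matrix(matrix, n_frames=100):
    n = matrix.shape[0] // 3
    return CovarianceResult(
        matrix=np.asarray(matrix, float),
        reference_mode="custom",
        reference_coords=np.zeros((n, 3)),
        atom_indices=np.arange(n),
        frame_window=(0, n_frames),
        n_frames=n_frames,
        mass_weighted=True,
    )


def jitter_trajectory(rng, n_atoms, n_frames, sigma, spread=20.0):
    base = spread * rng.standard_normal((n_atoms, 3))
    frames = base + sigma * rng.standard_normal((n_frames, n_atoms, 3))
    model = make_model(
        [("CA", "C", "ALA", 80 + i, "A") for i in range(n_atoms)], base
    )
    return Trajectory(model, frames)


class TestMassWeightedCovariance:
    def test_static_trajectory_is_zero(self):
        base = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]])
        model = make_model(
            [("CA", "C", "ALA", 80 + i, "A") for i in range(4)], base
        )
        traj = Trajectory(model, np.stack([base] * 6))
        cov = mass_weighted_covariance(traj, np.arange(4))
        np.testing.assert_allclose(cov.matrix, 0.0, atol=1e-12)
        assert cov.mass_weighted

    def test_mass_scaling_oracle(self):
        """Scaling all masses ×k scales every covariance block ×k."""
        rng = np.random.default_rng(1)
        traj_c = jitter_trajectory(rng, 5, 300, 0.3)
        specs = [("CA", "C", "ALA", 80 + i, "A") for i in range(5)]
        model_c = make_model(specs, traj_c.model.coordinates)
        # same coordinates, but every atom four carbon masses heavy
        atoms_heavy = [
            q.Atom(a.index, a.name, a.element, a.mass * 4.0, a.residue_name,
                   a.residue_number, a.chain_id)
            for a in model_c.atoms
        ]
        model_h = q.StructureModel(atoms_heavy, model_c.coordinates)
        traj_h = Trajectory(model_h, traj_c.frames)
        cov_c = mass_weighted_covariance(traj_c, np.arange(5))
        cov_h = mass_weighted_covariance(traj_h, np.arange(5))
        np.testing.assert_allclose(cov_h.matrix, 4.0 * cov_c.matrix, atol=1e-9)


class TestSchlitter:
    def test_zero_covariance_gives_zero_entropy(self):
        result = schlitter_entropy(mw_cov_from_matrix(np.zeros((6, 6))))
        assert result.S == 0.0

    def test_single_mode_closed_form(self):
        # one 1-D mode: m = 12 amu, positional variance 0.01 Å², T = 300 K
        m, var, temp = 12.0, 0.01, 300.0
        matrix = np.zeros((3, 3))
        matrix[0, 0] = m * var
        result = schlitter_entropy(mw_cov_from_matrix(matrix), temperature=temp)
        assert result.S == pytest.approx(
            closed_form_schlitter([m * var], temp), rel=1e-12
        )

    def test_sampled_gaussian_matches_closed_form_within_1pct(self):
        rng = np.random.default_rng(99)
        n_atoms, n_frames, temp = 8, 100_000, 300.0
        sigmas = rng.uniform(0.1, 0.5, n_atoms)
        mass = 12.011
        dev = rng.standard_normal((n_frames, n_atoms, 3)) * sigmas[None, :, None]
        dev = (dev * math.sqrt(mass)).reshape(n_frames, -1)
        matrix = dev.T @ dev / n_frames
        result = schlitter_entropy(mw_cov_from_matrix(matrix), temperature=temp)
        expected = closed_form_schlitter(np.repeat(mass * sigmas**2, 3), temp)
        assert result.S == pytest.approx(expected, rel=0.01)

    def test_monotone_in_eigenvalues(self):
        small = mw_cov_from_matrix(np.diag([0.1, 0.2, 0.3]))
        large = mw_cov_from_matrix(np.diag([0.2, 0.2, 0.3]))
        assert schlitter_entropy(large).S > schlitter_entropy(small).S

    def test_rejects_unweighted_covariance(self):
        cov = mw_cov_from_matrix(np.eye(3))
        cov.mass_weighted = False
        with pytest.raises(ValueError, match="mass-weighted"):
            schlitter_entropy(cov)


class TestQhCorrected:
    def test_pure_translation_yields_zero(self):
        base = np.array(
            [[0.0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5], [3, 3, 3]]
        )
        shifts = np.linspace(-2, 2, 40)
        frames = np.stack([base + np.array([s, 0, 0]) for s in shifts])
        model = make_model(
            [("CA", "C", "ALA", 80 + i, "A") for i in range(5)], base
        )
        traj = Trajectory(model, frames)
        result = qh_corrected_entropy(traj, np.arange(5))
        assert result.S == pytest.approx(0.0, abs=1e-9)
        assert result.dof_removed == 6

    def test_matches_schlitter_for_internal_jitter_only(self):
        rng = np.random.default_rng(5)
        traj = jitter_trajectory(rng, 40, 2000, 0.25)
        sel = np.arange(40)
        plain = schlitter_entropy(mass_weighted_covariance(traj, sel))
        corrected = qh_corrected_entropy(traj, sel)
        assert corrected.S == pytest.approx(plain.S, rel=1e-3)

    def test_removing_modes_never_increases_entropy(self):
        rng = np.random.default_rng(6)
        base = 15.0 * rng.standard_normal((10, 3))
        # jitter plus an incompletely-removed global wobble
        angles = np.radians(3.0 * np.sin(np.linspace(0, 8 * np.pi, 300)))
        frames = np.empty((300, 10, 3))
        for i, a in enumerate(angles):
            rot = np.array(
                [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
            )
            frames[i] = base @ rot.T
        frames += 0.1 * rng.standard_normal(frames.shape)
        model = make_model(
            [("CA", "C", "ALA", 80 + i, "A") for i in range(10)], base
        )
        traj = Trajectory(model, frames)
        sel = np.arange(10)
        plain = schlitter_entropy(mass_weighted_covariance(traj, sel))
        corrected = qh_corrected_entropy(traj, sel)
        assert corrected.S <= plain.S + 1e-12


class TestEntropyDifference:
    def test_equal_matrices_give_zero(self):
        cov = mw_cov_from_matrix(np.diag([0.3, 0.2, 0.1]))
        assert entropy_difference(cov, cov) == 0.0

    def test_antisymmetry(self):
        a = mw_cov_from_matrix(np.diag([0.3, 0.2, 0.1]))
        b = mw_cov_from_matrix(np.diag([0.5, 0.1, 0.4]))
        assert entropy_difference(a, b) == pytest.approx(
            -entropy_difference(b, a), abs=1e-15
        )

    def test_equals_entropy_subtraction(self):
        a = mw_cov_from_matrix(np.diag([0.3, 0.2, 0.1]))
        b = mw_cov_from_matrix(np.diag([0.5, 0.1, 0.4]))
        expected = schlitter_entropy(a).S - schlitter_entropy(b).S
        assert entropy_difference(a, b) == pytest.approx(expected, abs=1e-9)


class TestPipelineProperties:
    def test_invariant_under_rigid_transform_of_all_frames(self):
        rng = np.random.default_rng(7)
        traj = jitter_trajectory(rng, 15, 500, 0.3)
        sel = np.arange(15)
        s_plain = qh_corrected_entropy(traj, sel).S
        a = np.radians(35.0)
        rot = np.array(
            [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
        )
        moved = traj.frames @ rot.T + np.array([8.0, -2.0, 4.0])
        s_moved = qh_corrected_entropy(
            Trajectory(traj.model, moved), sel
        ).S
        assert s_moved == pytest.approx(s_plain, rel=1e-3)

    def test_generator_entropy_recovery_and_replica_spread(self, jitter_only_run):
        """Three independent seeds recover the analytic jitter entropy
        within 2%, and their spread gives a standard deviation."""
        spec0, model, _, _ = jitter_only_run
        # single-monomer selection: 168 dof converge well at 2000 frames
        sel = model.select("protein and chain A")
        values = []
        for seed in (101, 102, 103):
            spec = q.GeneratorSpec(
                n_frames=2000, seed=seed, rotation_mean=0.0, rotation_amplitude=0.0
            )
            _, traj, truth = q.generate(spec)
            values.append(
                schlitter_entropy(mass_weighted_covariance(traj, sel)).S
            )
            expected = truth.expected_schlitter(sel)
        values = np.array(values)
        assert np.all(np.abs(values - expected) / expected < 0.02)
        assert values.std() > 0  # replicas allow a standard deviation

    def test_frame_subsampling_stability(self, jitter_only_run):
        """Halving the frame count moves S by well under 1% when converged."""
        _, model, traj, _ = jitter_only_run
        sel = model.select("calpha and chain A")
        full = schlitter_entropy(mass_weighted_covariance(traj, sel)).S
        half_traj = Trajectory(traj.model, traj.frames[::2], traj.timestep * 2)
        half = schlitter_entropy(mass_weighted_covariance(half_traj, sel)).S
        assert abs(half - full) / full < 0.01
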