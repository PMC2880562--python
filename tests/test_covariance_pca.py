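"""Covariance matrices, correlation maps, and PCA against brute-force oracles."""

import numpy as np
import pytest

import quatdyn as q
from quatdyn.covariance_pca import (
    CorrelationMap,
    correlation_map,
    covariance_matrix,
    extreme_conformations,
    fuse_maps,
    pca,
)
from quatdyn.structure_model import Trajectory

from conftest import make_model


def brute_force_covariance(deviations):
    """Explicit double-loop covariance oracle over (F, 3N) deviations."""
    f, d = deviations.shape
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            acc = 0.0
            for t in range(f):
                acc += deviations[t, i] * deviations[t, j]
            out[i, j] = acc / f
    return out


def toy_trajectory(frames, n_atoms):
    model = make_model(
        [("CA", "C", "ALA", 80 + i, "A") for i in range(n_atoms)],
        np.asarray(frames, float)[0],
    )
    return Trajectory(model, np.asarray(frames, float))


class TestCovarianceMatrix:
    def test_static_trajectory_is_zero(self):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]])
        traj = toy_trajectory([base] * 5, 3)
        cov = covariance_matrix(traj, np.arange(3))
        np.testing.assert_allclose(cov.matrix, 0.0, atol=1e-12)

    def test_two_point_alternation_gives_unit_variance(self):
        # one mobile atom at x = ±1 plus a rigid 3-atom anchor for fitting
        anchor = np.array([[10.0, 0, 0], [0, 10, 0], [0, 0, 10]])
        frames = []
        for sign in [1, -1] * 10:
            frames.append(np.vstack([anchor, [sign * 1.0, 0.0, 0.0]]))
        traj = toy_trajectory(frames, 4)
        cov = covariance_matrix(
            traj, np.array([3]), fit_selection=np.array([0, 1, 2])
        )
        expected = np.zeros((3, 3))
        expected[0, 0] = 1.0
        np.testing.assert_allclose(cov.matrix, expected, atol=1e-10)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(42)
        base = 5.0 * rng.standard_normal((5, 3))
        frames = base + 0.4 * rng.standard_normal((50, 5, 3))
        traj = toy_trajectory(frames, 5)
        sel = np.arange(5)
        cov = covariance_matrix(traj, sel, keep_deviations=True)
        oracle = brute_force_covariance(cov.deviations)
        np.testing.assert_allclose(cov.matrix, oracle, atol=1e-10)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(43)
        base = 5.0 * rng.standard_normal((6, 3))
        frames = base + 0.3 * rng.standard_normal((40, 6, 3))
        traj = toy_trajectory(frames, 6)
        cov = covariance_matrix(traj, np.arange(6))
        np.testing.assert_allclose(cov.matrix, cov.matrix.T, atol=1e-12)
        evals = np.linalg.eigvalsh(cov.matrix)
        assert evals.min() >= -1e-8 * np.trace(cov.matrix)

    def test_single_frame_window_rejected(self):
        base = np.zeros((3, 3))
        traj = toy_trajectory([base] * 5, 3)
        with pytest.raises(ValueError, match="2 frames"):
            covariance_matrix(traj, np.arange(3), window=(0, 1))

    def test_trace_equals_sum_of_squared_rmsf(self, jitter_only_run):
        _, model, traj, _ = jitter_only_run
        sel = model.select("calpha and chain A")
        window = (0, 500)
        cov = covariance_matrix(traj, sel, window=window, fit_selection=sel)
        fluct = q.rmsf(traj, sel, window=window, align=True, fit_selection=sel)
        assert np.trace(cov.matrix) == pytest.approx(
            (fluct**2).sum(), rel=1e-6
        )


class TestCorrelationMap:
    def test_zero_covariance_gives_zero_map(self):
        base = np.array([[0.0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]])
        traj = toy_trajectory([base] * 4, 4)
        amap = correlation_map(covariance_matrix(traj, np.arange(4)))
        np.testing.assert_allclose(amap.map, 0.0, atol=1e-12)

    @pytest.mark.parametrize("phase,expected", [(+1.0, +1.0), (-1.0, -1.0)])
    def test_lockstep_and_antiphase_pairs(self, phase, expected):
        # two mobile atoms moving ±1 Å along x, in phase or anti-phase,
        # plus a rigid anchor that absorbs the fit
        anchor = np.array([[20.0, 0, 0], [0, 20, 0], [0, 0, 20]])
        frames = []
        for sign in [1.0, -1.0] * 10:
            frames.append(
                np.vstack(
                    [anchor, [sign, 0.0, 0.0], [phase * sign + 5.0, 5.0, 0.0]]
                )
            )
        traj = toy_trajectory(frames, 5)
        cov = covariance_matrix(
            traj, np.array([3, 4]), fit_selection=np.array([0, 1, 2])
        )
        amap = correlation_map(cov)
        assert amap.map[0, 1] == pytest.approx(expected, abs=1e-10)
        assert amap.map[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_fuse_is_identity_for_equal_maps(self):
        m = CorrelationMap(
            np.array([[1.0, 2.0], [2.0, 3.0]]), colorscale_limits=(-3, 3)
        )
        np.testing.assert_allclose(fuse_maps(m, m).map, m.map)

    def test_fuse_hand_assembled_3x3(self):
        a = CorrelationMap(np.full((3, 3), 1.0), (-1, 1))
        b = CorrelationMap(np.full((3, 3), 2.0), (-2, 2))
        fused = fuse_maps(a, b).map
        expected = np.array(
            [[1.0, 1, 1], [2, 1, 1], [2, 2, 1]]
        )
        np.testing.assert_allclose(fused, expected)
        assert not np.allclose(fused, fused.T)


class TestPCA:
    def _cov_from_matrix(self, matrix):
        from quatdyn.covariance_pca import CovarianceResult

        n = matrix.shape[0] // 3
        return CovarianceResult(
            matrix=matrix,
            reference_mode="custom",
            reference_coords=np.zeros((n, 3)),
            atom_indices=np.arange(n),
            frame_window=(0, 2),
            n_frames=2,
        )

    def test_diagonal_covariance(self):
        matrix = np.diag([4.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        result = pca(self._cov_from_matrix(matrix))
        np.testing.assert_allclose(result.eigenvalues[:2], [4.0, 1.0])
        assert abs(result.eigenvectors[0, 0]) == pytest.approx(1.0)

    def test_reconstruction_of_random_psd(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((12, 12))
        matrix = a @ a.T
        result = pca(self._cov_from_matrix(matrix))
        recon = (
            result.eigenvectors
            @ np.diag(result.eigenvalues)
            @ result.eigenvectors.T
        )
        np.testing.assert_allclose(recon, matrix, atol=1e-8)
        np.testing.assert_allclose(
            result.eigenvectors.T @ result.eigenvectors, np.eye(12), atol=1e-8
        )
        assert result.eigenvalues.sum() == pytest.approx(
            np.trace(matrix), rel=1e-6
        )

    def test_rank_one_lockstep_motion(self):
        anchor = np.array([[20.0, 0, 0], [0, 20, 0], [0, 0, 20]])
        frames = [
            np.vstack([anchor, [s, 0, 0], [s + 5.0, 0, 0]])
            for s in [1.0, -1.0] * 8
        ]
        traj = toy_trajectory(frames, 5)
        cov = covariance_matrix(
            traj, np.array([3, 4]), fit_selection=np.array([0, 1, 2])
        )
        result = pca(cov)
        assert result.eigenvalues[0] == pytest.approx(
            np.trace(cov.matrix), rel=1e-9
        )
        assert np.all(result.eigenvalues[1:] < 1e-10)

    def test_extreme_conformations_zero_projections(self):
        matrix = np.diag([1.0, 0.5, 0.2, 0.1, 0.05, 0.01])
        cov = self._cov_from_matrix(matrix)
        cov.deviations = np.zeros((4, 6))
        result = pca(cov)
        ref = np.arange(6, dtype=float).reshape(2, 3)
        plus, minus = extreme_conformations(result, 0, ref)
        np.testing.assert_allclose(plus, ref)
        np.testing.assert_allclose(minus, ref)

    def test_extreme_conformations_along_single_mode(self):
        anchor = np.array([[20.0, 0, 0], [0, 20, 0], [0, 0, 20]])
        frames = [
            np.vstack([anchor, [s, 0, 0], [5.0, 0, 0]])
            for s in [1.0, -1.0] * 8
        ]
        traj = toy_trajectory(frames, 5)
        cov = covariance_matrix(
            traj, np.array([3, 4]), fit_selection=np.array([0, 1, 2])
        )
        result = pca(cov)
        ref = cov.reference_coords
        plus, minus = extreme_conformations(result, 0, ref, 1.0)
        # only the oscillating atom's x-coordinate differs between extremes
        diff = np.abs(plus - minus)
        assert diff[0, 0] == pytest.approx(2.0, abs=1e-9)
        assert np.abs(diff).sum() == pytest.approx(2.0, abs=1e-9)


class TestReferencingContrast:
    def test_trimer_referencing_unmasks_rotation(self, clean_run):
        """Pure-oscillation hexamer: initial-structure trimer referencing
        must light up the mobile trimer's correlation block ≫ the
        window-mean hexamer referencing."""
        _, model, traj, _ = clean_run
        ca = model.select("calpha")
        abc_ca = model.select("calpha and chain A,B,C")

        hex_cov = covariance_matrix(traj, ca, "hexamer_mean")
        tri_cov = covariance_matrix(
            traj,
            ca,
            "trimer_fit_initial",
            fit_selection=abc_ca,
            reference_coords=model.coordinates,
        )
        hex_map = correlation_map(hex_cov).map
        tri_map = correlation_map(tri_cov).map

        chains = np.array([model.atoms[i].chain_id for i in ca])
        in_def = np.isin(chains, list("DEF"))
        cross_monomer = (chains[:, None] != chains[None, :]) & (
            in_def[:, None] & in_def[None, :]
        )
        tri_block = np.abs(tri_map[cross_monomer]).mean()
        hex_block = np.abs(hex_map[cross_monomer]).mean()
        assert tri_block > 5.0 * hex_block
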