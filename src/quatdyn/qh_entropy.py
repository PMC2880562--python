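"""Quasi-harmonic configurational entropy from mass-weighted covariance.

The Schlitter bound estimates the configurational entropy of a sampled
ensemble from the mass-weighted covariance σ of atomic positions::

    S ≤ (k_B/2) · ln det[ 1 + (k_B·T·e²/ħ²) · σ ]

with e Euler's number.  σ is built from frames rigid-body aligned
(whole-selection, mass-weighted fit) to a reference so that overall
translation and rotation do not contribute; internal collective motion
(e.g. inter-trimer rotation of a hexamer) does.

Because a Cartesian covariance is singular in the six rigid-body
directions, a corrected variant projects the 6-dimensional rigid-body
null space (3 translations + 3 infinitesimal rotations, built from the
reference geometry and mass-weighted Gram–Schmidt orthonormalized) out
of σ before evaluation.

Entropy differences between two states use the same regularized
determinants: ΔS = (k_B/2)·ln(det σ_a′ / det σ_b′) with
σ′ = 1 + const·σ.  (The difference formula is sometimes printed without
the logarithm; that form is dimensionally impossible and the log form is
what is implemented here.)

All determinants are evaluated as sums of eigenvalue logarithms.
Entropies are returned in kJ/(mol·K).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import R_GAS, schlitter_scale
from .covariance_pca import CovarianceResult
from .structure_model import Trajectory
from .superpose import align_frames

__all__ = [
    "EntropyResult",
    "mass_weighted_covariance",
    "schlitter_entropy",
    "qh_corrected_entropy",
    "entropy_difference",
    "rigid_body_modes",
]


@dataclasses.dataclass(frozen=True)
class EntropyResult:
    S: float  # kJ/(mol·K)
    method: str  # "schlitter" | "qh_corrected"
    temperature: float  # K
    n_frames: int
    n_atoms: int
    dof_removed: int = 0


def mass_weighted_covariance(
    traj: Trajectory,
    selection: np.ndarray,
    align_reference: np.ndarray | None = None,
    window: tuple[int, int | None] = (0, None),
) -> CovarianceResult:
    """Mass-weighted covariance σ_ab = √(m_a·m_b)·C_ab in amu·Å².

    Every frame is rigid-body aligned to ``align_reference`` (default:
    the first window frame) by a mass-weighted fit of the whole
    selection; deviations are taken from the window mean of the aligned
    frames.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("selection is empty")
    masses = traj.model.masses[sel]
    if np.any(masses <= 0):
        raise ValueError("zero- or negative-mass atom in selection")

    start, stop = window
    frames = traj.frames[start:stop]
    n_frames = frames.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    reference = frames[0] if align_reference is None else np.asarray(align_reference)

    aligned = align_frames(frames, sel, reference, weights=masses)
    sub = aligned[:, sel, :]
    dev = (sub - sub.mean(axis=0)).reshape(n_frames, -1)
    sqrt_m = np.repeat(np.sqrt(masses), 3)
    dev = dev * sqrt_m
    matrix = dev.T @ dev / n_frames
    matrix = 0.5 * (matrix + matrix.T)
    return CovarianceResult(
        matrix=matrix,
        reference_mode="hexamer_mean",
        reference_coords=sub.mean(axis=0),
        atom_indices=sel,
        frame_window=(start, start + n_frames),
        n_frames=n_frames,
        deviations=dev,
        masses=masses,
        mass_weighted=True,
    )


def _log_det_regularized(matrix: np.ndarray, temperature: float) -> float:
    """ln det(1 + scale·σ) via eigenvalues; tolerates tiny negatives."""
    scale = schlitter_scale(temperature)
    evals = np.linalg.eigvalsh(matrix)
    tol = -1e-8 * max(float(np.abs(evals).max()), 1.0)
    if evals.min(initial=0.0) < tol:
        raise ValueError(
            f"covariance not positive semidefinite: min eigenvalue {evals.min():g}"
        )
    return float(np.log1p(scale * np.clip(evals, 0.0, None)).sum())


def schlitter_entropy(
    mw_cov: CovarianceResult, temperature: float = 300.0
) -> EntropyResult:
    """Schlitter entropy bound of a mass-weighted covariance, kJ/(mol·K)."""
    if not mw_cov.mass_weighted:
        raise ValueError("schlitter_entropy requires a mass-weighted covariance")
    log_det = _log_det_regularized(mw_cov.matrix, temperature)
    s = 0.5 * R_GAS * log_det / 1000.0
    return EntropyResult(
        S=s,
        method="schlitter",
        temperature=temperature,
        n_frames=mw_cov.n_frames,
        n_atoms=mw_cov.n_atoms,
        dof_removed=0,
    )


def rigid_body_modes(
    reference: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Orthonormal mass-weighted rigid-body modes (3N, k≤6) of a geometry.

    Columns span the null space of internal motion: three translations
    and three infinitesimal rotations about the center of mass, built in
    √m-scaled coordinates and Gram–Schmidt orthonormalized.  Degenerate
    rotations (e.g. a single atom) are dropped.
    """
    reference = np.asarray(reference, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = reference.shape[0]
    com = (masses[:, None] * reference).sum(axis=0) / masses.sum()
    rel = reference - com
    sqrt_m = np.sqrt(masses)

    raw = []
    for axis in np.eye(3):
        raw.append((sqrt_m[:, None] * axis[None, :]).ravel())
    for axis in np.eye(3):
        raw.append((sqrt_m[:, None] * np.cross(axis[None, :], rel)).ravel())

    modes: list[np.ndarray] = []
    for vec in raw:
        v = vec.astype(float)
        for m in modes:
            v -= (m @ v) * m
        norm = np.linalg.norm(v)
        if norm > 1e-10 * np.sqrt(3 * n):
            modes.append(v / norm)
    return np.column_stack(modes) if modes else np.zeros((3 * n, 0))


def qh_corrected_entropy(
    traj: Trajectory,
    selection: np.ndarray,
    temperature: float = 300.0,
    align_reference: np.ndarray | None = None,
    window: tuple[int, int | None] = (0, None),
) -> EntropyResult:
    """Schlitter entropy with the rigid-body singularity projected out.

    The 6 rigid-body directions of the reference geometry are removed
    from the mass-weighted covariance before the quasi-harmonic
    evaluation; residual rigid-body variance (imperfectly removed by the
    per-frame fit) therefore cannot inflate the entropy.
    """
    mw_cov = mass_weighted_covariance(traj, selection, align_reference, window)
    modes = rigid_body_modes(
        mw_cov.reference_coords, traj.model.masses[np.asarray(selection, dtype=int)]
    )
    projector = np.eye(mw_cov.matrix.shape[0]) - modes @ modes.T
    projected = projector @ mw_cov.matrix @ projector
    projected = 0.5 * (projected + projected.T)
    log_det = _log_det_regularized(projected, temperature)
    s = 0.5 * R_GAS * log_det / 1000.0
    return EntropyResult(
        S=s,
        method="qh_corrected",
        temperature=temperature,
        n_frames=mw_cov.n_frames,
        n_atoms=mw_cov.n_atoms,
        dof_removed=modes.shape[1],
    )


def entropy_difference(
    cov_a: CovarianceResult,
    cov_b: CovarianceResult,
    temperature: float = 300.0,
) -> float:
    """ΔS = (k_B/2)·ln(det σ_a′/det σ_b′), kJ/(mol·K); antisymmetric in (a, b)."""
    if not (cov_a.mass_weighted and cov_b.mass_weighted):
        raise ValueError("entropy_difference requires mass-weighted covariances")
    if cov_a.matrix.shape != cov_b.matrix.shape:
        raise ValueError(
            f"dimension mismatch: {cov_a.matrix.shape} vs {cov_b.matrix.shape}"
        )
    log_a = _log_det_regularized(cov_a.matrix, temperature)
    log_b = _log_det_regularized(cov_b.matrix, temperature)
    return 0.5 * R_GAS * (log_a - log_b) / 1000.0
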