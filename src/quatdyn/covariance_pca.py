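"""Atomic-displacement covariance matrices, correlation maps, and PCA.

The covariance matrix over a selection of N atoms is 3N×3N, in Å²::

    C_ij = ⟨ (x_i − x̄_i)(x_j − x̄_j) ⟩

with ⟨⟩ the average over a frame window, after each frame has been
rigid-body fitted to a reference on a fit selection.  Two referencing
modes matter for quaternary dynamics:

``hexamer_mean``
    fit on the whole selection; deviations from the window-mean
    structure.  Rigid inter-trimer motion is absorbed by the fit and is
    largely invisible.

``trimer_fit_initial``
    fit on one trimer only; deviations from the *initial* (reference)
    structure.  Rigid rotation of the opposite trimer then shows up as a
    coherent, strongly positive block of pair correlations — this is the
    unmasking trick that exposes inter-trimer rotation.

Normalization is by the number of frames (population covariance).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structure_model import Trajectory
from .superpose import align_frames

__all__ = [
    "CovarianceResult",
    "CorrelationMap",
    "PCAResult",
    "covariance_matrix",
    "correlation_map",
    "fuse_maps",
    "pca",
    "extreme_conformations",
]

REFERENCE_MODES = ("hexamer_mean", "trimer_fit_initial", "custom")


@dataclasses.dataclass
class CovarianceResult:
    """3N×3N covariance (Å²) plus the bookkeeping needed to reuse it."""

    matrix: np.ndarray
    reference_mode: str
    reference_coords: np.ndarray
    atom_indices: np.ndarray
    frame_window: tuple[int, int]
    n_frames: int
    deviations: np.ndarray | None = None  # (F, 3N), kept for projections
    masses: np.ndarray | None = None
    mass_weighted: bool = False

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0] // 3


@dataclasses.dataclass
class CorrelationMap:
    """N×N per-atom-pair map: C_xx + C_yy + C_zz (Å²)."""

    map: np.ndarray
    colorscale_limits: tuple[float, float]


@dataclasses.dataclass
class PCAResult:
    eigenvalues: np.ndarray  # Å², descending
    eigenvectors: np.ndarray  # columns, orthonormal 3N-vectors
    projections: np.ndarray | None  # (F, n_modes) per-frame scores


def covariance_matrix(
    traj: Trajectory,
    selection: np.ndarray,
    reference_mode: str = "hexamer_mean",
    fit_selection: np.ndarray | None = None,
    window: tuple[int, int | None] = (0, None),
    reference_coords: np.ndarray | None = None,
    fit_weights: np.ndarray | None = None,
    keep_deviations: bool = True,
) -> CovarianceResult:
    """Displacement covariance of ``selection`` over a frame window.

    ``fit_selection`` names the atoms used for the per-frame rigid-body
    fit (defaults to ``selection``).  In ``trimer_fit_initial`` mode
    deviations are taken from the reference structure itself (default:
    the first window frame) rather than from the window mean, matching
    the initial-structure referencing used for rotation analyses.
    """
    if reference_mode not in REFERENCE_MODES:
        raise ValueError(
            f"reference_mode must be one of {REFERENCE_MODES}, got {reference_mode!r}"
        )
    sel = np.asarray(selection, dtype=int)
    n_total = traj.model.n_atoms
    if sel.size == 0:
        raise ValueError("selection is empty")
    if sel.max() >= n_total or sel.min() < 0:
        raise IndexError(f"selection index out of range for {n_total} atoms")
    fsel = sel if fit_selection is None else np.asarray(fit_selection, dtype=int)
    if fsel.max(initial=0) >= n_total or fsel.min(initial=0) < 0:
        raise IndexError(f"fit_selection index out of range for {n_total} atoms")

    start, stop = window
    frames = traj.frames[start:stop]
    n_frames = frames.shape[0]
    if n_frames < 2:
        raise ValueError(
            f"covariance needs at least 2 frames, window selects {n_frames}"
        )
    stop_resolved = start + n_frames

    reference = frames[0] if reference_coords is None else np.asarray(reference_coords)

    if reference_mode == "hexamer_mean":
        # fit to the reference once, take the mean, re-fit to the mean,
        # and accumulate deviations from that mean
        aligned = align_frames(frames, fsel, reference, fit_weights)
        mean = aligned.mean(axis=0)
        aligned = align_frames(aligned, fsel, mean, fit_weights)
        center = aligned[:, sel, :].mean(axis=0)
    else:
        aligned = align_frames(frames, fsel, reference, fit_weights)
        center = reference[sel]

    dev = (aligned[:, sel, :] - center).reshape(n_frames, -1)
    matrix = dev.T @ dev / n_frames
    matrix = 0.5 * (matrix + matrix.T)
    return CovarianceResult(
        matrix=matrix,
        reference_mode=reference_mode,
        reference_coords=center,
        atom_indices=sel,
        frame_window=(start, stop_resolved),
        n_frames=n_frames,
        deviations=dev if keep_deviations else None,
    )


def correlation_map(cov: CovarianceResult) -> CorrelationMap:
    """Collapse a 3N×3N covariance into the N×N map C_xx + C_yy + C_zz."""
    n = cov.n_atoms
    c = cov.matrix.reshape(n, 3, n, 3)
    amap = np.einsum("ikjk->ij", c)
    amap = 0.5 * (amap + amap.T)
    vmax = float(np.abs(amap).max()) if amap.size else 0.0
    return CorrelationMap(map=amap, colorscale_limits=(-vmax, vmax))


def fuse_maps(upper: CorrelationMap, lower: CorrelationMap) -> CorrelationMap:
    """Fuse two maps along the diagonal to eliminate redundancy.

    The upper-left triangle (including the diagonal) comes from the first
    map, the lower-right triangle from the second — the display trick for
    comparing two simulations in a single panel.
    """
    a, b = upper.map, lower.map
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    fused = np.triu(a) + np.tril(b, k=-1)
    lo = min(upper.colorscale_limits[0], lower.colorscale_limits[0])
    hi = max(upper.colorscale_limits[1], lower.colorscale_limits[1])
    return CorrelationMap(map=fused, colorscale_limits=(lo, hi))


def _fix_eigenvector_signs(vectors: np.ndarray) -> np.ndarray:
    """Sign convention: largest-magnitude component of each vector positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def pca(cov: CovarianceResult) -> PCAResult:
    """Eigen-decompose a covariance matrix into principal motions.

    Eigenvalues are returned in descending order and sum to the matrix
    trace.  Per-frame projections (scores) are computed when the
    covariance result retained its deviation matrix.
    """
    evals, evecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_eigenvector_signs(evecs[:, order])
    projections = None
    if cov.deviations is not None:
        projections = cov.deviations @ evecs
    return PCAResult(eigenvalues=evals, eigenvectors=evecs, projections=projections)


def extreme_conformations(
    pca_result: PCAResult,
    component: int,
    reference_coords: np.ndarray,
    amplitude_quantile: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates at ± the observed amplitude along one principal mode.

    The amplitude is the given quantile of |projection| along the chosen
    component (1.0 → the maximum observed score).  Returns the pair of
    (N, 3) coordinate sets ``reference ± amplitude · eigenvector``.
    """
    if pca_result.projections is None:
        raise ValueError("PCA result has no projections; recompute with deviations")
    if not 0.0 <= amplitude_quantile <= 1.0:
        raise ValueError("amplitude_quantile must lie in [0, 1]")
    scores = np.abs(pca_result.projections[:, component])
    amplitude = float(np.quantile(scores, amplitude_quantile))
    mode = pca_result.eigenvectors[:, component].reshape(-1, 3)
    ref = np.asarray(reference_coords, dtype=float)
    if ref.shape != mode.shape:
        raise ValueError(
            f"reference shape {ref.shape} does not match mode shape {mode.shape}"
        )
    return ref + amplitude * mode, ref - amplitude * mode
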