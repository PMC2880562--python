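"""Weighted least-squares superposition and basic structural metrics.

The workhorse is the Kabsch algorithm: given two matched point sets and
non-negative weights, find the proper rotation + translation minimizing
the weighted RMSD.  Reflections are explicitly excluded.  On top of it
sit the standard per-trajectory metrics: RMSD series, RMSF, radius of
gyration, and center-of-mass distance series.

Conventions: RMSD/RMSF divide by the number of points (population
normalization, the usual MD convention); RMSF windows are half-open
frame ranges [start, stop); alignment defaults to mass weights, Cα RMSD
reporting to uniform weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateGeometryError
from .structure_model import Trajectory

__all__ = [
    "FitResult",
    "kabsch_fit",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "com_distance_series",
    "align_frames",
]


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Optimal rigid-body transform: y ≈ x @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    weights_used: np.ndarray

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (N, 3) coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation


def _check_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights shape {w.shape} does not match {n} points")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("weights must not all be zero")
    return w


def kabsch_fit(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Weighted Kabsch superposition of ``mobile`` onto ``target``.

    Returns the proper rotation (det = +1) and translation minimizing the
    weighted RMSD.  Raises :class:`DegenerateGeometryError` for fewer
    than three points or a rank-deficient (collinear) configuration.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"point sets must both be (N, 3); got {mobile.shape} vs {target.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    w = _check_weights(weights, n)
    wsum = w.sum()
    mob_c = mobile - (w @ mobile) / wsum
    tgt_c = target - (w @ target) / wsum

    h = (w[:, None] * mob_c).T @ tgt_c
    u, s, vt = np.linalg.svd(h)
    # collinear/degenerate input: two vanishing singular values
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-10:
        raise DegenerateGeometryError(
            "rank-deficient configuration (points are collinear or coincident)"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = (w @ target) / wsum - ((w @ mobile) / wsum) @ rotation.T
    fitted = mobile @ rotation.T + translation
    value = float(np.sqrt((w * ((fitted - target) ** 2).sum(axis=1)).sum() / wsum))
    return FitResult(rotation, translation, value, w)


def rmsd(
    a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Plain (no-fit) weighted RMSD between two matched coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = _check_weights(weights, a.shape[0])
    return float(np.sqrt((w * ((a - b) ** 2).sum(axis=1)).sum() / w.sum()))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
    fit: bool = True,
    fit_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) of ``measure_selection`` against a reference.

    When ``fit`` is set each frame is first superposed on the reference
    using ``fit_selection`` (defaults to the measured atoms).  The fitted
    RMSD is never larger than the unfitted one.
    """
    reference = np.asarray(reference, dtype=float)
    n = traj.model.n_atoms
    measure = (
        np.arange(n) if measure_selection is None else np.asarray(measure_selection)
    )
    if measure.size == 0:
        raise ValueError("measure_selection is empty")
    if measure.max(initial=0) >= n or measure.min(initial=0) < 0:
        raise IndexError(f"selection index out of range for {n} atoms")
    fit_sel = measure if fit_selection is None else np.asarray(fit_selection)

    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        if fit:
            result = kabsch_fit(frame[fit_sel], reference[fit_sel], fit_weights)
            frame = result.transform(frame)
        out[i] = rmsd(frame[measure], reference[measure])
    return out


def align_frames(
    frames: np.ndarray,
    fit_selection: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Rigid-body fit every frame onto ``reference`` using ``fit_selection``.

    The transform is determined on the fit selection but applied to all
    atoms of each frame.  Returns a new frame stack.
    """
    aligned = np.empty_like(frames)
    ref_sel = reference[fit_selection]
    for i, frame in enumerate(frames):
        result = kabsch_fit(frame[fit_selection], ref_sel, weights)
        aligned[i] = result.transform(frame)
    return aligned


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    window: tuple[int, int | None] = (0, None),
    align: bool = False,
    fit_selection: np.ndarray | None = None,
    fit_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom RMS fluctuation (Å) about the window-mean position.

    ``window`` is a half-open frame range.  With ``align`` set, frames
    are first fitted to the first window frame on ``fit_selection``
    (defaulting to the measured selection), then re-fitted to the
    resulting mean — this makes the result invariant under rigid-body
    motion of the whole window.
    """
    start, stop = window
    frames = traj.frames[start:stop]
    if frames.shape[0] < 1:
        raise ValueError(f"window [{start}, {stop}) selects no frames")
    sel = (
        np.arange(traj.model.n_atoms) if selection is None else np.asarray(selection)
    )
    if align:
        fsel = sel if fit_selection is None else np.asarray(fit_selection)
        frames = align_frames(frames, fsel, frames[0], fit_weights)
        mean = frames.mean(axis=0)
        frames = align_frames(frames, fsel, mean, fit_weights)
    sub = frames[:, sel, :]
    dev = sub - sub.mean(axis=0)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration (Å) of one coordinate frame."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    return float(
        np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / masses.sum())
    )


def com_distance_series(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame distance (Å) between the mass-weighted COMs of two groups."""
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both groups must be non-empty")
    m = traj.model.masses if masses is None else np.asarray(masses, dtype=float)
    wa = m[ga] / m[ga].sum()
    wb = m[gb] / m[gb].sum()
    com_a = np.einsum("i,fij->fj", wa, traj.frames[:, ga, :])
    com_b = np.einsum("i,fij->fj", wb, traj.frames[:, gb, :])
    return np.linalg.norm(com_a - com_b, axis=1)
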