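"""Interface observables: diagonal pocket distances, Δδ, and dihedrals.

The quaternary ensemble of a two-trimer hexamer is summarized by six
Cα–Cα distances that span the inter-trimer interface diagonally across
each ligand-binding pocket (canonically Gly103 of one subunit to Asp128
of the subunit diagonally across).  Subtracting a reference distance —
the value in the ligand-bound crystal form, 9.8 Å for EcArgRC — turns
each raw distance into a deviation Δδ whose distribution separates the
mean quaternary shift (histogram center) from oscillation (histogram
breadth).  Distances are frame-internal: no fitting is applied, so the
series is invariant under rigid-body motion.

Sidechain dihedral series use circular statistics, since spreads of
tens of degrees routinely cross the ±180° wrap-around.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import circmean, circstd

from .structure_model import StructureModel, Trajectory

__all__ = [
    "PairScheme",
    "DeltaDeltaSeries",
    "default_pair_scheme",
    "pair_distances",
    "delta_delta",
    "histogram",
    "dihedral_series",
    "dihedral",
]

AtomSpec = tuple[str, int, str]  # (chain, residue number, atom name)


@dataclasses.dataclass(frozen=True)
class PairScheme:
    """Atom pairs spanning the inter-trimer interface (six for a hexamer)."""

    pairs: tuple[tuple[AtomSpec, AtomSpec], ...]

    def resolve(self, model: StructureModel) -> np.ndarray:
        """Map pair specs to (n_pairs, 2) atom indices; errors name the pair."""
        lookup = {
            (a.chain_id, a.residue_number, a.name.upper()): a.index
            for a in model.atoms
        }
        out = []
        for spec_a, spec_b in self.pairs:
            row = []
            for chain, resnum, name in (spec_a, spec_b):
                key = (chain, resnum, name.upper())
                if key not in lookup:
                    raise KeyError(
                        f"pair {spec_a}–{spec_b}: atom "
                        f"{chain}:{resnum}:{name} not present in model"
                    )
                row.append(lookup[key])
            out.append(row)
        return np.array(out, dtype=int)


def default_pair_scheme(
    model: StructureModel,
    residue_a: int = 103,
    residue_b: int = 128,
    atom_name: str = "CA",
) -> PairScheme:
    """The canonical six diagonal pairs of a partitioned hexamer.

    Chain k of one trimer pairs residue ``residue_a`` with residue
    ``residue_b`` of the positionally matched chain of the other trimer
    (A↔D, B↔E, C↔F in deposition order), in both directions — six pairs.
    The exact chain pairing of a real deposition is a configuration
    choice; this default matches the synthetic generator's geometry.
    """
    groups = model.trimer_groups()
    if len(groups) != 2:
        raise ValueError("model must be partitioned into two trimer groups")
    chains_a = sorted(
        c for c, g in model.trimer_partition.items() if g == groups[0]
    )
    chains_b = sorted(
        c for c, g in model.trimer_partition.items() if g == groups[1]
    )
    if len(chains_a) != len(chains_b):
        raise ValueError("trimer groups have unequal chain counts")
    pairs = []
    for ca, cb in zip(chains_a, chains_b):
        pairs.append(((ca, residue_a, atom_name), (cb, residue_b, atom_name)))
        pairs.append(((cb, residue_a, atom_name), (ca, residue_b, atom_name)))
    return PairScheme(pairs=tuple(pairs))


@dataclasses.dataclass
class DeltaDeltaSeries:
    raw: np.ndarray  # (F, n_pairs) or (F,) distances, Å
    delta: np.ndarray  # raw − reference_distance
    reference_distance: float
    averaging: str  # "per_pair" | "hexamer_mean"
    bin_width: float
    histogram: dict[float, int]  # bin left edge → count


def pair_distances(traj: Trajectory, scheme: PairScheme) -> np.ndarray:
    """Per-frame Euclidean distances (Å) for each scheme pair, no fitting."""
    idx = scheme.resolve(traj.model)
    diff = traj.frames[:, idx[:, 0], :] - traj.frames[:, idx[:, 1], :]
    return np.linalg.norm(diff, axis=2)


def histogram(values: np.ndarray, bin_width: float = 0.1) -> dict[float, int]:
    """Bin values into half-open bins [k·w, (k+1)·w); counts are conserved.

    Negative values land in negative-index bins.  Keys are bin left
    edges.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        return {}
    indices = np.floor(values / bin_width).astype(int)
    out: dict[float, int] = {}
    for k, count in zip(*np.unique(indices, return_counts=True)):
        out[round(float(k) * bin_width, 12)] = int(count)
    return out


def delta_delta(
    series: np.ndarray,
    reference_distance: float,
    averaging: str = "hexamer_mean",
    bin_width: float = 0.1,
    stride: int = 1,
) -> DeltaDeltaSeries:
    """Normalize a distance series to deviations Δδ and histogram them.

    ``hexamer_mean`` averages the pair distances within each frame
    before tabulation (one Δδ value per frame); ``per_pair`` keeps every
    pair as its own series.  ``stride`` subsamples frames before
    tabulation (e.g. every 50 ps).
    """
    if averaging not in ("per_pair", "hexamer_mean"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    raw = np.asarray(series, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    raw = raw[::stride]
    if averaging == "hexamer_mean":
        raw = raw.mean(axis=1)
    delta = raw - reference_distance
    return DeltaDeltaSeries(
        raw=raw,
        delta=delta,
        reference_distance=float(reference_distance),
        averaging=averaging,
        bin_width=float(bin_width),
        histogram=histogram(delta, bin_width),
    )


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (deg) in (−180, 180], standard convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    angle = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(angle, -180.0) else angle


def dihedral_series(
    traj: Trajectory, four_atoms: tuple[int, int, int, int]
) -> tuple[np.ndarray, float, float]:
    """Per-frame dihedral (deg) plus its circular mean and circular sd."""
    i, j, k, l = four_atoms
    angles = np.array(
        [dihedral(f[i], f[j], f[k], f[l]) for f in traj.frames]
    )
    mean = float(np.degrees(circmean(np.radians(angles))))
    if mean > 180.0:
        mean -= 360.0
    sd = float(np.degrees(circstd(np.radians(angles))))
    return angles, mean, sd
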