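"""Linear interaction energy (LIE) binding free energies and enthalpies.

The LIE estimate of a binding free energy is

    ΔG = α·(⟨V_lj⟩_bound − ⟨V_lj⟩_free) + β·(⟨V_elec⟩_bound − ⟨V_elec⟩_free)

where the averages are ligand–environment interaction-energy means over
the bound (ligand in the protein + surrounding water) and free (ligand
alone in water) simulations.  The default scaling factors α = 0.18 and
β = 0.50 are the standard values for small, charged ligands, and the
default free-state reference means (−4.63 kJ/mol Lennard-Jones,
−453.458 kJ/mol electrostatic) are those of free L-arginine in SPC
water.

The binding enthalpy is the nonbonded interaction-energy difference

    ΔH = ⟨V(protein·ligand)⟩ + ⟨V(ligand·water)_bound⟩ − ⟨V(ligand·water)_free⟩

with electrostatic and Lennard-Jones components summed within each term.

A minimal Coulomb + Lennard-Jones evaluator is provided for synthetic
systems (plain cutoff, Lorentz–Berthelot combining); it is not a force
field.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import COULOMB_KJ_MOL_NM

__all__ = [
    "EnergyTerms",
    "LIEResult",
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
    "FREE_LIGAND_WATER_ELEC",
    "FREE_LIGAND_WATER_LJ",
    "default_free_terms",
    "lie_free_energy",
    "binding_enthalpy",
    "nonbonded_energy",
    "read_energy_tsv",
    "write_energy_tsv",
    "read_xvg",
]

DEFAULT_ALPHA = 0.18
DEFAULT_BETA = 0.50

#: Free L-arg in SPC water reference means, kJ/mol.
FREE_LIGAND_WATER_ELEC = -453.458
FREE_LIGAND_WATER_LJ = -4.63

CONTEXTS = ("ligand_protein_bound", "ligand_water_bound", "ligand_water_free")


@dataclasses.dataclass
class EnergyTerms:
    """Per-frame electrostatic and Lennard-Jones series, kJ/mol."""

    elec: np.ndarray
    lj: np.ndarray
    context: str

    def __post_init__(self) -> None:
        self.elec = np.atleast_1d(np.asarray(self.elec, dtype=float))
        self.lj = np.atleast_1d(np.asarray(self.lj, dtype=float))
        if self.elec.shape != self.lj.shape:
            raise ValueError(
                f"elec/lj length mismatch: {self.elec.shape} vs {self.lj.shape}"
            )
        if self.elec.size == 0:
            raise ValueError("energy series must be non-empty")

    @property
    def mean_elec(self) -> float:
        return float(self.elec.mean())

    @property
    def mean_lj(self) -> float:
        return float(self.lj.mean())

    @property
    def mean_total(self) -> float:
        return self.mean_elec + self.mean_lj


def default_free_terms() -> EnergyTerms:
    """Constant free-ligand/water reference series."""
    return EnergyTerms(
        elec=np.array([FREE_LIGAND_WATER_ELEC]),
        lj=np.array([FREE_LIGAND_WATER_LJ]),
        context="ligand_water_free",
    )


@dataclasses.dataclass(frozen=True)
class LIEResult:
    dG: float  # kJ/mol
    alpha: float
    beta: float
    means_used: dict[str, float]  # bound/free ⟨V⟩ values

    def recompute(self) -> float:
        m = self.means_used
        return self.alpha * (m["lj_bound"] - m["lj_free"]) + self.beta * (
            m["elec_bound"] - m["elec_free"]
        )


def lie_free_energy(
    bound: EnergyTerms | Sequence[EnergyTerms],
    free: EnergyTerms | None = None,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> LIEResult:
    """LIE binding free energy from bound and free energy series.

    ``bound`` may be a single ligand–environment series or several
    contexts (e.g. ligand–protein and ligand–water of the bound state)
    whose component means are summed.  ``free`` defaults to the
    free-L-arg-in-water reference constants.
    """
    if isinstance(bound, EnergyTerms):
        bound_list = [bound]
    else:
        bound_list = list(bound)
    if not bound_list:
        raise ValueError("bound must contain at least one energy series")
    free = free if free is not None else default_free_terms()

    lj_bound = sum(t.mean_lj for t in bound_list)
    elec_bound = sum(t.mean_elec for t in bound_list)
    means = {
        "lj_bound": lj_bound,
        "elec_bound": elec_bound,
        "lj_free": free.mean_lj,
        "elec_free": free.mean_elec,
    }
    dg = alpha * (lj_bound - free.mean_lj) + beta * (elec_bound - free.mean_elec)
    return LIEResult(dG=float(dg), alpha=alpha, beta=beta, means_used=means)


def binding_enthalpy(
    ligand_protein_bound: EnergyTerms,
    ligand_water_bound: EnergyTerms,
    ligand_water_free: EnergyTerms | None = None,
) -> float:
    """Nonbonded binding enthalpy, kJ/mol.

    The free-ligand/water interaction energy is subtracted from the sum
    of the bound-state protein–ligand and ligand–water terms; elec and
    LJ components are summed within each term.
    """
    free = (
        ligand_water_free if ligand_water_free is not None else default_free_terms()
    )
    return (
        ligand_protein_bound.mean_total
        + ligand_water_bound.mean_total
        - free.mean_total
    )


def nonbonded_energy(
    frame: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    charges: np.ndarray,
    lj_sigma: np.ndarray,
    lj_epsilon: np.ndarray,
    cutoff: float = 10.0,
) -> tuple[float, float]:
    """Pairwise Coulomb and Lennard-Jones energy between two groups, kJ/mol.

    Charges in e, σ in Å, ε in kJ/mol, cutoff in Å; pairs beyond the
    cutoff contribute nothing.  Lorentz–Berthelot combining rules.  The
    Coulomb prefactor is N_A·e²/(4πε₀) ≈ 138.935458 kJ·mol⁻¹·nm·e⁻²
    (distances converted to nm internally).  Symmetric in group order.
    """
    coords = np.asarray(frame, dtype=float)
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if np.intersect1d(ga, gb).size:
        raise ValueError("groups must be disjoint")
    charges = np.asarray(charges, dtype=float)
    lj_sigma = np.asarray(lj_sigma, dtype=float)
    lj_epsilon = np.asarray(lj_epsilon, dtype=float)

    diff = coords[ga][:, None, :] - coords[gb][None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    mask = (r <= cutoff) & (r > 0)
    if not mask.any():
        return 0.0, 0.0

    qq = np.outer(charges[ga], charges[gb])
    r_nm = r * 0.1
    elec = float((COULOMB_KJ_MOL_NM * qq / np.where(mask, r_nm, 1.0))[mask].sum())

    sigma = 0.5 * (lj_sigma[ga][:, None] + lj_sigma[gb][None, :])
    eps = np.sqrt(np.outer(lj_epsilon[ga], lj_epsilon[gb]))
    sr6 = np.where(mask, (sigma / np.where(mask, r, 1.0)) ** 6, 0.0)
    lj = float((4.0 * eps * (sr6**2 - sr6))[mask].sum())
    return elec, lj


# ---------------------------------------------------------------------------
# Energy series I/O: TSV with time/elec/lj/context columns, or XVG extracts
# ---------------------------------------------------------------------------


def write_energy_tsv(
    terms: Iterable[EnergyTerms], path: str | Path, timestep: float = 1.0
) -> None:
    rows = []
    for t in terms:
        for i, (e, l) in enumerate(zip(t.elec, t.lj)):
            rows.append(
                {"time": i * timestep, "elec": e, "lj": l, "context": t.context}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_energy_tsv(path: str | Path) -> dict[str, EnergyTerms]:
    """Read a (time, elec, lj, context) TSV into per-context series."""
    df = pd.read_csv(path, sep="\t")
    required = {"elec", "lj", "context"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: energy TSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    out = {}
    for context, group in df.groupby("context", sort=False):
        out[str(context)] = EnergyTerms(
            elec=group["elec"].to_numpy(),
            lj=group["lj"].to_numpy(),
            context=str(context),
        )
    return out


def read_xvg(path: str | Path) -> np.ndarray:
    """Read a Grace/GROMACS-style .xvg table, skipping '@'/'#' lines."""
    lines = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith(("@", "#")):
                continue
            lines.append(stripped)
    if not lines:
        raise ValueError(f"{path}: no data rows")
    return np.loadtxt(io.StringIO("\n".join(lines)))
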