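"""Reaction-coordinate assembly across ligation states.

A hexamer binding up to six ligands is described by a series of
:class:`LigationState` records, each carrying the per-state analysis
outputs: quasi-harmonic entropy (± sd over replicas), the three
inter-trimer hydrogen-bond counts, per-ligand enthalpy and LIE free
energy, and an estimated relative free-energy level.  States are
ordered along a conformational coordinate — apo basin, binding-competent
state, the singly-liganded manifold (possibly several sub-states), then
successive ligation up to the fully bound form.

Free-energy levels for intermediate ligation (n = 3, 4, 5) are obtained
by linear interpolation between the n = 2 and n = 6 anchor levels.  The
combination of entropy, bond counts, and per-ligand energetics into a
single level is an estimate by construction: levels are built as
``level(anchor) + Σ per-ligand ΔG increments`` and labelled
"estimated"; entropy and bond-count panels are reported alongside, not
folded in.  A level that the available information cannot pin down is
stored as an interval, never silently imputed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LigationState",
    "interpolate_levels",
    "assemble_coordinate",
    "states_to_json",
    "states_from_json",
    "plot_coordinate",
]


@dataclasses.dataclass
class LigationState:
    n_ligands: int
    label: str
    S: float | None = None  # kJ/(mol·K)
    S_sd: float | None = None
    hbond_counts: tuple[float, float, float] | None = None
    dH_per_ligand: float | None = None  # kJ/mol
    dG_per_ligand: float | None = None  # kJ/mol
    free_energy_level: float | None = None  # kJ/mol, relative
    free_energy_interval: tuple[float, float] | None = None
    level_unconstrained: bool = False
    interpolated: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_ligands <= 6:
            raise ValueError(f"n_ligands must lie in 0..6, got {self.n_ligands}")
        if self.hbond_counts is not None:
            persistent, excl, incl = self.hbond_counts
            if persistent > excl + 1e-9 or persistent > incl + 1e-9:
                raise ValueError(
                    "persistent bond count cannot exceed total counts"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LigationState":
        d = dict(d)
        if d.get("hbond_counts") is not None:
            d["hbond_counts"] = tuple(d["hbond_counts"])
        if d.get("free_energy_interval") is not None:
            d["free_energy_interval"] = tuple(d["free_energy_interval"])
        return cls(**d)


def interpolate_levels(states: Sequence[LigationState]) -> list[LigationState]:
    """Fill n = 3, 4, 5 free-energy levels by linear interpolation in n.

    The anchors are the n = 2 and n = 6 states, both of which must carry
    a level.  Anchors flagged ``level_unconstrained`` propagate the flag
    to the interpolated states.  Existing explicit levels at n = 3..5
    are replaced only when absent.
    """
    by_n: dict[int, LigationState] = {}
    for s in states:
        by_n.setdefault(s.n_ligands, s)
    for anchor in (2, 6):
        if anchor not in by_n or by_n[anchor].free_energy_level is None:
            raise ValueError(
                f"interpolation requires a free-energy level for the "
                f"n={anchor} anchor state"
            )
    lo, hi = by_n[2], by_n[6]
    unconstrained = lo.level_unconstrained or hi.level_unconstrained

    out = list(states)
    for n in (3, 4, 5):
        frac = (n - 2) / 4.0
        level = (1 - frac) * lo.free_energy_level + frac * hi.free_energy_level
        existing = by_n.get(n)
        if existing is not None and existing.free_energy_level is None:
            existing.free_energy_level = level
            existing.level_unconstrained = unconstrained
            existing.interpolated = True
        elif existing is None:
            out.append(
                LigationState(
                    n_ligands=n,
                    label=f"+{n}arg (interpolated)",
                    free_energy_level=level,
                    level_unconstrained=unconstrained,
                    interpolated=True,
                )
            )
    return sorted(out, key=lambda s: (s.n_ligands, s.label))


_PHASE_ORDER = {"apo": 0, "apo_rotated": 0, "binding_competent": 1}


def assemble_coordinate(
    states: Sequence[LigationState], interpolate: bool = True
) -> tuple[list[LigationState], dict]:
    """Order states along the reaction coordinate and build the report.

    The ordering is: apo basin (including the rotated conformer),
    binding-competent state, then ligation states by increasing ligand
    count; several sub-states at the same count (the +1 manifold) each
    keep their own coordinate.  Missing quantities are serialized as
    null, never imputed.  The report is deterministic for fixed inputs.
    """
    ordered = sorted(
        states,
        key=lambda s: (
            s.n_ligands,
            _PHASE_ORDER.get(s.label, 2),
            s.label,
        ),
    )
    if interpolate and any(s.n_ligands >= 2 for s in ordered):
        have = {s.n_ligands for s in ordered if s.free_energy_level is not None}
        if {2, 6} <= have:
            ordered = interpolate_levels(ordered)

    report = {
        "coordinate": [s.label for s in ordered],
        "panels": {
            "entropy": [
                {"label": s.label, "S": s.S, "sd": s.S_sd} for s in ordered
            ],
            "hbond_counts": [
                {
                    "label": s.label,
                    "persistent": None if s.hbond_counts is None else s.hbond_counts[0],
                    "total_excl_ligand": (
                        None if s.hbond_counts is None else s.hbond_counts[1]
                    ),
                    "total_incl_ligand": (
                        None if s.hbond_counts is None else s.hbond_counts[2]
                    ),
                }
                for s in ordered
            ],
            "free_energy": [
                {
                    "label": s.label,
                    "level": s.free_energy_level,
                    "interval": s.free_energy_interval,
                    "unconstrained": s.level_unconstrained,
                    "interpolated": s.interpolated,
                }
                for s in ordered
            ],
        },
    }
    return ordered, report


def states_to_json(states: Sequence[LigationState], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in states], fh, indent=2, sort_keys=True)
        fh.write("\n")


def states_from_json(path: str | Path) -> list[LigationState]:
    with open(path) as fh:
        return [LigationState.from_dict(d) for d in json.load(fh)]


def plot_coordinate(report: dict, path: str | Path) -> None:
    """Render the three-panel reaction-coordinate figure (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = report["coordinate"]
    x = np.arange(len(labels))
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)

    entropy = report["panels"]["entropy"]
    s_vals = [e["S"] for e in entropy]
    s_sd = [e["sd"] or 0.0 for e in entropy]
    mask = [i for i, v in enumerate(s_vals) if v is not None]
    axes[0].errorbar(
        x[mask], [s_vals[i] for i in mask], yerr=[s_sd[i] for i in mask],
        fmt="o-", color="black",
    )
    axes[0].set_ylabel("S  [kJ/(mol·K)]")

    hb = report["panels"]["hbond_counts"]
    for key, color in (
        ("persistent", "lightblue"),
        ("total_excl_ligand", "darkblue"),
        ("total_incl_ligand", "green"),
    ):
        vals = [h[key] for h in hb]
        mask = [i for i, v in enumerate(vals) if v is not None]
        axes[1].plot(x[mask], [vals[i] for i in mask], "o-", color=color, label=key)
    axes[1].set_ylabel("inter-trimer H-bonds")
    axes[1].legend(fontsize=8)

    fe = report["panels"]["free_energy"]
    for i, f in enumerate(fe):
        if f["level"] is not None:
            style = "--" if f["unconstrained"] or f["interpolated"] else "-"
            axes[2].hlines(f["level"], i - 0.3, i + 0.3, linestyles=style)
        elif f["interval"] is not None:
            lo, hi = f["interval"]
            axes[2].vlines(i, lo, hi, linestyles=":")
    axes[2].set_ylabel("relative ΔG  [kJ/mol]")
    axes[2].set_xticks(x)
    axes[2].set_xticklabels(labels, rotation=45, ha="right", fontsize=8)

    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
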