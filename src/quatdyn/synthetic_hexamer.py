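"""Ground-truth generator of oscillating-hexamer trajectories.

The generator builds a pseudo-atomic two-trimer hexamer — chains A–C
stacked below chains D–F on a common 3-fold (z) axis — and animates it
with a prescribed inter-trimer rotation process plus per-atom Gaussian
jitter, so that every analysis stage of the package can be tested
against known analytic values without running MD:

* the top (DEF) trimer rotates about z by θ(t) drawn from a sinusoid,
  an exactly-discretized Ornstein–Uhlenbeck process, or a two-state
  switch (dominant rotated conformer vs rare unrotated one).  Positive
  θ is clockwise viewed down the axis from the DEF side, matching the
  package's rotation sign convention;
* per-atom isotropic jitter with a core→surface motion gradient
  (standard deviation interpolated linearly in the atom's distance from
  its monomer center);
* six "pocket" marker pairs — Cα atoms of residues 103 (Gly) and 128
  (Asp) across the interface — whose distance responds geometrically to
  θ: exactly ``pocket_rest_distance`` at θ = 0 and
  ``pocket_rest_distance + pocket_opening`` at the nominal rotation;
* six gated inter-trimer hydrogen-bond pairs (Arg110 NH1 donors to
  Asp128 OD1 acceptors) whose donor–acceptor distance crosses the
  detection cutoff exactly at ``gate_angle``, so a bond is present iff
  θ < gate_angle.  The N–O distance stays inside the salt-bridge cutoff
  throughout the oscillation range, so the electrostatic contact
  survives even when hydrogen-bond geometry is broken;
* constant intra-monomer and intra-trimer donor/acceptor pairs for
  span-classification tests;
* optional bound ligands (free arginine residues, chain L) contributing
  one hydrogen bond each; with the ligand brake enabled, each bound
  ligand multiplies the rotation mean and amplitude by ``brake_factor``
  (≈ 0 already at one ligand), emulating arrest of oscillation upon
  first binding;
* Gaussian ligand–environment energy series for the LIE machinery.

Pseudo-monomers are rigid bodies plus independent jitter — no internal
normal modes.  Every random draw is fixed by ``seed``; different seeds
change the noise but never the topology.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable

import numpy as np

from .constants import R_GAS, schlitter_scale
from .lie_energetics import (
    FREE_LIGAND_WATER_ELEC,
    FREE_LIGAND_WATER_LJ,
    EnergyTerms,
    write_energy_tsv,
)
from .qh_entropy import rigid_body_modes
from .structure_model import (
    Atom,
    StructureModel,
    Trajectory,
    element_mass,
    partition_trimers,
    write_trajectory,
)

__all__ = ["GeneratorSpec", "GroundTruth", "generate", "generate_energy_series", "write_fixture"]

_DEFAULT_ENERGY_MEANS = {
    # (elec, lj) kJ/mol; bound contexts sum to (−473.458, −14.63) so the
    # default LIE free energy is 0.18·(−10) + 0.50·(−20) = −11.8 kJ/mol
    "ligand_protein_bound": (-320.0, -9.0),
    "ligand_water_bound": (-153.458, -5.63),
    "ligand_water_free": (FREE_LIGAND_WATER_ELEC, FREE_LIGAND_WATER_LJ),
}
_DEFAULT_ENERGY_SIGMAS = {
    "ligand_protein_bound": (5.0, 1.0),
    "ligand_water_bound": (5.0, 1.0),
    "ligand_water_free": (5.0, 1.0),
}

_PROCESSES = ("sinusoid", "ou_process", "two_state")


@dataclasses.dataclass
class GeneratorSpec:
    """Study conditions for one synthetic trajectory.

    Defaults emulate the apo hexamer's observed behaviour: a ~13° mean
    inter-trimer rotation oscillating with a few degrees amplitude and a
    ~250 ps cycle, monomer centers ~18 Å from the 3-fold axis, pocket
    distances resting at the ligand-bound crystal value 9.8 Å and
    opening by ~1.6 Å at the rotated mean, and fluctuation magnitudes
    bracketing the 0.3–1.5 Å RMSF range typical of a compact domain.
    """

    n_atoms_per_monomer: int = 50
    ring_radius: float = 18.0  # Å, monomer COM distance from the 3-fold axis
    trimer_separation: float = 18.0  # Å between trimer planes along z
    rotation_mean: float = 13.0  # deg
    rotation_amplitude: float = 3.0  # deg
    rotation_period: float = 250.0  # ps
    rotation_process: str = "sinusoid"
    two_state_occupancy: float = 0.9  # dominant (rotated) conformer weight
    jitter_sigma_core: float = 0.17  # Å per coordinate
    jitter_sigma_surface: float = 0.6
    pocket_rest_distance: float = 9.8  # Å at θ = 0
    pocket_opening: float = 1.6  # extra Å at the nominal rotation
    pocket_twist_deg: float = 20.0  # azimuthal stagger of pocket pairs
    gate_angle: float = 13.0  # deg; H-bond present iff θ < gate
    hbond_rest_distance: float = 2.9  # Å at θ = 0
    hbond_cut_distance: float = 3.5  # Å at θ = gate (detection cutoff)
    hbond_twist_deg: float = 10.0
    ligand_count: int = 0
    ligand_brake: bool = True
    brake_factor: float = 0.05
    energy_means: dict | None = None
    energy_sigmas: dict | None = None
    n_frames: int = 2000
    timestep: float = 1.0  # ps
    seed: int = 0

    def validate(self) -> None:
        if self.n_atoms_per_monomer < 49:
            raise ValueError(
                "n_atoms_per_monomer: need at least 49 residues (80–128) "
                "to place the pocket markers"
            )
        for field in ("ring_radius", "trimer_separation", "rotation_period",
                      "timestep", "pocket_rest_distance", "hbond_rest_distance"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field}: must be positive")
        for field in ("rotation_amplitude", "jitter_sigma_core",
                      "jitter_sigma_surface", "pocket_opening"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field}: must be non-negative")
        if self.rotation_process not in _PROCESSES:
            raise ValueError(
                f"rotation_process: must be one of {_PROCESSES}, "
                f"got {self.rotation_process!r}"
            )
        if not 0 <= self.ligand_count <= 6:
            raise ValueError("ligand_count: must lie in 0..6")
        if not 0.0 <= self.two_state_occupancy <= 1.0:
            raise ValueError("two_state_occupancy: must lie in [0, 1]")
        if self.hbond_cut_distance <= self.hbond_rest_distance:
            raise ValueError(
                "hbond_cut_distance: must exceed hbond_rest_distance"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames: must be at least 1")

    # -- effective (post-brake) rotation parameters --------------------

    @property
    def brake_scale(self) -> float:
        if self.ligand_brake and self.ligand_count > 0:
            return self.brake_factor**self.ligand_count
        return 1.0

    @property
    def effective_rotation_mean(self) -> float:
        return self.rotation_mean * self.brake_scale

    @property
    def effective_rotation_amplitude(self) -> float:
        return self.rotation_amplitude * self.brake_scale


@dataclasses.dataclass
class GroundTruth:
    """Analytic values the generator guarantees about its own output."""

    theta: np.ndarray  # deg, per frame (jitter-free rotation angle)
    rotation_mean: float
    rotation_amplitude: float
    rotation_period: float
    rotation_process: str
    gate_angle: float
    bond_open_fraction: float  # empirical fraction of frames with θ < gate
    bond_open_fraction_analytic: float | None
    pocket_rest_distance: float
    pocket_open_distance: float
    pocket_distance_of_theta: Callable[[np.ndarray], np.ndarray]
    delta_delta_mean: float  # mean d(θ) − rest over the realized θ series
    monomer_com_distance: float
    jitter_sigma: np.ndarray  # per-atom, Å per coordinate
    masses: np.ndarray
    base_coordinates: np.ndarray
    energy_means: dict
    energy_sigmas: dict
    two_state_occupancy: float | None = None

    def expected_schlitter(
        self,
        selection: np.ndarray | None = None,
        temperature: float = 300.0,
        remove_rigid_body: bool = True,
    ) -> float:
        """Schlitter entropy (kJ/(mol·K)) of the jitter alone.

        The jitter covariance is diagonal, m_a·σ_a² per coordinate.
        With ``remove_rigid_body`` the six rigid-body directions of the
        base geometry are projected out first, mirroring what the
        per-frame alignment of the analysis pipeline removes.
        """
        sel = (
            np.arange(self.masses.size)
            if selection is None
            else np.asarray(selection, dtype=int)
        )
        variances = np.repeat(self.masses[sel] * self.jitter_sigma[sel] ** 2, 3)
        scale = schlitter_scale(temperature)
        if not remove_rigid_body:
            return 0.5 * R_GAS * np.log1p(scale * variances).sum() / 1000.0
        sigma = np.diag(variances)
        modes = rigid_body_modes(self.base_coordinates[sel], self.masses[sel])
        projector = np.eye(sigma.shape[0]) - modes @ modes.T
        evals = np.linalg.eigvalsh(projector @ sigma @ projector)
        return 0.5 * R_GAS * np.log1p(scale * np.clip(evals, 0, None)).sum() / 1000.0


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------


def _cyl(radius: float, azimuth_deg: float, z: float) -> np.ndarray:
    a = math.radians(azimuth_deg)
    return np.array([radius * math.cos(a), radius * math.sin(a), z])


def _solve_pair_geometry(
    d_rest: float, d_far: float, twist_deg: float, angle_deg: float
) -> tuple[float, float]:
    """Radius and axial gap placing a marker pair at ``d_rest`` for θ=0
    and ``d_far`` for θ=angle, when their separation follows
    d(θ)² = 2r²(1 − cos(twist + θ)) + dz²."""
    psi = math.radians(twist_deg)
    th = math.radians(angle_deg)
    denom = 2.0 * (math.cos(psi) - math.cos(psi + th))
    if denom <= 0:
        raise ValueError("pocket/h-bond geometry unsolvable: twist too large")
    r_sq = (d_far**2 - d_rest**2) / denom
    dz_sq = d_rest**2 - 2.0 * r_sq * (1.0 - math.cos(psi))
    if r_sq <= 0 or dz_sq <= 0:
        raise ValueError(
            "pocket/h-bond geometry unsolvable for the requested distances"
        )
    return math.sqrt(r_sq), math.sqrt(dz_sq)


def _build_base(spec: GeneratorSpec):
    """Base (θ = 0) structure: atoms, coordinates, jitter sigmas, metadata."""
    n_res = spec.n_atoms_per_monomer
    ref_angle = spec.rotation_mean if abs(spec.rotation_mean) > 1e-9 else 13.0
    r_p, dz_p = _solve_pair_geometry(
        spec.pocket_rest_distance,
        spec.pocket_rest_distance + spec.pocket_opening,
        spec.pocket_twist_deg,
        ref_angle,
    )
    r_h, dz_h = _solve_pair_geometry(
        spec.hbond_rest_distance,
        spec.hbond_cut_distance,
        spec.hbond_twist_deg,
        spec.gate_angle,
    )
    psi = spec.pocket_twist_deg
    psi_h = spec.hbond_twist_deg
    z_half = spec.trimer_separation / 2.0
    r_t = 2.8 / (2.0 * math.sin(math.radians(5.0)))  # constant 2.8 Å pair

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    def add(name, element, resname, resnum, chain, xyz, *, ligand=False, het=False):
        atoms.append(
            Atom(
                index=len(atoms),
                name=name,
                element=element,
                mass=element_mass(element),
                residue_name=resname,
                residue_number=resnum,
                chain_id=chain,
                is_ligand=ligand,
                is_hetero=het,
            )
        )
        coords.append(np.asarray(xyz, dtype=float))

    special_res = {103: "GLY", 110: "ARG", 128: "ASP"}
    marker_resnums = {103, 128}

    for trimer, chains, z_sign, az_off in (
        ("ABC", "ABC", -1.0, 0.0),
        ("DEF", "DEF", +1.0, 60.0),
    ):
        zc = z_sign * z_half
        zm = z_sign * dz_p / 2.0
        zh = z_sign * dz_h / 2.0
        for k, chain in enumerate(chains):
            base_az = az_off + 120.0 * k
            body_slots: list[int] = []
            for i in range(n_res):
                resnum = 80 + i
                resname = special_res.get(resnum, "ALA")
                t = i / max(n_res - 1, 1)
                if resnum == 103:
                    xyz = _cyl(r_p, base_az, zm)  # Gly pocket marker
                elif resnum == 128:
                    shift = 80.0 if trimer == "ABC" else -80.0
                    xyz = _cyl(r_p, base_az + shift, zm)  # Asp pocket marker
                else:
                    local = np.array(
                        [
                            (3.0 + 4.0 * t) * math.cos(2.399963 * i),
                            (3.0 + 4.0 * t) * math.sin(2.399963 * i),
                            -5.0 + 10.0 * t,
                        ]
                    )
                    xyz = _cyl(spec.ring_radius, base_az, zc) + local
                    body_slots.append(len(atoms))
                add("CA", "C", resname, resnum, chain, xyz)
                if resnum == 105:
                    add("N", "N", resname, resnum, chain,
                        _cyl(spec.ring_radius, base_az + 25.0, zc))
                if resnum == 106:
                    add("O", "O", resname, resnum, chain,
                        _cyl(spec.ring_radius + 2.9, base_az + 25.0, zc))
                if resnum == 110:
                    add("NH1", "N", "ARG", resnum, chain,
                        _cyl(r_h, base_az + 30.0, zh))
                if resnum == 121:
                    add("N", "N", resname, resnum, chain,
                        _cyl(r_t, base_az + 115.0, zc))
                if resnum == 122:
                    add("O", "O", resname, resnum, chain,
                        _cyl(r_t, base_az + 5.0, zc))
                if resnum == 128:
                    shift = 100.0 if trimer == "ABC" else -40.0
                    add("OD1", "O", "ASP", resnum, chain,
                        _cyl(r_h, base_az + shift, zh))

            # shift the generic body atoms so the monomer COM lands exactly
            # at (ring_radius, base_az, zc)
            target = _cyl(spec.ring_radius, base_az, zc)
            chain_idx = [a.index for a in atoms if a.chain_id == chain]
            masses = np.array([atoms[i].mass for i in chain_idx])
            pts = np.array([coords[i] for i in chain_idx])
            com = (masses[:, None] * pts).sum(axis=0) / masses.sum()
            body_mass = sum(atoms[i].mass for i in body_slots)
            shift_vec = (target - com) * (masses.sum() / body_mass)
            for i in body_slots:
                coords[i] = coords[i] + shift_vec

    # ligands: one per occupied pocket, bonded to the static (ABC) side
    for lig in range(spec.ligand_count):
        resnum = 200 + lig
        if lig < 3:
            anchor_az = 30.0 + 120.0 * lig  # ABC NH1 donor pocket
            anchor = _cyl(r_h, anchor_az, -dz_h / 2.0)
        else:
            anchor_az = 100.0 + 120.0 * (lig - 3)  # ABC OD1 acceptor pocket
            anchor = _cyl(r_h, anchor_az, -dz_h / 2.0)
        e_r = _cyl(1.0, anchor_az, 0.0)
        first = ("O", "O") if lig < 3 else ("N", "N")
        add(first[0], first[1], "ARG", resnum, "L", anchor + 2.9 * e_r,
            ligand=True, het=True)
        add("CA", "C", "ARG", resnum, "L", anchor + 4.4 * e_r,
            ligand=True, het=True)
        second = ("N", "N") if lig < 3 else ("O", "O")
        add(second[0], second[1], "ARG", resnum, "L", anchor + 5.9 * e_r,
            ligand=True, het=True)

    base = np.array(coords)

    # motion gradient: jitter sigma linear in distance from the monomer COM
    sigma = np.empty(len(atoms))
    for chain in "ABCDEF":
        idx = [a.index for a in atoms if a.chain_id == chain]
        masses = np.array([atoms[i].mass for i in idx])
        pts = base[idx]
        com = (masses[:, None] * pts).sum(axis=0) / masses.sum()
        rho = np.linalg.norm(pts - com, axis=1)
        rho_max = rho.max() if rho.max() > 0 else 1.0
        sigma[idx] = spec.jitter_sigma_core + (
            spec.jitter_sigma_surface - spec.jitter_sigma_core
        ) * (rho / rho_max)
    lig_idx = [a.index for a in atoms if a.is_ligand]
    sigma[lig_idx] = spec.jitter_sigma_core

    pocket_geometry = (r_p, dz_p, psi)
    return atoms, base, sigma, pocket_geometry


def _theta_series(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    mean = spec.effective_rotation_mean
    amp = spec.effective_rotation_amplitude
    t = spec.timestep * np.arange(spec.n_frames)
    if spec.rotation_process == "sinusoid":
        return mean + amp * np.sin(2.0 * np.pi * t / spec.rotation_period)
    if spec.rotation_process == "ou_process":
        # exact discretization: decay + matched Gaussian innovation, so the
        # stationary sd is exactly `amp` and the autocorrelation time is the
        # rotation period
        tau = spec.rotation_period
        decay = math.exp(-spec.timestep / tau)
        innov = amp * math.sqrt(1.0 - decay**2)
        x = np.empty(spec.n_frames)
        x[0] = amp * rng.standard_normal()
        noise = rng.standard_normal(spec.n_frames)
        for i in range(1, spec.n_frames):
            x[i] = x[i - 1] * decay + innov * noise[i]
        return mean + x
    # two_state: dominant rotated conformer vs rare unrotated (crystal-like)
    dominant = rng.random(spec.n_frames) < spec.two_state_occupancy
    return np.where(dominant, mean, 0.0)


def _rotation_z(theta_deg: float) -> np.ndarray:
    a = math.radians(theta_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _open_fraction_analytic(spec: GeneratorSpec) -> float | None:
    from scipy.stats import norm

    mean = spec.effective_rotation_mean
    amp = spec.effective_rotation_amplitude
    gate = spec.gate_angle
    if spec.rotation_process == "sinusoid":
        if amp <= 0:
            return 1.0 if mean < gate else 0.0
        c = (gate - mean) / amp
        if c <= -1:
            return 0.0
        if c >= 1:
            return 1.0
        return 0.5 + math.asin(c) / math.pi
    if spec.rotation_process == "ou_process":
        if amp <= 0:
            return 1.0 if mean < gate else 0.0
        return float(norm.cdf((gate - mean) / amp))
    p = spec.two_state_occupancy
    return p * (1.0 if mean < gate else 0.0) + (1 - p) * (1.0 if 0.0 < gate else 0.0)


def generate(spec: GeneratorSpec) -> tuple[StructureModel, Trajectory, GroundTruth]:
    """Build the hexamer model, its trajectory, and the analytic ground truth.

    The model's own coordinate set is the unrotated (θ = 0, jitter-free)
    base structure — the "crystal" reference — while the trajectory
    oscillates about the rotated mean, so initial-structure referencing
    against the model exposes the full quaternary shift.
    """
    spec.validate()
    atoms, base, sigma, (r_p, dz_p, psi) = _build_base(spec)
    rng = np.random.default_rng([spec.seed % (2**31), 11])

    theta = _theta_series(spec, rng)
    def_mask = np.array([a.chain_id in "DEF" and not a.is_ligand for a in atoms])

    frames = np.empty((spec.n_frames, len(atoms), 3))
    for i, th in enumerate(theta):
        frame = base.copy()
        # positive θ = clockwise viewed from the DEF (top, +z) side
        frame[def_mask] = base[def_mask] @ _rotation_z(-th).T
        frames[i] = frame
    frames += rng.standard_normal(frames.shape) * sigma[None, :, None]

    model = StructureModel(atoms, base)
    model = partition_trimers(model, top_chains=set("DEF"))
    traj = Trajectory(model, frames, timestep=spec.timestep)

    def pocket_distance(theta_deg):
        th = np.radians(np.asarray(theta_deg, dtype=float))
        return np.sqrt(
            2.0 * r_p**2 * (1.0 - np.cos(math.radians(psi) + th)) + dz_p**2
        )

    d_theta = pocket_distance(theta)
    truth = GroundTruth(
        theta=theta,
        rotation_mean=spec.effective_rotation_mean,
        rotation_amplitude=spec.effective_rotation_amplitude,
        rotation_period=spec.rotation_period,
        rotation_process=spec.rotation_process,
        gate_angle=spec.gate_angle,
        bond_open_fraction=float((theta < spec.gate_angle).mean()),
        bond_open_fraction_analytic=_open_fraction_analytic(spec),
        pocket_rest_distance=spec.pocket_rest_distance,
        pocket_open_distance=float(
            pocket_distance(spec.rotation_mean if abs(spec.rotation_mean) > 1e-9 else 13.0)
        ),
        pocket_distance_of_theta=pocket_distance,
        delta_delta_mean=float(d_theta.mean() - spec.pocket_rest_distance),
        monomer_com_distance=math.hypot(
            spec.ring_radius, spec.trimer_separation / 2.0
        ),
        jitter_sigma=sigma,
        masses=model.masses,
        base_coordinates=base,
        energy_means=dict(spec.energy_means or _DEFAULT_ENERGY_MEANS),
        energy_sigmas=dict(spec.energy_sigmas or _DEFAULT_ENERGY_SIGMAS),
        two_state_occupancy=(
            spec.two_state_occupancy if spec.rotation_process == "two_state" else None
        ),
    )
    return model, traj, truth


def generate_energy_series(spec: GeneratorSpec) -> dict[str, EnergyTerms]:
    """Seeded Gaussian ligand–environment energy series per context."""
    spec.validate()
    means = dict(spec.energy_means or _DEFAULT_ENERGY_MEANS)
    sigmas = dict(spec.energy_sigmas or _DEFAULT_ENERGY_SIGMAS)
    rng = np.random.default_rng([spec.seed % (2**31), 7])
    out: dict[str, EnergyTerms] = {}
    for context, (mean_elec, mean_lj) in means.items():
        sd_elec, sd_lj = sigmas.get(context, (0.0, 0.0))
        out[context] = EnergyTerms(
            elec=mean_elec + sd_elec * rng.standard_normal(spec.n_frames),
            lj=mean_lj + sd_lj * rng.standard_normal(spec.n_frames),
            context=context,
        )
    return out


def write_fixture(spec: GeneratorSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write trajectory + energies + ground-truth summary; seed-deterministic."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, traj, truth = generate(spec)
    energies = generate_energy_series(spec)

    traj_path = out_dir / "trajectory.pdb"
    write_trajectory(traj, traj_path)
    energy_path = out_dir / "energies.tsv"
    write_energy_tsv(energies.values(), energy_path, timestep=spec.timestep)

    truth_path = out_dir / "ground_truth.json"
    summary = {
        "rotation_mean": truth.rotation_mean,
        "rotation_amplitude": truth.rotation_amplitude,
        "rotation_period": truth.rotation_period,
        "rotation_process": truth.rotation_process,
        "gate_angle": truth.gate_angle,
        "bond_open_fraction": truth.bond_open_fraction,
        "pocket_rest_distance": truth.pocket_rest_distance,
        "pocket_open_distance": truth.pocket_open_distance,
        "delta_delta_mean": truth.delta_delta_mean,
        "monomer_com_distance": truth.monomer_com_distance,
        "energy_means": truth.energy_means,
        "energy_sigmas": truth.energy_sigmas,
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "timestep": spec.timestep,
    }
    with open(truth_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"trajectory": traj_path, "energies": energy_path, "ground_truth": truth_path}
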