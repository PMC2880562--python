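"""Geometric hydrogen-bond and salt-bridge detection with persistence.

Detection is donor/acceptor based so that heavy-atom-only models (the
common case for coarse trajectories and for crystal structures without
hydrogens) are fully supported:

* donors: nitrogen atoms; acceptors: oxygen and nitrogen atoms;
* a pair is bonded when the donor–acceptor heavy-atom distance is at
  most ``d_max`` (default 3.5 Å) and, when hydrogens are present on the
  donor, some D–H···A angle deviates from linearity by at most 30°;
  without hydrogens a donor-antecedent angle ≥ 90° is required when an
  antecedent heavy atom can be identified (distance-only otherwise);
* salt bridges pair basic sidechain nitrogens (Arg NE/NH1/NH2, Lys NZ,
  His ND1/NE2) with acidic sidechain oxygens (Asp OD1/OD2, Glu OE1/OE2)
  at N–O ≤ 4.0 Å; contacts inside that cutoff are listed even when they
  fail hydrogen-bond geometry (electrostatic interaction preserved).

Persistence of a pair over a frame window is the fraction of frames in
which it is bonded; "persistent" means strictly more than half the
frames.  Occupancy is evaluated per stored frame with no time smoothing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import PartitionError, QuatdynError
from .structure_model import StructureModel, Trajectory

__all__ = [
    "HBondCriteria",
    "ContactPair",
    "HBondTable",
    "InterTrimerCounts",
    "detect_hbonds",
    "salt_bridges",
    "occupancy_table",
    "count_inter_trimer",
    "PERSISTENCE_THRESHOLD",
]

#: A bond is "persistent" when present in strictly more than this fraction
#: of frames.
PERSISTENCE_THRESHOLD = 0.5

_BASIC_GROUPS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_GROUPS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclasses.dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5  # donor–acceptor heavy-atom distance cutoff, Å
    dha_max_deviation: float = 30.0  # deg from linear, when hydrogens exist
    antecedent_angle_min: float = 90.0  # deg, heavy-atom fallback
    hydrogen_bond_length: float = 1.2  # Å, donor–H covalent search radius
    antecedent_length: float = 1.8  # Å, donor-antecedent covalent search radius


@dataclasses.dataclass(frozen=True)
class ContactPair:
    donor_atom: int
    acceptor_atom: int
    donor_residue: tuple[str, int, str]
    acceptor_residue: tuple[str, int, str]
    span_class: str  # intra_monomer | intra_trimer | inter_trimer | ligand
    salt_bridge: bool
    distance: float = float("nan")

    @property
    def key(self) -> tuple[int, int]:
        return (self.donor_atom, self.acceptor_atom)


@dataclasses.dataclass
class HBondTable:
    pairs: list[ContactPair]
    occupancy: np.ndarray  # (n_pairs, n_frames) booleans
    persistence: np.ndarray  # per-pair fraction in [0, 1]
    window: tuple[int, int]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pair, pers in zip(self.pairs, self.persistence):
            rows.append(
                {
                    "donor_atom": pair.donor_atom,
                    "acceptor_atom": pair.acceptor_atom,
                    "donor_residue": "{}:{}{}".format(*pair.donor_residue),
                    "acceptor_residue": "{}:{}{}".format(*pair.acceptor_residue),
                    "span_class": pair.span_class,
                    "salt_bridge": pair.salt_bridge,
                    "persistence": pers,
                    "persistent": pers > PERSISTENCE_THRESHOLD,
                }
            )
        return pd.DataFrame(rows)


def _span_class(model: StructureModel, i: int, j: int) -> str:
    a, b = model.atoms[i], model.atoms[j]
    if a.is_ligand or b.is_ligand:
        return "ligand"
    if a.chain_id == b.chain_id:
        return "intra_monomer"
    if not model.trimer_partition:
        raise PartitionError(
            "cross-chain contact classification requires a trimer partition"
        )
    if model.trimer_group(a.chain_id) == model.trimer_group(b.chain_id):
        return "intra_trimer"
    return "inter_trimer"


def _is_salt_bridge_pair(model: StructureModel, donor: int, acceptor: int) -> bool:
    d, a = model.atoms[donor], model.atoms[acceptor]
    basic = _BASIC_GROUPS.get(d.residue_name.upper(), set())
    acidic = _ACIDIC_GROUPS.get(a.residue_name.upper(), set())
    return d.name.upper() in basic and a.name.upper() in acidic


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 180.0
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _donor_geometry_ok(
    coords: np.ndarray,
    model: StructureModel,
    donor: int,
    acceptor: int,
    criteria: HBondCriteria,
) -> bool:
    datom = model.atoms[donor]
    same_res = [
        a.index
        for a in model.atoms
        if a.residue_id == datom.residue_id and a.index != donor
    ]
    # explicit hydrogens on the donor take precedence
    hydrogens = [
        i
        for i in same_res
        if not model.atoms[i].is_heavy
        and np.linalg.norm(coords[i] - coords[donor]) <= criteria.hydrogen_bond_length
    ]
    if hydrogens:
        best = max(
            _angle_deg(coords[donor], coords[h], coords[acceptor]) for h in hydrogens
        )
        return best >= 180.0 - criteria.dha_max_deviation
    antecedents = [
        i
        for i in same_res
        if model.atoms[i].is_heavy
        and np.linalg.norm(coords[i] - coords[donor]) <= criteria.antecedent_length
    ]
    if antecedents:
        nearest = min(
            antecedents, key=lambda i: np.linalg.norm(coords[i] - coords[donor])
        )
        angle = _angle_deg(coords[nearest], coords[donor], coords[acceptor])
        return angle >= criteria.antecedent_angle_min
    return True  # isolated donor: distance criterion only


def _donors_acceptors(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    donors = [a.index for a in model.atoms if a.element.upper() == "N"]
    acceptors = [a.index for a in model.atoms if a.element.upper() in ("O", "N")]
    if not donors or not acceptors:
        return np.array(donors, dtype=int), np.array(acceptors, dtype=int)
    for idx in donors + acceptors:
        if not model.atoms[idx].element:
            raise QuatdynError("model lacks element information")
    return np.array(donors, dtype=int), np.array(acceptors, dtype=int)


def detect_hbonds(
    frame: np.ndarray,
    model: StructureModel,
    criteria: HBondCriteria | None = None,
) -> list[ContactPair]:
    """Hydrogen bonds present in one coordinate frame."""
    criteria = criteria or HBondCriteria()
    coords = np.asarray(frame, dtype=float)
    donors, acceptors = _donors_acceptors(model)
    if donors.size == 0 or acceptors.size == 0:
        return []
    tree = cKDTree(coords[acceptors])
    pairs: list[ContactPair] = []
    for donor in donors:
        for k in tree.query_ball_point(coords[donor], criteria.d_max):
            acceptor = int(acceptors[k])
            if acceptor == donor:
                continue
            if model.atoms[donor].residue_id == model.atoms[acceptor].residue_id:
                continue
            if not _donor_geometry_ok(coords, model, donor, acceptor, criteria):
                continue
            dist = float(np.linalg.norm(coords[donor] - coords[acceptor]))
            pairs.append(
                ContactPair(
                    donor_atom=int(donor),
                    acceptor_atom=acceptor,
                    donor_residue=model.atoms[donor].residue_id,
                    acceptor_residue=model.atoms[acceptor].residue_id,
                    span_class=_span_class(model, int(donor), acceptor),
                    salt_bridge=_is_salt_bridge_pair(model, int(donor), acceptor),
                    distance=dist,
                )
            )
    return pairs


def salt_bridges(
    frame: np.ndarray,
    model: StructureModel,
    d_max: float = 4.0,
) -> list[ContactPair]:
    """Basic–acidic sidechain N–O contacts within ``d_max`` Å.

    Contacts are reported whether or not they satisfy hydrogen-bond
    geometry: an Arg–Asp pair inside the cutoff but with broken
    hydrogen-bond geometry still preserves its electrostatic interaction
    and is listed (salt_bridge flag set).
    """
    coords = np.asarray(frame, dtype=float)
    basics = [
        a.index
        for a in model.atoms
        if a.name.upper() in _BASIC_GROUPS.get(a.residue_name.upper(), set())
    ]
    acidics = [
        a.index
        for a in model.atoms
        if a.name.upper() in _ACIDIC_GROUPS.get(a.residue_name.upper(), set())
    ]
    out: list[ContactPair] = []
    for b in basics:
        for a in acidics:
            if model.atoms[b].residue_id == model.atoms[a].residue_id:
                continue
            dist = float(np.linalg.norm(coords[b] - coords[a]))
            if dist <= d_max:
                out.append(
                    ContactPair(
                        donor_atom=b,
                        acceptor_atom=a,
                        donor_residue=model.atoms[b].residue_id,
                        acceptor_residue=model.atoms[a].residue_id,
                        span_class=_span_class(model, b, a),
                        salt_bridge=True,
                        distance=dist,
                    )
                )
    return out


def occupancy_table(
    traj: Trajectory,
    criteria: HBondCriteria | None = None,
    window: tuple[int, int | None] = (0, None),
) -> HBondTable:
    """Union of hydrogen bonds over a frame window with per-frame occupancy.

    Pairs detected in any frame form the rows; persistence is the column
    mean of the occupancy matrix (exactly).
    """
    start, stop = window
    frames = traj.frames[start:stop]
    n_frames = frames.shape[0]
    if n_frames < 1:
        raise ValueError(f"window [{start}, {stop}) selects no frames")
    criteria = criteria or HBondCriteria()

    pair_index: dict[tuple[int, int], int] = {}
    pairs: list[ContactPair] = []
    per_frame: list[set[tuple[int, int]]] = []
    for frame in frames:
        present: set[tuple[int, int]] = set()
        for pair in detect_hbonds(frame, traj.model, criteria):
            if pair.key not in pair_index:
                pair_index[pair.key] = len(pairs)
                pairs.append(pair)
            present.add(pair.key)
        per_frame.append(present)

    occupancy = np.zeros((len(pairs), n_frames), dtype=bool)
    for f, present in enumerate(per_frame):
        for key in present:
            occupancy[pair_index[key], f] = True
    persistence = (
        occupancy.mean(axis=1) if pairs else np.zeros(0)
    )
    return HBondTable(
        pairs=pairs,
        occupancy=occupancy,
        persistence=persistence,
        window=(start, start + n_frames),
    )


@dataclasses.dataclass(frozen=True)
class InterTrimerCounts:
    """The three count variants of an inter-trimer hydrogen-bond census.

    ``persistent``            — bonds present in >50% of frames;
    ``total_excl_ligand``     — all inter-trimer bonds, ligand bonds excluded;
    ``total_incl_ligand``     — inter-trimer bonds plus ligand-mediated bonds.
    """

    persistent: float | np.ndarray
    total_excl_ligand: float | np.ndarray
    total_incl_ligand: float | np.ndarray


def count_inter_trimer(
    table: HBondTable, per_frame: bool = False
) -> InterTrimerCounts:
    """Count inter-trimer hydrogen bonds in the three standard variants.

    With ``per_frame`` the counts are per-frame occupied-bond numbers;
    otherwise their means over the window.  Including ligand bonds never
    yields fewer bonds than excluding them.
    """
    if not table.pairs:
        zero = np.zeros(table.occupancy.shape[1]) if per_frame else 0.0
        return InterTrimerCounts(zero, zero, zero)

    inter = np.array([p.span_class == "inter_trimer" for p in table.pairs])
    ligand = np.array([p.span_class == "ligand" for p in table.pairs])
    persistent = inter & (table.persistence > PERSISTENCE_THRESHOLD)

    def _count(mask: np.ndarray):
        series = table.occupancy[mask].sum(axis=0).astype(float)
        return series if per_frame else float(series.mean())

    return InterTrimerCounts(
        persistent=_count(persistent),
        total_excl_ligand=_count(inter),
        total_incl_ligand=_count(inter | ligand),
    )
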