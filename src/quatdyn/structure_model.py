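"""Structure and trajectory data model.

A :class:`StructureModel` is an ordered list of atoms with one coordinate
set (Å); a :class:`Trajectory` binds a model to a stack of coordinate
frames with a timestep in ps.  PDB is the native structure format and
multi-model PDB the native trajectory format; binary MD formats are
delegated to MDAnalysis behind the same contract.

Hexamer conventions follow the arginine-repressor C-terminal domain
(ArgRC) geometry the package is built around: six chains A–F forming two
stacked trimers (by default ABC below, DEF above, sharing a 3-fold axis),
with residues numbered as deposited (80–156 for EcArgRC).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AtomCountMismatchError,
    FormatError,
    PartitionError,
    UnknownElementError,
)

try:  # Bio.Data carries the IUPAC standard atomic weights
    from Bio.Data.IUPACData import atom_weights as _ATOM_WEIGHTS
except ImportError:  # pragma: no cover - biopython is a hard dependency
    _ATOM_WEIGHTS = {}

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "partition_trimers",
    "element_mass",
]


def element_mass(element: str) -> float:
    """Standard atomic weight (amu) for an element symbol."""
    sym = element.strip().capitalize()
    try:
        return float(_ATOM_WEIGHTS[sym])
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {element!r}") from None


@dataclasses.dataclass(slots=True)
class Atom:
    """A single atom record.

    ``residue_number`` keeps the deposited (1-based) PDB numbering;
    insertion codes are part of residue identity and never collapsed.
    """

    index: int
    name: str
    element: str
    mass: float
    residue_name: str
    residue_number: int
    chain_id: str
    icode: str = ""
    is_ligand: bool = False
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        if not self.chain_id:
            raise ValueError(f"atom {self.name}: chain_id must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_calpha(self) -> bool:
        return self.name == "CA" and self.element.upper() == "C"

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, residue number, insertion code) — unique residue key."""
        return (self.chain_id, self.residue_number, self.icode)


class StructureModel:
    """Ordered atoms plus one coordinate set and an optional trimer partition."""

    def __init__(
        self,
        atoms: Sequence[Atom],
        coordinates: np.ndarray,
        trimer_partition: Mapping[str, str] | None = None,
    ):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (len(atoms), 3):
            raise ValueError(
                f"coordinate count {coordinates.shape} does not match "
                f"atom count {len(atoms)}"
            )
        self.atoms: list[Atom] = list(atoms)
        self.coordinates = coordinates
        self.trimer_partition: dict[str, str] = dict(trimer_partition or {})
        self._masses: np.ndarray | None = None

    # -- basic views ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        if self._masses is None:
            self._masses = np.array([a.mass for a in self.atoms], dtype=float)
        return self._masses

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def protein_chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            if not a.is_ligand:
                seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def ligand_flags(self) -> dict[tuple[str, int, str], bool]:
        """Per-residue ligand flag keyed by residue identity."""
        flags: dict[tuple[str, int, str], bool] = {}
        for a in self.atoms:
            key = a.residue_id
            flags[key] = flags.get(key, False) or a.is_ligand
        return flags

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.atoms, self.coordinates.copy(), dict(self.trimer_partition)
        )

    def with_coordinates(self, coordinates: np.ndarray) -> "StructureModel":
        return StructureModel(self.atoms, coordinates, dict(self.trimer_partition))

    # -- selection -----------------------------------------------------

    def select(self, expression: str) -> np.ndarray:
        """Evaluate a selection expression; indices are strictly increasing.

        Selections are a function of the model only — they never look at
        coordinates, so the same index list is valid in every frame.
        """
        from .selection import select as _select

        return _select(self, expression)

    def calpha_indices(self) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if a.is_calpha], dtype=int
        )

    # -- trimer partition ----------------------------------------------

    def trimer_group(self, chain_id: str) -> str:
        try:
            return self.trimer_partition[chain_id]
        except KeyError:
            raise PartitionError(
                f"chain {chain_id!r} has no trimer assignment; "
                "call partition_trimers first"
            ) from None

    def trimer_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.trimer_partition.values():
            seen.setdefault(g, None)
        return list(seen)

    def trimer_indices(self, group: str, calpha_only: bool = False) -> np.ndarray:
        """Atom indices belonging to one trimer group."""
        chains = {c for c, g in self.trimer_partition.items() if g == group}
        if not chains:
            raise PartitionError(f"no chains assigned to trimer group {group!r}")
        idx = [
            a.index
            for a in self.atoms
            if a.chain_id in chains
            and not a.is_ligand
            and (a.is_calpha or not calpha_only)
        ]
        return np.array(idx, dtype=int)


@dataclasses.dataclass
class Trajectory:
    """Coordinate frames (F, N, 3) in Å bound to a model; timestep in ps."""

    model: StructureModel
    frames: np.ndarray
    timestep: float = 1.0
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.model.n_atoms, 3):
            raise AtomCountMismatchError(
                f"frame array of shape {self.frames.shape} does not match "
                f"model with {self.model.n_atoms} atoms"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must hold at least one frame")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps."""
        return self.time_origin + self.timestep * np.arange(self.n_frames)

    def window(self, start: int = 0, stop: int | None = None) -> "Trajectory":
        """Sub-trajectory over the half-open frame range [start, stop)."""
        frames = self.frames[start:stop]
        if frames.shape[0] == 0:
            raise ValueError(f"window [{start}, {stop}) selects no frames")
        return Trajectory(
            self.model,
            frames,
            self.timestep,
            self.time_origin + self.timestep * (start % max(self.n_frames, 1)),
        )


# ---------------------------------------------------------------------------
# PDB I/O (Biopython-backed reader, fixed-column writer)
# ---------------------------------------------------------------------------


def _parse_pdb(path: str | Path):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return parser.get_structure("model", str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable PDB record ({exc})") from exc


def _resolve_altlocs(residue):
    """Yield one atom per altloc group: highest occupancy, ties → altloc 'A'."""
    groups: dict[str, list] = {}
    order: list[str] = []
    for atom in residue.get_unpacked_list():
        name = atom.get_name()
        if name not in groups:
            groups[name] = []
            order.append(name)
        groups[name].append(atom)
    for name in order:
        candidates = groups[name]
        if len(candidates) == 1:
            yield candidates[0]
            continue
        def rank(a):
            occ = a.get_occupancy()
            occ = 0.0 if occ is None else occ
            alt = a.get_altloc() or ""
            # prefer higher occupancy; on ties prefer 'A', then lexicographic
            return (-occ, 0 if alt == "A" else 1, alt)
        yield sorted(candidates, key=rank)[0]


def _extract_atoms(bio_model, ligand_residue_names: set[str]):
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for chain in bio_model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            is_het = hetflag.strip() != ""
            is_lig = resname in ligand_residue_names
            for bio_atom in _resolve_altlocs(residue):
                element = (bio_atom.element or "").strip()
                if not element:
                    # fall back to the leading letter of the atom name
                    element = "".join(
                        c for c in bio_atom.get_name() if c.isalpha()
                    )[:1]
                if not element:
                    raise UnknownElementError(
                        f"atom {bio_atom.get_full_id()} has no element symbol"
                    )
                atoms.append(
                    Atom(
                        index=len(atoms),
                        name=bio_atom.get_name(),
                        element=element.capitalize(),
                        mass=element_mass(element),
                        residue_name=resname,
                        residue_number=int(resseq),
                        chain_id=str(chain.id).strip() or "A",
                        icode=icode.strip(),
                        is_ligand=is_lig,
                        is_hetero=is_het,
                    )
                )
                coords.append(np.asarray(bio_atom.get_coord(), dtype=float))
    return atoms, np.array(coords, dtype=float).reshape(len(atoms), 3)


def read_structure(
    path: str | Path, ligand_residue_names: Iterable[str] = ()
) -> StructureModel:
    """Read a (possibly multi-model) PDB file into a StructureModel.

    Only the first MODEL contributes coordinates.  Residues whose name is
    in ``ligand_residue_names`` are flagged as bound ligands.  Altloc
    groups are resolved to a single conformer (highest occupancy, ties
    going to altloc 'A').
    """
    structure = _parse_pdb(path)
    bio_models = list(structure)
    if not bio_models:
        raise FormatError(f"{path}: no MODEL/atom records found")
    atoms, coords = _extract_atoms(bio_models[0], set(ligand_residue_names))
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(atoms, coords)


def read_trajectory(
    path: str | Path,
    model: StructureModel,
    timestep: float | None = None,
    ligand_residue_names: Iterable[str] = (),
) -> Trajectory:
    """Read a trajectory bound to ``model``.

    Multi-model PDB is handled natively; any other extension is delegated
    to MDAnalysis (coordinates converted to Å on read, which is already
    MDAnalysis' native unit).
    """
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        structure = _parse_pdb(path)
        frames = []
        for bio_model in structure:
            _, coords = _extract_atoms(bio_model, set(ligand_residue_names))
            if coords.shape[0] != model.n_atoms:
                raise AtomCountMismatchError(
                    f"{path}: MODEL {bio_model.id + 1} has {coords.shape[0]} atoms, "
                    f"model has {model.n_atoms}"
                )
            frames.append(coords)
        if not frames:
            raise FormatError(f"{path}: no frames found")
        if timestep is None:
            if len(frames) <= 1:
                warnings.warn(
                    f"{path}: single-frame trajectory, defaulting timestep to 1 ps",
                    stacklevel=2,
                )
            timestep = 1.0
        return Trajectory(model, np.array(frames), timestep)
    return _read_trajectory_mdanalysis(path, model, timestep)


def _read_trajectory_mdanalysis(
    path: Path, model: StructureModel, timestep: float | None
) -> Trajectory:
    import tempfile

    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise FormatError(
            f"{path}: reading {path.suffix} trajectories requires MDAnalysis "
            "(install the 'md' extra)"
        ) from exc

    with tempfile.NamedTemporaryFile(suffix=".pdb", mode="w", delete=False) as fh:
        top_path = fh.name
        fh.write(_format_pdb_frame(model, model.coordinates, model_number=None))
        fh.write("END\n")
    universe = mda.Universe(top_path, str(path))
    if universe.atoms.n_atoms != model.n_atoms:
        raise AtomCountMismatchError(
            f"{path}: trajectory has {universe.atoms.n_atoms} atoms, "
            f"model has {model.n_atoms}"
        )
    frames = np.array([universe.atoms.positions.copy() for _ in universe.trajectory])
    dt = timestep
    if dt is None:
        dt = float(getattr(universe.trajectory, "dt", 1.0)) or 1.0
    return Trajectory(model, frames, dt)


_PDB_LINE = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element symbols of one letter start in column 14
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def _format_pdb_frame(
    model: StructureModel, coords: np.ndarray, model_number: int | None
) -> str:
    lines = []
    if model_number is not None:
        lines.append(f"MODEL     {model_number:>4d}\n")
    for atom, xyz in zip(model.atoms, coords):
        lines.append(
            _PDB_LINE.format(
                record="HETATM" if atom.is_hetero else "ATOM",
                serial=(atom.index % 99999) + 1,
                name=_format_atom_name(atom.name, atom.element),
                altloc=" ",
                resname=atom.residue_name,
                chain=atom.chain_id[:1],
                resseq=atom.residue_number,
                icode=atom.icode[:1] or " ",
                x=xyz[0],
                y=xyz[1],
                z=xyz[2],
                occ=1.0,
                b=0.0,
                element=atom.element.upper()[:2],
            )
        )
    if model_number is not None:
        lines.append("ENDMDL\n")
    return "".join(lines)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model's coordinate set as a single-model PDB file."""
    with open(path, "w") as fh:
        fh.write(_format_pdb_frame(model, model.coordinates, model_number=None))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write all frames as a multi-model PDB file."""
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(_format_pdb_frame(traj.model, frame, model_number=i + 1))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trimer partitioning
# ---------------------------------------------------------------------------


def partition_trimers(
    model: StructureModel, top_chains: Iterable[str]
) -> StructureModel:
    """Assign every protein chain to one of two trimer groups.

    ``top_chains`` names the chains of one trimer (conventionally the
    DEF/top trimer); all remaining protein chains form the other group.
    Group names are the sorted concatenation of member chain ids, so a
    canonical hexamer yields groups ``"ABC"`` and ``"DEF"``.  Idempotent.
    """
    top = {str(c) for c in top_chains}
    if not top:
        raise PartitionError("top_chains must be non-empty")
    chains = set(model.protein_chain_ids)
    missing = top - chains
    if missing:
        raise PartitionError(
            f"chains {sorted(missing)} not present in model (has {sorted(chains)})"
        )
    bottom = chains - top
    if not bottom:
        raise PartitionError(
            "top_chains must be a strict subset of the model's chains "
            "(no chains left for the second trimer)"
        )
    top_name = "".join(sorted(top))
    bottom_name = "".join(sorted(bottom))
    partition = {c: top_name for c in top}
    partition.update({c: bottom_name for c in bottom})
    out = model.copy()
    out.trimer_partition = partition
    return out
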