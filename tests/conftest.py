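"""Shared fixtures: hand-built PDB snippets and cached generator output."""

from __future__ import annotations

import numpy as np
import pytest

import quatdyn as q


def make_model(specs, coords, partition=None):
    """Build a StructureModel from (name, element, resname, resnum, chain) tuples."""
    atoms = [
        q.Atom(
            index=i,
            name=name,
            element=element,
            mass=q.structure_model.element_mass(element),
            residue_name=resname,
            residue_number=resnum,
            chain_id=chain,
        )
        for i, (name, element, resname, resnum, chain) in enumerate(specs)
    ]
    model = q.StructureModel(atoms, np.asarray(coords, dtype=float))
    if partition:
        model = q.partition_trimers(model, partition)
    return model


@pytest.fixture
def tiny_pdb(tmp_path):
    """Minimal one-atom PDB file (a single ALA Cα)."""
    path = tmp_path / "tiny.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A  80       1.000   2.000   3.000  1.00  0.00"
        "           C\n"
        "END\n"
    )
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """Two-conformer Cα plus an unambiguous CB."""
    path = tmp_path / "altloc.pdb"
    path.write_text(
        "ATOM      1  CA AALA A  80       1.000   0.000   0.000  0.40  0.00"
        "           C\n"
        "ATOM      2  CA BALA A  80       2.000   0.000   0.000  0.60  0.00"
        "           C\n"
        "ATOM      3  CB  ALA A  80       0.000   1.000   0.000  1.00  0.00"
        "           C\n"
        "END\n"
    )
    return path


@pytest.fixture
def ligand_pdb(tmp_path):
    """Protein chain A plus a free-arginine HETATM ligand chain L."""
    path = tmp_path / "ligand.pdb"
    path.write_text(
        "ATOM      1  CA  GLY A 103       0.000   0.000   0.000  1.00  0.00"
        "           C\n"
        "ATOM      2  CA  ASP A 128       9.800   0.000   0.000  1.00  0.00"
        "           C\n"
        "HETATM    3  N   ARG L 200       5.000   5.000   0.000  1.00  0.00"
        "           N\n"
        "END\n"
    )
    return path


@pytest.fixture
def multimodel_pdb(tmp_path):
    """Two-frame trajectory of a 3-atom chain."""
    lines = []
    for m, shift in ((1, 0.0), (2, 1.0)):
        lines.append(f"MODEL     {m:>4d}")
        for i, (x, y, z) in enumerate([(0, 0, 0), (1.5, 0, 0), (3.0, 0, 0)]):
            lines.append(
                f"ATOM  {i + 1:>5d}  CA  ALA A{80 + i:>4d}    "
                f"{x + shift:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "multi.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


# -- cached generator scenarios (session scope: built once) ----------------


@pytest.fixture(scope="session")
def default_run():
    """Moderate default-condition run: oscillating apo hexamer."""
    spec = q.GeneratorSpec(n_frames=1500, seed=11)
    model, traj, truth = q.generate(spec)
    return spec, model, traj, truth


@pytest.fixture(scope="session")
def clean_run():
    """Low-jitter oscillation run for geometry-sensitive checks."""
    spec = q.GeneratorSpec(
        n_frames=1000, seed=7, jitter_sigma_core=0.02, jitter_sigma_surface=0.05
    )
    model, traj, truth = q.generate(spec)
    return spec, model, traj, truth


@pytest.fixture(scope="session")
def jitter_only_run():
    """No rotation at all: pure harmonic jitter about the base structure."""
    spec = q.GeneratorSpec(
        n_frames=4000, seed=5, rotation_mean=0.0, rotation_amplitude=0.0
    )
    model, traj, truth = q.generate(spec)
    return spec, model, traj, truth
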