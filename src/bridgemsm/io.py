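"""Plain-text persistence for trajectories, models and helix ensembles.

Feature trajectories are delimited text (one frame per row, ``#`` header
carrying the frame interval and feature labels) with a JSON manifest per
set; discrete trajectories are one integer per line with a JSON sidecar;
helix C-alpha ensembles are minimal multi-MODEL PDB files written and
read through biotite.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from biotite.structure import Atom, array as atom_array, stack as atom_stack
from biotite.structure.io.pdb import PDBFile

from .features import FeatureTrajectory

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_dtrajs",
    "read_dtrajs",
    "write_helix_ensemble_pdb",
    "read_helix_ensemble_pdb",
]


def write_trajectories(
    trajs: Sequence[FeatureTrajectory], directory, prefix: str = "traj"
) -> Path:
    """Write trajectories as delimited text plus an index manifest (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, tr in enumerate(trajs):
        name = f"{prefix}_{i:03d}.tsv"
        header = (
            f"frame_interval={tr.frame_interval}\n"
            f"features={','.join(tr.feature_labels)}"
        )
        np.savetxt(directory / name, tr.values, header=header, delimiter="\t")
        names.append(name)
    manifest = directory / f"{prefix}_manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "files": names,
                "frame_interval": trajs[0].frame_interval,
                "feature_labels": trajs[0].feature_labels,
            }
        )
    )
    return manifest


def read_trajectories(manifest_path) -> list[FeatureTrajectory]:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    out = []
    for name in meta["files"]:
        values = np.loadtxt(manifest_path.parent / name, delimiter="\t", ndmin=2)
        out.append(
            FeatureTrajectory(
                values, meta["frame_interval"], list(meta["feature_labels"])
            )
        )
    return out


def write_dtrajs(dtrajs: Sequence[np.ndarray], directory, meta: dict | None = None):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, d in enumerate(dtrajs):
        name = f"dtraj_{i:03d}.txt"
        np.savetxt(directory / name, np.asarray(d, dtype=np.int64), fmt="%d")
        names.append(name)
    sidecar = {"files": names}
    sidecar.update(meta or {})
    (directory / "dtraj_manifest.json").write_text(json.dumps(sidecar))
    return directory / "dtraj_manifest.json"


def read_dtrajs(manifest_path) -> tuple[list[np.ndarray], dict]:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    dtrajs = [
        np.loadtxt(manifest_path.parent / name, dtype=np.int64, ndmin=1)
        for name in meta["files"]
    ]
    return dtrajs, meta


def _helix_atom_array(coords: np.ndarray):
    atoms = [
        Atom(
            coord,
            chain_id="A",
            res_id=i + 1,
            res_name="ALA",
            atom_name="CA",
            element="C",
        )
        for i, coord in enumerate(coords)
    ]
    return atom_array(atoms)


def write_helix_ensemble_pdb(ensembles: Sequence[np.ndarray], path) -> None:
    """Write C-alpha conformations as a multi-MODEL PDB (one MODEL each)."""
    arrays = [_helix_atom_array(np.asarray(c, dtype=float)) for c in ensembles]
    stack = atom_stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_helix_ensemble_pdb(path) -> list[np.ndarray]:
    """Read CA coordinates per MODEL, ordered by residue number."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    mask = stack.atom_name == "CA"
    out = []
    for model in stack:
        ca = model[mask]
        order = np.argsort(ca.res_id, kind="stable")
        out.append(np.asarray(ca.coord[order], dtype=float))
    return out
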