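"""Portable dataset container and standard-format trajectory reading.

Container layout (HDF5): /coordinates (n_frames, n_beads, 3), optional
/forces with the same shape, /box (3,), /bead_types (n_beads,),
/lipid_index (n_beads,), all float64/int64, with root attributes
``format_version``, ``units`` (JSON) and ``provenance`` (JSON).  Units are
always angstrom / kcal/mol/angstrom / amu / fs; readers of external formats
convert at the boundary (e.g. GRO files are nanometers) and refuse formats
whose units they cannot determine.

All writes are atomic (temp file + rename) so interrupted runs never leave
truncated artifacts.
"""

from __future__ import annotations

import json
import os
import tempfile

import h5py
import numpy as np

from cglipid.mapping import CGFrame
from cglipid.simulate import Trajectory

__all__ = [
    "UNITS",
    "FORMAT_VERSION",
    "ContainerError",
    "write_container",
    "read_container",
    "container_to_frames",
    "read_trajectory",
    "atomic_write_text",
]

FORMAT_VERSION = 1
UNITS = {
    "length": "angstrom",
    "force": "kcal/mol/angstrom",
    "energy": "kcal/mol",
    "mass": "amu",
    "time": "fs",
}


class ContainerError(ValueError):
    pass


def atomic_write_text(path, text: str) -> None:
    """Write text via a temp file + rename in the destination directory."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_container(
    path,
    coordinates: np.ndarray,
    box: np.ndarray,
    bead_types: np.ndarray,
    lipid_index: np.ndarray,
    forces: np.ndarray | None = None,
    time_per_frame: float = 0.0,
    provenance: dict | None = None,
) -> None:
    coordinates = np.asarray(coordinates, dtype=np.float64)
    if coordinates.ndim != 3 or coordinates.shape[2] != 3:
        raise ContainerError("coordinates must have shape (n_frames, n_beads, 3)")
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as h5:
            h5.create_dataset("coordinates", data=coordinates)
            if forces is not None:
                forces = np.asarray(forces, dtype=np.float64)
                if forces.shape != coordinates.shape:
                    raise ContainerError("forces shape differs from coordinates")
                h5.create_dataset("forces", data=forces)
            h5.create_dataset("box", data=np.asarray(box, dtype=np.float64))
            h5.create_dataset("bead_types", data=np.asarray(bead_types, dtype=np.int64))
            h5.create_dataset("lipid_index", data=np.asarray(lipid_index, dtype=np.int64))
            h5.attrs["format_version"] = FORMAT_VERSION
            h5.attrs["units"] = json.dumps(UNITS)
            h5.attrs["time_per_frame"] = float(time_per_frame)
            h5.attrs["provenance"] = json.dumps(provenance or {})
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_container(path) -> dict:
    """Read and validate a container; returns a dict of arrays + metadata."""
    with h5py.File(path, "r") as h5:
        if "format_version" not in h5.attrs:
            raise ContainerError("missing format_version attribute")
        out = {
            "coordinates": h5["coordinates"][...],
            "forces": h5["forces"][...] if "forces" in h5 else None,
            "box": h5["box"][...],
            "bead_types": h5["bead_types"][...].astype(np.intp),
            "lipid_index": h5["lipid_index"][...].astype(np.intp),
            "units": json.loads(h5.attrs["units"]),
            "time_per_frame": float(h5.attrs.get("time_per_frame", 0.0)),
            "provenance": json.loads(h5.attrs.get("provenance", "{}")),
            "format_version": int(h5.attrs["format_version"]),
        }
    n_beads = out["coordinates"].shape[1]
    if out["bead_types"].shape != (n_beads,) or out["lipid_index"].shape != (n_beads,):
        raise ContainerError("bead_types/lipid_index inconsistent with coordinates")
    if out["forces"] is not None and out["forces"].shape != out["coordinates"].shape:
        raise ContainerError("forces shape inconsistent with coordinates")
    return out


def container_to_frames(data: dict) -> list[CGFrame]:
    frames = []
    for i in range(data["coordinates"].shape[0]):
        frames.append(
            CGFrame(
                coordinates=data["coordinates"][i],
                forces=None if data["forces"] is None else data["forces"][i],
                bead_types=data["bead_types"],
                lipid_index=data["lipid_index"],
                box=data["box"],
            )
        )
    return frames


def container_to_trajectory(data: dict) -> Trajectory:
    return Trajectory(
        coordinates=data["coordinates"],
        box=data["box"],
        bead_types=data["bead_types"],
        lipid_index=data["lipid_index"],
        time_per_frame=data["time_per_frame"],
    )


_MDA_FORMATS = {".pdb", ".gro", ".dcd", ".xtc", ".trr"}


def read_trajectory(path, topology_path=None) -> Trajectory:
    """Read a trajectory from the container or a standard MD format.

    PDB/GRO/DCD/XTC/TRR go through MDAnalysis, which converts coordinates
    to angstroms (GRO/XTC/TRR are stored in nanometers).  Anything else is
    rejected explicitly rather than unit-guessed.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".h5", ".hdf5"}:
        return container_to_trajectory(read_container(path))
    if ext not in _MDA_FORMATS:
        raise ContainerError(f"unsupported trajectory format {ext!r}")
    import MDAnalysis as mda

    if topology_path is not None:
        u = mda.Universe(str(topology_path), str(path))
    else:
        u = mda.Universe(str(path))
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float64)
    dims = u.trajectory.ts.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ContainerError("trajectory has no box information")
    dt_fs = float(getattr(u.trajectory, "dt", 0.0)) * 1000.0  # MDAnalysis dt is ps
    n = u.atoms.n_atoms
    return Trajectory(
        coordinates=coords,
        box=np.asarray(dims[:3], dtype=np.float64),
        bead_types=np.zeros(n, dtype=np.intp),
        lipid_index=np.zeros(n, dtype=np.intp),
        time_per_frame=dt_fs,
    )
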