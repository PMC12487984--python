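"""Atomistic-to-CG mapping: six-bead center-of-mass coordinates and forces.

Each lipid is mapped to beads by mass-weighted averaging of disjoint atom
groups (HG = phosphate + choline/serine, MG = glycerol + esters, T1/T2 =
first/second half of each acyl tail for the standard six-bead scheme).  The
consistent force map for a COM coordinate map with disjoint groups is the
plain sum of the atomic forces in each group, which conserves the total
force exactly.

Bead ordering is deterministic: lipids in ascending lipid index, beads in
scheme order within each lipid.  Downstream topology construction relies on
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "BeadDef",
    "MappingScheme",
    "AtomisticFrame",
    "CGFrame",
    "CGTopology",
    "MappingError",
    "map_coordinates",
    "map_forces",
    "map_frame",
    "build_topology",
]


class MappingError(ValueError):
    """Raised for inconsistent mapping schemes or uncovered atoms."""


@dataclass(frozen=True)
class BeadDef:
    """One bead of a mapping scheme.

    ``atom_indices`` are 0-based positions within the lipid's atom block;
    ``masses`` are the corresponding atom masses in amu.
    """

    label: str
    bead_type: str
    atom_indices: tuple[int, ...]
    masses: tuple[float, ...]

    def __post_init__(self):
        if len(self.atom_indices) == 0:
            raise MappingError(f"bead {self.label}: empty atom group")
        if len(self.atom_indices) != len(self.masses):
            raise MappingError(f"bead {self.label}: indices/masses length mismatch")
        if any(m <= 0 for m in self.masses):
            raise MappingError(f"bead {self.label}: non-positive atom mass")


@dataclass(frozen=True)
class MappingScheme:
    """Per-lipid-type bead groups and intra-lipid bond topology."""

    lipid_type: str
    beads: tuple[BeadDef, ...]
    bonds: tuple[tuple[str, str], ...]

    def __post_init__(self):
        labels = [b.label for b in self.beads]
        if len(set(labels)) != len(labels):
            raise MappingError("duplicate bead labels")
        seen: set[int] = set()
        for b in self.beads:
            overlap = seen.intersection(b.atom_indices)
            if overlap:
                raise MappingError(f"atoms {sorted(overlap)} assigned to more than one bead")
            seen.update(b.atom_indices)
        for a, b in self.bonds:
            if a not in labels or b not in labels:
                raise MappingError(f"bond ({a},{b}) references unknown bead label")
            if a == b:
                raise MappingError(f"self-bond on bead {a}")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_atoms(self) -> int:
        return sum(len(b.atom_indices) for b in self.beads)

    @property
    def bead_masses(self) -> np.ndarray:
        return np.array([sum(b.masses) for b in self.beads])

    def bond_type_label(self, a: str, b: str) -> str:
        ta = next(x.bead_type for x in self.beads if x.label == a)
        tb = next(x.bead_type for x in self.beads if x.label == b)
        return "-".join(sorted((ta, tb)))

    @classmethod
    def from_yaml(cls, path) -> "MappingScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "MappingScheme":
        beads = tuple(
            BeadDef(
                label=b["label"],
                bead_type=b["bead_type"],
                atom_indices=tuple(int(i) for i in b["atom_indices"]),
                masses=tuple(float(m) for m in b["masses"]),
            )
            for b in doc["beads"]
        )
        bonds = tuple((str(a), str(b)) for a, b in doc.get("bonds", []))
        return cls(lipid_type=str(doc["lipid_type"]), beads=beads, bonds=bonds)

    def to_dict(self) -> dict:
        return {
            "lipid_type": self.lipid_type,
            "beads": [
                {
                    "label": b.label,
                    "bead_type": b.bead_type,
                    "atom_indices": [int(i) for i in b.atom_indices],
                    "masses": [float(m) for m in b.masses],
                }
                for b in self.beads
            ],
            "bonds": [list(b) for b in self.bonds],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class AtomisticFrame:
    """One frame of pseudo-atomistic coordinates and forces.

    coordinates/forces: (n_atoms, 3) in A and kcal/mol/A; masses: (n_atoms,)
    amu; lipid_index: (n_atoms,) integer lipid each atom belongs to;
    lipid_types: lipid_type label per lipid index; box: orthorhombic edge
    lengths (3,) in A.
    """

    coordinates: np.ndarray
    forces: np.ndarray
    masses: np.ndarray
    lipid_index: np.ndarray
    lipid_types: list[str]
    box: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.forces = np.asarray(self.forces, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coordinates.shape != self.forces.shape:
            raise MappingError("coordinates and forces shapes differ")
        if np.any(self.box <= 0):
            raise MappingError("box edges must be positive")


@dataclass
class CGFrame:
    """One CG frame: bead coordinates/forces (A, kcal/mol/A), integer bead
    types, per-bead lipid index, and orthorhombic box edges (A)."""

    coordinates: np.ndarray
    forces: np.ndarray | None
    bead_types: np.ndarray
    lipid_index: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if not np.all(np.isfinite(self.coordinates)):
            raise MappingError("non-finite bead coordinates")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=np.float64)
            if not np.all(np.isfinite(self.forces)):
                raise MappingError("non-finite bead forces")

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class CGTopology:
    """Global CG bond list and the bead-type vocabulary."""

    bond_pairs: np.ndarray  # (n_bonds, 2) int
    bond_type_labels: list[str]  # per bond
    type_codes: dict[str, int]  # bead_type label -> integer code
    bead_types: np.ndarray  # (n_beads,) int
    bead_masses: np.ndarray  # (n_beads,) amu
    lipid_index: np.ndarray  # (n_beads,) int

    def __post_init__(self):
        bp = np.asarray(self.bond_pairs, dtype=np.intp)
        if bp.size and bp.shape[1] != 2:
            raise MappingError("bond_pairs must be (n,2)")
        if bp.size:
            if np.any(bp[:, 0] == bp[:, 1]):
                raise MappingError("self-bond in topology")
            key = {tuple(sorted(p)) for p in bp.tolist()}
            if len(key) != len(bp):
                raise MappingError("duplicate bond pair")
            if bp.max() >= len(self.bead_types) or bp.min() < 0:
                raise MappingError("bond index out of range")
        self.bond_pairs = bp

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)


def _lipid_blocks(frame: AtomisticFrame):
    """Yield (lipid index, lipid_type, atom indices sorted) per lipid."""
    lipid_index = np.asarray(frame.lipid_index)
    for li in np.unique(lipid_index):
        atoms = np.nonzero(lipid_index == li)[0]
        yield int(li), frame.lipid_types[int(li)], atoms


def _check_coverage(scheme: MappingScheme, n_atoms: int):
    covered = sorted(i for b in scheme.beads for i in b.atom_indices)
    if covered != list(range(n_atoms)):
        raise MappingError(
            f"scheme {scheme.lipid_type} covers atoms {covered[:5]}... "
            f"but lipid has {n_atoms} atoms; every atom must be in exactly one bead"
        )


def _unwrap_group(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image unwrap of a group relative to its first atom.

    Lipids can straddle the periodic boundary; averaging raw wrapped
    coordinates would place the COM in the middle of the box.
    """
    ref = coords[0]
    delta = coords - ref
    delta -= box * np.round(delta / box)
    return ref + delta


def map_coordinates(
    frame: AtomisticFrame, schemes: dict[str, MappingScheme] | MappingScheme
) -> CGFrame:
    """Map atomistic coordinates to bead COM positions (forces left unset)."""
    return _map(frame, schemes, do_forces=False)


def map_forces(
    frame: AtomisticFrame, schemes: dict[str, MappingScheme] | MappingScheme
) -> CGFrame:
    """Map atomistic coordinates and forces to beads (COM + group force sum)."""
    return _map(frame, schemes, do_forces=True)


def map_frame(frame, schemes) -> CGFrame:
    """Alias for :func:`map_forces`: full coordinate + force mapping."""
    return _map(frame, schemes, do_forces=True)


def _as_scheme_dict(schemes) -> dict[str, MappingScheme]:
    if isinstance(schemes, MappingScheme):
        return {schemes.lipid_type: schemes}
    return dict(schemes)


def _type_codes(schemes: dict[str, MappingScheme]) -> dict[str, int]:
    labels = sorted({b.bead_type for s in schemes.values() for b in s.beads})
    return {lab: i for i, lab in enumerate(labels)}


def _map(frame: AtomisticFrame, schemes, do_forces: bool) -> CGFrame:
    schemes = _as_scheme_dict(schemes)
    codes = _type_codes(schemes)
    coords_out, forces_out, types_out, lidx_out = [], [], [], []
    for li, ltype, atoms in _lipid_blocks(frame):
        if ltype not in schemes:
            raise MappingError(f"no mapping scheme for lipid type {ltype!r}")
        scheme = schemes[ltype]
        _check_coverage(scheme, len(atoms))
        for bead in scheme.beads:
            sel = atoms[list(bead.atom_indices)]
            m = np.asarray(bead.masses)
            mtot = m.sum()
            if mtot <= 0:
                raise MappingError(f"bead {bead.label}: zero total mass")
            xyz = _unwrap_group(frame.coordinates[sel], frame.box)
            coords_out.append(m @ xyz / mtot)
            if do_forces:
                forces_out.append(frame.forces[sel].sum(axis=0))
            types_out.append(codes[bead.bead_type])
            lidx_out.append(li)
    return CGFrame(
        coordinates=np.array(coords_out),
        forces=np.array(forces_out) if do_forces else None,
        bead_types=np.array(types_out, dtype=np.intp),
        lipid_index=np.array(lidx_out, dtype=np.intp),
        box=frame.box.copy(),
    )


def build_topology(
    schemes: dict[str, MappingScheme] | MappingScheme,
    lipid_counts: dict[str, int] | None = None,
    lipid_sequence: list[str] | None = None,
) -> CGTopology:
    """Build the global CG bond list for a sequence of lipids.

    Either ``lipid_counts`` (type -> count, types concatenated in sorted
    order) or an explicit ``lipid_sequence`` of types must be given.  Bead
    indexing follows the mapping convention: lipids in order, beads in
    scheme order.
    """
    schemes = _as_scheme_dict(schemes)
    if lipid_sequence is None:
        if not lipid_counts:
            raise MappingError("need lipid_counts or lipid_sequence")
        lipid_sequence = []
        for t in sorted(lipid_counts):
            n = int(lipid_counts[t])
            if n < 1:
                raise MappingError(f"lipid count for {t!r} must be >= 1")
            lipid_sequence.extend([t] * n)
    if not lipid_sequence:
        raise MappingError("empty lipid sequence")
    codes = _type_codes(schemes)
    pairs, labels, btypes, bmasses, lidx = [], [], [], [], []
    offset = 0
    for li, t in enumerate(lipid_sequence):
        if t not in schemes:
            raise MappingError(f"unknown lipid type {t!r}")
        s = schemes[t]
        lab2idx = {b.label: offset + k for k, b in enumerate(s.beads)}
        for a, b in s.bonds:
            pairs.append((lab2idx[a], lab2idx[b]))
            labels.append(s.bond_type_label(a, b))
        for b in s.beads:
            btypes.append(codes[b.bead_type])
            bmasses.append(sum(b.masses))
            lidx.append(li)
        offset += s.n_beads
    return CGTopology(
        bond_pairs=np.array(pairs, dtype=np.intp).reshape(-1, 2),
        bond_type_labels=labels,
        type_codes=codes,
        bead_types=np.array(btypes, dtype=np.intp),
        bead_masses=np.array(bmasses),
        lipid_index=np.array(lidx, dtype=np.intp),
    )
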