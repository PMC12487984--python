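"""Ground-truth fixtures: toy CG lipid force field and bilayer generators.

The toy force field is a statistical stand-in for mapped atomistic
reference data: six-bead lipids with harmonic bonds, a soft r^-6 repulsion
between all bead pairs, and Gaussian attraction wells that make tails
cohesive and keep headgroups solvated-like at the interface, so a bilayer
is metastable without explicit solvent.  All parameters are recorded with
every fixture, forces are exact analytic gradients, and configurations are
sampled by running the package's own Langevin integrator, which makes every
downstream stage (mapping, prior fitting, training, simulation, analysis)
testable against known truth with no external data.

Fixtures make no attempt to mimic real DOPC/DOPS chemistry or atomistic
energetics; they provide known-truth statistics at the right geometry and
scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from cglipid.mapping import (
    AtomisticFrame,
    BeadDef,
    CGFrame,
    CGTopology,
    MappingScheme,
)
from cglipid.simulate import LangevinConfig, SimState, Trajectory, langevin_step, run_simulation
from cglipid.units import KB

__all__ = [
    "PairTerm",
    "ToyForceField",
    "FixtureSpec",
    "CGDataset",
    "StageError",
    "default_toy_forcefield",
    "toy_topology",
    "build_bilayer",
    "generate_cg_dataset",
    "expand_pseudo_atomistic",
    "end_to_end_recovery",
]

BEAD_TYPE_LABELS = ["HG", "MG", "T1", "T2"]  # codes 0..3 (sorted order)
BEAD_MASSES = {"HG": 180.0, "MG": 160.0, "T1": 120.0, "T2": 110.0}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PairTerm:
    """V(r) = eps_rep (sigma/r)^6 + depth exp(-(r-r_well)^2 / (2 w^2)),
    taken smoothly to zero at the cutoff by a cosine envelope."""

    eps_rep: float  # kcal/mol
    sigma: float  # A
    depth: float = 0.0  # kcal/mol (negative = cohesive)
    r_well: float = 5.5  # A
    width: float = 1.2  # A


@dataclass
class ToyForceField:
    """Analytic six-bead toy force field with recorded parameters."""

    bonds: dict[str, tuple[float, float]]  # label -> (k, r0)
    pairs: dict[str, PairTerm]  # "A-B" sorted label -> term
    cutoff: float = 12.0

    def to_dict(self) -> dict:
        return {
            "bonds": {k: list(v) for k, v in self.bonds.items()},
            "pairs": {k: asdict(v) for k, v in self.pairs.items()},
            "cutoff": self.cutoff,
        }

    # -- evaluation --------------------------------------------------------
    def _pair_vf(self, r: np.ndarray, term: PairTerm):
        """Enveloped pair energy and dV/dr (vectorized)."""
        rc = self.cutoff
        r = np.asarray(r, dtype=np.float64)
        rep = term.eps_rep * (term.sigma / r) ** 6
        drep = -6.0 * rep / r
        gauss = term.depth * np.exp(-((r - term.r_well) ** 2) / (2 * term.width**2))
        dgauss = gauss * (-(r - term.r_well) / term.width**2)
        env = 0.5 * (np.cos(np.pi * r / rc) + 1.0)
        denv = -0.5 * np.pi / rc * np.sin(np.pi * r / rc)
        v = rep + gauss
        dv = drep + dgauss
        return env * v, denv * v + env * dv

    def evaluate(self, frame: CGFrame, topo: CGTopology) -> tuple[float, np.ndarray]:
        from cglipid.geometry import pair_displacements
        from cglipid.potential import neighbor_pairs

        coords, box = frame.coordinates, frame.box
        forces = np.zeros_like(coords)
        energy = 0.0
        if len(topo.bond_pairs):
            disp, d = pair_displacements(coords, topo.bond_pairs, box)
            labels = np.asarray(topo.bond_type_labels)
            for label in np.unique(labels):
                sel = labels == label
                k, r0 = self.bonds[label]
                dr = d[sel] - r0
                energy += float(k * np.sum(dr**2))
                fvec = (2.0 * k * dr / d[sel])[:, None] * disp[sel]
                np.add.at(forces, topo.bond_pairs[sel, 0], fvec)
                np.add.at(forces, topo.bond_pairs[sel, 1], -fvec)
        pairs, shifts, d = neighbor_pairs(coords, box, self.cutoff)
        n = len(coords)
        if len(topo.bond_pairs):
            bp = np.sort(topo.bond_pairs, axis=1)
            excl = bp[:, 0] * n + bp[:, 1]
            keep = ~np.isin(pairs[:, 0] * n + pairs[:, 1], excl)
            pairs, shifts, d = pairs[keep], shifts[keep], d[keep]
        if len(pairs):
            code2label = {v: k for k, v in topo.type_codes.items()}
            nt = len(code2label)
            disp = coords[pairs[:, 1]] + shifts - coords[pairs[:, 0]]
            ta = topo.bead_types[pairs[:, 0]]
            tb = topo.bead_types[pairs[:, 1]]
            pkey = np.minimum(ta, tb) * nt + np.maximum(ta, tb)
            for key in np.unique(pkey):
                a, b = divmod(int(key), nt)
                term = self.pairs["-".join(sorted((code2label[a], code2label[b])))]
                sel = pkey == key
                v, dv = self._pair_vf(d[sel], term)
                energy += float(v.sum())
                fvec = (dv / d[sel])[:, None] * disp[sel]
                np.add.at(forces, pairs[sel, 0], fvec)
                np.add.at(forces, pairs[sel, 1], -fvec)
        return float(energy), forces


class BoundToyForceField:
    """Adapter binding a ToyForceField to a topology so it satisfies the
    potential contract energy_and_forces(frame)."""

    def __init__(self, ff: ToyForceField, topo: CGTopology):
        self.ff = ff
        self.topo = topo

    def energy_and_forces(self, frame: CGFrame):
        return self.ff.evaluate(frame, self.topo)


def default_toy_forcefield() -> ToyForceField:
    """Reference parameters: tails cohesive enough to hold a solvent-free
    bilayer together at 300 K, headgroups bulky and purely repulsive."""
    soft = dict(eps_rep=0.8, depth=0.0)
    return ToyForceField(
        bonds={"HG-MG": (3.0, 5.0), "MG-T1": (3.0, 5.0), "T1-T2": (4.0, 4.5)},
        pairs={
            "HG-HG": PairTerm(eps_rep=1.2, sigma=6.0),
            "HG-MG": PairTerm(eps_rep=1.0, sigma=5.5),
            "HG-T1": PairTerm(eps_rep=1.2, sigma=6.5),
            "HG-T2": PairTerm(eps_rep=1.2, sigma=6.5),
            "MG-MG": PairTerm(eps_rep=0.8, sigma=5.0, depth=-0.4, r_well=5.5, width=1.2),
            "MG-T1": PairTerm(eps_rep=0.8, sigma=5.0, depth=-0.4, r_well=5.5, width=1.2),
            "MG-T2": PairTerm(eps_rep=0.8, sigma=5.0, depth=-0.3, r_well=5.5, width=1.2),
            "T1-T1": PairTerm(eps_rep=0.8, sigma=4.8, depth=-1.1, r_well=5.4, width=1.4),
            "T1-T2": PairTerm(eps_rep=0.8, sigma=4.8, depth=-1.1, r_well=5.4, width=1.4),
            "T2-T2": PairTerm(eps_rep=0.8, sigma=4.8, depth=-1.2, r_well=5.4, width=1.4),
        },
        cutoff=12.0,
    )


def toy_topology(n_lipids: int) -> CGTopology:
    """Topology for n six-bead lipids: beads HG, MG, T1a, T2a, T1b, T2b with
    bonds HG-MG, MG-T1a, T1a-T2a, MG-T1b, T1b-T2b."""
    codes = {lab: i for i, lab in enumerate(BEAD_TYPE_LABELS)}
    bead_labels = ["HG", "MG", "T1", "T2", "T1", "T2"]
    bond_local = [(0, 1), (1, 2), (2, 3), (1, 4), (4, 5)]
    pairs, labels, btypes, masses, lidx = [], [], [], [], []
    for li in range(n_lipids):
        off = 6 * li
        for a, b in bond_local:
            pairs.append((off + a, off + b))
            labels.append("-".join(sorted((bead_labels[a], bead_labels[b]))))
        for lab in bead_labels:
            btypes.append(codes[lab])
            masses.append(BEAD_MASSES[lab])
            lidx.append(li)
    return CGTopology(
        bond_pairs=np.array(pairs, dtype=np.intp),
        bond_type_labels=labels,
        type_codes=codes,
        bead_types=np.array(btypes, dtype=np.intp),
        bead_masses=np.array(masses),
        lipid_index=np.array(lidx, dtype=np.intp),
    )


@dataclass(frozen=True)
class FixtureSpec:
    """What fixture to generate; the seed is mandatory and the spec hash is
    embedded in the output provenance."""

    n_lipids: int = 32
    geometry: str = "bilayer"  # bilayer | random-gas | dimer
    temperature: float = 300.0
    seed: int = 0
    n_frames: int = 100
    box_z: float = 80.0
    area_per_lipid: float = 64.0  # A^2, sets the xy box for bilayers
    atoms_per_bead: int = 3
    burn_in_steps: int = 2000
    sample_interval: int = 100  # >= 100 steps between stored frames
    timestep: float = 10.0  # fs
    damping: float = 1.0  # ps^-1; generator thermostat, not the CG run value

    def spec_hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class CGDataset:
    """Frames with exact toy-truth forces plus topology and provenance."""

    frames: list[CGFrame]
    topology: CGTopology
    provenance: dict

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_trajectory(self, time_per_frame: float = 1.0) -> Trajectory:
        return Trajectory(
            coordinates=np.array([f.coordinates for f in self.frames]),
            box=self.frames[0].box,
            bead_types=self.topology.bead_types,
            lipid_index=self.topology.lipid_index,
            time_per_frame=time_per_frame,
        )


def build_bilayer(spec: FixtureSpec, rng=None) -> tuple[CGFrame, CGTopology]:
    """Two opposed leaflets of six-bead lipids on a jittered xy grid."""
    if spec.n_lipids % 2:
        raise ValueError("bilayer needs an even lipid count")
    rng = rng or np.random.default_rng(spec.seed)
    per_leaf = spec.n_lipids // 2
    nx = int(np.ceil(np.sqrt(per_leaf)))
    ny = int(np.ceil(per_leaf / nx))
    spacing = np.sqrt(spec.area_per_lipid)
    box = np.array([nx * spacing, ny * spacing, spec.box_z])
    topo = toy_topology(spec.n_lipids)
    coords = np.zeros((6 * spec.n_lipids, 3))
    li = 0
    # z offsets from the midplane for HG, MG, T1a, T2a, T1b, T2b
    z_off = np.array([16.0, 11.0, 6.5, 2.5, 6.5, 2.5])
    x_off = np.array([0.0, 0.0, -1.2, -1.2, 1.2, 1.2])
    for leaflet in (+1, -1):
        for g in range(per_leaf):
            gx, gy = g % nx, g // nx
            base = np.array(
                [
                    (gx + 0.5) * spacing + rng.normal(0, 0.3),
                    (gy + 0.5) * spacing + rng.normal(0, 0.3),
                    spec.box_z / 2,
                ]
            )
            for b in range(6):
                coords[6 * li + b] = base + [x_off[b], 0.0, leaflet * z_off[b]]
            li += 1
    frame = CGFrame(
        coordinates=coords,
        forces=None,
        bead_types=topo.bead_types,
        lipid_index=topo.lipid_index,
        box=box,
    )
    return frame, topo


def _build_random_gas(spec: FixtureSpec, rng) -> tuple[CGFrame, CGTopology]:
    """Lipids dropped as compact random chains on a coarse grid (jittered so
    beads never start on top of each other)."""
    topo = toy_topology(spec.n_lipids)
    n_side = int(np.ceil(spec.n_lipids ** (1 / 3)))
    spacing = 14.0
    box = np.array([n_side * spacing] * 3)
    coords = np.zeros((6 * spec.n_lipids, 3))
    offsets = np.array(
        [[0, 0, 5.0], [0, 0, 0.0], [-1.2, 0, -4.5], [-1.2, 0, -8.5], [1.2, 0, -4.5], [1.2, 0, -8.5]]
    )
    for li in range(spec.n_lipids):
        gx = li % n_side
        gy = (li // n_side) % n_side
        gz = li // (n_side * n_side)
        base = (np.array([gx, gy, gz]) + 0.5) * spacing + rng.normal(0, 0.5, 3)
        rotz = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(rotz), np.sin(rotz)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        coords[6 * li : 6 * li + 6] = base + offsets @ R.T
    frame = CGFrame(coords, None, topo.bead_types, topo.lipid_index, box)
    return frame, topo


def _build_dimer(spec: FixtureSpec) -> tuple[CGFrame, CGTopology]:
    """A single bonded T1-T2 bead pair (thermostat validation system)."""
    codes = {lab: i for i, lab in enumerate(BEAD_TYPE_LABELS)}
    topo = CGTopology(
        bond_pairs=np.array([[0, 1]], dtype=np.intp),
        bond_type_labels=["T1-T2"],
        type_codes=codes,
        bead_types=np.array([codes["T1"], codes["T2"]], dtype=np.intp),
        bead_masses=np.array([BEAD_MASSES["T1"], BEAD_MASSES["T2"]]),
        lipid_index=np.array([0, 0], dtype=np.intp),
    )
    box = np.array([spec.box_z] * 3)
    coords = np.array([[0.0, 0.0, 0.0], [4.5, 0.0, 0.0]]) + box / 2
    frame = CGFrame(coords, None, topo.bead_types, topo.lipid_index, box)
    return frame, topo


def generate_cg_dataset(spec: FixtureSpec, ff: ToyForceField | None = None) -> CGDataset:
    """Sample configurations with the toy force field and store them with
    exact forces (re-evaluated at the stored coordinates)."""
    ff = ff or default_toy_forcefield()
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "bilayer":
        frame0, topo = build_bilayer(spec, rng)
    elif spec.geometry == "random-gas":
        frame0, topo = _build_random_gas(spec, rng)
    elif spec.geometry == "dimer":
        frame0, topo = _build_dimer(spec)
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    n_steps = spec.burn_in_steps + spec.n_frames * spec.sample_interval
    cfg = LangevinConfig(
        temperature=spec.temperature,
        damping=spec.damping,
        timestep=spec.timestep,
        n_steps=n_steps,
        save_interval=spec.sample_interval,
        seed=spec.seed,
    )
    try:
        traj = run_simulation(frame0, topo, None, BoundToyForceField(ff, topo), cfg)
    except Exception as exc:  # noqa: BLE001 - re-raise with guidance
        raise StageError(
            f"fixture equilibration failed ({exc}); try a smaller timestep in the spec"
        ) from exc
    n_burn_frames = spec.burn_in_steps // spec.sample_interval + 1
    frames = []
    for i in range(n_burn_frames, traj.n_frames):
        f = CGFrame(
            coordinates=traj.coordinates[i],
            forces=None,
            bead_types=topo.bead_types,
            lipid_index=topo.lipid_index,
            box=traj.box,
        )
        _, forces = ff.evaluate(f, topo)
        f.forces = forces
        frames.append(f)
    if len(frames) > spec.n_frames:
        frames = frames[-spec.n_frames :]
    provenance = {
        "spec": asdict(spec),
        "spec_hash": spec.spec_hash(),
        "forcefield": ff.to_dict(),
        "generator": "cglipid.synthetic.generate_cg_dataset",
    }
    return CGDataset(frames=frames, topology=topo, provenance=provenance)


# -------------------------------------------------------------------------
# pseudo-atomistic expansion
# -------------------------------------------------------------------------


def expand_pseudo_atomistic(
    dataset: CGDataset, atoms_per_bead: int, seed: int
) -> tuple[list[AtomisticFrame], MappingScheme]:
    """Replace each bead by ``atoms_per_bead`` atoms whose mass-weighted mean
    position and force sum reproduce the bead exactly; the returned scheme
    inverts the expansion.  Atom masses are drawn once so the scheme is
    constant across frames."""
    if atoms_per_bead < 1:
        raise ValueError("atoms_per_bead must be >= 1")
    topo = dataset.topology
    if topo.n_beads != 6 * (int(topo.lipid_index.max()) + 1):
        raise ValueError("pseudo-atomistic expansion requires six-bead lipids")
    rng = np.random.default_rng(seed)
    apb = atoms_per_bead
    code2label = {v: k for k, v in topo.type_codes.items()}

    bead_labels = ["HG", "MG", "T1a", "T2a", "T1b", "T2b"]
    bead_types = ["HG", "MG", "T1", "T2", "T1", "T2"]
    masses_per_bead = []
    beads = []
    for b in range(6):
        total = BEAD_MASSES[bead_types[b]]
        w = rng.uniform(0.5, 1.5, apb)
        m = total * w / w.sum()
        masses_per_bead.append(m)
        beads.append(
            BeadDef(
                label=bead_labels[b],
                bead_type=bead_types[b],
                atom_indices=tuple(range(b * apb, (b + 1) * apb)),
                masses=tuple(m),
            )
        )
    scheme = MappingScheme(
        lipid_type="TOY",
        beads=tuple(beads),
        bonds=(("HG", "MG"), ("MG", "T1a"), ("T1a", "T2a"), ("MG", "T1b"), ("T1b", "T2b")),
    )

    n_lipids = int(topo.lipid_index.max()) + 1
    frames_out = []
    for f in dataset.frames:
        n_atoms = f.n_beads * apb
        coords = np.empty((n_atoms, 3))
        forces = np.empty((n_atoms, 3))
        masses = np.empty(n_atoms)
        lipid_index = np.repeat(topo.lipid_index, apb)
        for bi in range(f.n_beads):
            m = masses_per_bead[bi % 6]
            if apb == 1:
                disp = np.zeros((1, 3))
                fnoise = np.zeros((1, 3))
            else:
                disp = rng.normal(0, 0.6, (apb, 3))
                disp -= (m @ disp / m.sum())  # mass-weighted mean is exactly zero
                fnoise = rng.normal(0, 1.0, (apb, 3))
                fnoise -= fnoise.mean(axis=0)  # sums exactly to zero
            sl = slice(bi * apb, (bi + 1) * apb)
            coords[sl] = f.coordinates[bi] + disp
            forces[sl] = f.forces[bi] / apb + fnoise
            masses[sl] = m
        frames_out.append(
            AtomisticFrame(
                coordinates=coords,
                forces=forces,
                masses=masses,
                lipid_index=lipid_index,
                lipid_types=["TOY"] * n_lipids,
                box=f.box.copy(),
            )
        )
    return frames_out, scheme


# -------------------------------------------------------------------------
# end-to-end closed loop
# -------------------------------------------------------------------------


def end_to_end_recovery(
    spec: FixtureSpec,
    train_cfg=None,
    ff: ToyForceField | None = None,
    sim_steps: int = 8000,
    rdf_bin_width: float = 0.5,
) -> dict:
    """Run the full pipeline on a toy fixture and report recovery metrics.

    Stages: generate truth data -> pseudo-atomistic round trip -> fit priors
    -> delta forces -> train a pairwise spline potential -> simulate with
    prior + trained model -> compare observables against a truth-driven
    simulation.  Returns a report with prior-parameter recovery errors,
    validation force RMSE before/after training, and RDF peak agreement.
    """
    from cglipid import priors as pr
    from cglipid.analysis import compute_rdf
    from cglipid.mapping import map_frame
    from cglipid.potential import SplinePairPotential, SplinePairPotentialConfig
    from cglipid.training import FMDataset, TrainConfig, force_rmse, train_potential

    if spec.n_lipids > 50 or spec.n_frames > 2000:
        raise ValueError("end_to_end_recovery is desk-scale: <= 50 lipids, <= 2000 frames")
    ff = ff or default_toy_forcefield()
    train_cfg = train_cfg or TrainConfig(max_epochs=80, learning_rate=1e-2, seed=spec.seed)
    report: dict = {"spec_hash": spec.spec_hash()}

    def stage(name):
        report.setdefault("stages", []).append(name)
        return name

    try:
        stage("generate")
        data = generate_cg_dataset(spec, ff)
        topo = data.topology

        stage("map-roundtrip")
        aa_frames, scheme = expand_pseudo_atomistic(data, spec.atoms_per_bead, spec.seed + 1)
        mapped = [map_frame(fr, scheme) for fr in aa_frames]
        coord_err = max(
            float(np.abs(m.coordinates - f.coordinates).max())
            for m, f in zip(mapped, data.frames)
        )
        force_err = max(
            float(np.abs(m.forces - f.forces).max()) for m, f in zip(mapped, data.frames)
        )
        report["mapping_roundtrip_coord_err"] = coord_err
        report["mapping_roundtrip_force_err"] = force_err

        stage("fit-priors")
        prior = pr.fit_prior_forcefield(mapped, topo, spec.temperature, cutoff=ff.cutoff)
        report["bond_prior_recovery"] = {
            lab: {
                "k_true": ff.bonds[lab][0],
                "k_fit": prior.bonds[lab].k,
                "r0_true": ff.bonds[lab][1],
                "r0_fit": prior.bonds[lab].r0,
                "k_rel_err": abs(prior.bonds[lab].k - ff.bonds[lab][0]) / ff.bonds[lab][0],
                "r0_rel_err": abs(prior.bonds[lab].r0 - ff.bonds[lab][1]) / ff.bonds[lab][1],
            }
            for lab in ff.bonds
        }

        stage("delta-forces")
        targets = []
        for m in mapped:
            _, f_prior = pr.evaluate_prior(m, topo, prior)
            targets.append(pr.compute_delta_forces(m, f_prior))

        stage("train")
        box_min = float(data.frames[0].box.min())
        model_cutoff = min(ff.cutoff, box_min / 2 * 0.999)
        model = SplinePairPotential(
            SplinePairPotentialConfig(cutoff=model_cutoff, r_min=2.5, n_basis=12, n_types=4),
            exclusions={tuple(p) for p in topo.bond_pairs.tolist()},
        )
        fm_data = FMDataset.from_frames(
            mapped, targets, val_fraction=0.1, seed=spec.seed, provenance=spec.spec_hash()
        )
        val_frames = [mapped[i] for i in fm_data.val_idx]
        rmse0 = force_rmse(model, prior, topo, val_frames)
        model, history = train_potential(model, fm_data, train_cfg)
        rmse1 = force_rmse(model, prior, topo, val_frames)
        report["val_force_rmse_initial"] = rmse0
        report["val_force_rmse_trained"] = rmse1
        report["val_force_rmse_ratio"] = rmse1 / rmse0
        report["final_train_loss"] = history[-1]["train_loss"]

        stage("simulate")
        initial = data.frames[-1]
        sim_cfg = LangevinConfig(
            temperature=spec.temperature,
            damping=0.1,
            timestep=spec.timestep,
            n_steps=sim_steps,
            save_interval=100,
            seed=spec.seed + 2,
        )
        traj_truth = run_simulation(initial, topo, None, BoundToyForceField(ff, topo), sim_cfg)
        traj_model = run_simulation(initial, topo, prior, model, sim_cfg)

        stage("analyze")
        tails = np.nonzero(
            (topo.bead_types == topo.type_codes["T1"]) | (topo.bead_types == topo.type_codes["T2"])
        )[0]
        r_max = box_min / 2 * 0.98
        n_bins = int(r_max / rdf_bin_width)
        rdf_truth = compute_rdf(traj_truth, tails, tails, r_max, n_bins, labels=("T", "T"))
        rdf_model = compute_rdf(traj_model, tails, tails, r_max, n_bins, labels=("T", "T"))
        report["rdf_bin_width"] = float(rdf_truth.bin_centers[1] - rdf_truth.bin_centers[0])
        report["rdf_first_peak_truth"] = rdf_truth.first_peak
        report["rdf_first_peak_model"] = rdf_model.first_peak
        report["rdf_peak_offset_bins"] = abs(
            rdf_model.first_peak - rdf_truth.first_peak
        ) / report["rdf_bin_width"]
        return report
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {report['stages'][-1]!r} failed: {exc}") from exc
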