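"""Solvent-free CG Langevin dynamics (NVT, orthorhombic periodic box).

The integrator is the BAOAB splitting of underdamped Langevin dynamics,
chosen for its accurate configurational sampling at large time steps.  With
temperature 0 and zero damping it reduces to velocity Verlet.  Units: A,
fs, amu, kcal/mol; the damping constant is given in ps^-1 as is
conventional for membrane simulations (default 0.1 ps^-1, default time
step 1-20 fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cglipid.mapping import CGFrame, CGTopology
from cglipid.units import FORCE_TO_ACC, KB, PS_TO_FS, kinetic_energy, kinetic_temperature

__all__ = [
    "LangevinConfig",
    "SimState",
    "Trajectory",
    "BlowUpError",
    "langevin_step",
    "run_simulation",
    "maxwell_boltzmann_velocities",
]


class BlowUpError(RuntimeError):
    """Integration produced non-finite coordinates."""


@dataclass
class LangevinConfig:
    temperature: float = 300.0  # K
    damping: float = 0.1  # ps^-1
    timestep: float = 20.0  # fs
    n_steps: int = 1000
    save_interval: int = 100
    seed: int = 0
    remove_com_motion: bool = False

    def __post_init__(self):
        if self.temperature < 0 or self.damping < 0 or self.timestep <= 0:
            raise ValueError("invalid Langevin parameters")


@dataclass
class SimState:
    coordinates: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    box: np.ndarray
    masses: np.ndarray
    step: int = 0

    def copy(self) -> "SimState":
        return SimState(
            self.coordinates.copy(),
            self.velocities.copy(),
            self.forces.copy(),
            self.box.copy(),
            self.masses.copy(),
            self.step,
        )


@dataclass
class Trajectory:
    """Saved frames of a CG run. Coordinates are unwrapped (no PBC folding),
    which is what displacement-based observables need; distance-based
    observables apply the minimum image themselves."""

    coordinates: np.ndarray  # (n_frames, n_beads, 3)
    box: np.ndarray  # (3,)
    bead_types: np.ndarray
    lipid_index: np.ndarray
    time_per_frame: float  # fs
    energies: list[dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def frame(self, i: int) -> CGFrame:
        return CGFrame(
            coordinates=self.coordinates[i],
            forces=None,
            bead_types=self.bead_types,
            lipid_index=self.lipid_index,
            box=self.box,
        )


def maxwell_boltzmann_velocities(masses, temperature, rng) -> np.ndarray:
    """Initial velocities (A/fs) from the Maxwell-Boltzmann distribution."""
    sigma = np.sqrt(KB * max(temperature, 0.0) * FORCE_TO_ACC / np.asarray(masses))
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def langevin_step(state: SimState, force_fn, cfg: LangevinConfig, rng) -> SimState:
    """One BAOAB step: B(h/2) A(h/2) O A(h/2) [force update] B(h/2).

    ``force_fn(coords) -> (energy, forces)``; the state caches the forces at
    its coordinates so each step costs one force evaluation.
    """
    h = cfg.timestep
    m = state.masses[:, None]
    gamma = cfg.damping / PS_TO_FS  # fs^-1
    x = state.coordinates
    v = state.velocities

    v = v + 0.5 * h * state.forces * FORCE_TO_ACC / m
    x = x + 0.5 * h * v
    c1 = np.exp(-gamma * h)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma = np.sqrt(KB * cfg.temperature * FORCE_TO_ACC / m)
    v = c1 * v + c2 * sigma * rng.normal(size=v.shape)
    x = x + 0.5 * h * v
    _, forces = force_fn(x)
    v = v + 0.5 * h * forces * FORCE_TO_ACC / m

    dmax = float(np.nanmax(np.abs(x - state.coordinates)))
    # a step larger than half a box edge invalidates minimum-image forces,
    # so it is a blow-up even while coordinates are still finite
    if not np.all(np.isfinite(x)) or dmax > 0.5 * float(state.box.min()):
        raise BlowUpError(f"integration blew up at step {state.step + 1} (max disp {dmax:.3g} A)")
    if cfg.remove_com_motion:
        v = v - np.average(v, axis=0, weights=state.masses)
    return SimState(x, v, forces, state.box, state.masses, state.step + 1)


def run_simulation(
    initial: CGFrame,
    topo: CGTopology,
    prior,
    model,
    cfg: LangevinConfig,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """Langevin NVT run under prior + trained model; frames saved every
    ``save_interval`` steps (the initial frame is always included)."""
    from cglipid.priors import evaluate_prior
    from cglipid.potential import total_force_field

    def force_fn(coords):
        f = CGFrame(
            coordinates=coords,
            forces=None,
            bead_types=initial.bead_types,
            lipid_index=initial.lipid_index,
            box=initial.box,
        )
        if prior is not None:
            e, forces = evaluate_prior(f, topo, prior)
        else:
            e, forces = 0.0, np.zeros_like(coords)
        if model is not None:
            em, fm = model.energy_and_forces(f)
            e, forces = e + em, forces + fm
        return e, forces

    rng = np.random.default_rng(cfg.seed)
    masses = topo.bead_masses
    if velocities is None:
        velocities = maxwell_boltzmann_velocities(masses, cfg.temperature, rng)
    e0, f0 = force_fn(initial.coordinates)
    state = SimState(
        initial.coordinates.astype(np.float64).copy(),
        velocities.copy(),
        f0,
        initial.box.copy(),
        masses.copy(),
        0,
    )

    frames = [state.coordinates.copy()]
    energies = [_energy_record(state, e0)]
    pot = e0
    for _ in range(cfg.n_steps):
        state = langevin_step(state, force_fn, cfg, rng)
        if state.step % cfg.save_interval == 0:
            pot = force_fn(state.coordinates)[0]
            frames.append(state.coordinates.copy())
            energies.append(_energy_record(state, pot))
    return Trajectory(
        coordinates=np.array(frames),
        box=initial.box.copy(),
        bead_types=initial.bead_types.copy(),
        lipid_index=initial.lipid_index.copy(),
        time_per_frame=cfg.timestep * cfg.save_interval,
        energies=energies,
    )


def _energy_record(state: SimState, potential: float) -> dict:
    ke = kinetic_energy(state.velocities, state.masses)
    return {
        "step": state.step,
        "potential": potential,
        "kinetic": ke,
        "total": potential + ke,
        "temperature": kinetic_temperature(state.velocities, state.masses),
    }
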