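# Methods

This note records the modelling assumptions, numerical choices, and default
parameters behind `cglipid`, and what the synthetic fixtures do and do not
establish about real membrane data.

## Mapping

Six beads per lipid (HG, MG, T1/T2 per tail), COM mapping. The force map is
the unweighted sum of atomic forces per group: for a COM coordinate map
with disjoint groups this is the consistent choice, and it conserves the
total force identically (checked to machine precision in the tests). Bead
order is fixed — lipids ascending, beads in scheme order — because the
bond topology indexes beads positionally. Before averaging, each group is
unwrapped by minimum image relative to its first atom, so lipids straddling
a periodic boundary map correctly. Atom-level group membership is a user
YAML config (`MappingScheme`); the fixture generator emits a matching
scheme for its own pseudo-atoms.

## Priors

* **Bonds.** Harmonic, `V(r) = k (r - r0)^2 + V0` (no 1/2 — k absorbs it).
  Fit by moment matching on the Jacobian-corrected density p(r)/r^2:
  moments are bin-free and unbiased, and they are exact for the Gaussian
  this functional form implies. The 1/r^2 correction is the standard radial
  Jacobian for distance distributions in 3-D.
* **Repulsion.** `V(r) = 4 eps r^-6 + V0`. eps is a linear least-squares
  fit of the pair PMF (-kB T ln g(r), plateau of g normalized to 1) over
  the rising wall: from the smallest observed distance to where g(r) first
  reaches 1. Only the wall is fit because that is all this term is meant to
  model; an attractive fit clips to eps = 0.
* **Exclusions.** Directly bonded (1-2) pairs are excluded from the
  repulsive term; 1-3 pairs are kept. The choice is recorded in the
  serialized force field.
* **No angle priors.** The prior is bonds + repulsion only; angular
  correlations are left to the trained potential.
* **Near-singularity guard.** Below r = 0.5 A the repulsive potential
  continues linearly, which caps the force at its value at the guard while
  keeping the force the exact gradient of the evaluated energy. This keeps
  early training and equilibration finite; equilibrated configurations
  never visit this region.
* **Spline bonds.** For visibly non-Gaussian bond-length distributions
  (the double-peaked tail bond being the motivating case) a cubic B-spline
  fit of the corrected PMF is available per bond type; it reproduces
  double-well shapes the harmonic cannot. Outside the knot range it
  continues linearly with the edge slope so forces stay bounded and
  restoring. Bins that are empty inside the fit range are skipped with a
  warning and bridged by the spline's own smoothness.

## Trainable potentials

Both implementations expose the same contract: scalar energy of
(coordinates, bead types, box); forces are the exact negative gradient;
energy is translation invariant and invariant under permutation of
identical-type beads.

* **Graph potential.** Continuous-filter convolution network: type
  embeddings (width 128 by default), edges = bead pairs within the cutoff
  (12 A default) under minimum image, Gaussian radial basis (18 functions)
  with a cosine envelope that takes every filter smoothly to zero at the
  cutoff (continuous forces are required by the integrator), four
  interaction layers by default, shifted-softplus activations, per-bead
  energy head summed to E (size-extensive). All widths/depths are
  configurable. Parameter initialization is deterministic under a recorded
  seed, because seed-to-seed variation of trained models is part of the
  workflow and must be reproducible.
* **Autodiff core.** The network runs on a small reverse-mode engine over
  NumPy arrays written for this package. Backward rules are themselves
  composed of differentiable operations, so gradients can be
  differentiated again — training on forces needs exactly that
  (d/dtheta of dE/dx). First- and second-order gradients are verified
  against finite differences in the tests.
* **Spline potential.** Per type-pair cubic B-splines on [r_min, cutoff]
  with the same cosine envelope; energy is linear in the coefficients, so
  its force-matching loss is convex and its parameter gradients are exact
  in closed form. It doubles as an independent cross-check on the graph
  model and as the fast default for the closed-loop fixture, whose truth
  is pairwise. Bonded pairs can be excluded via the topology.

## Training

The loss is the mean over frames of `1/(3N) sum_I |F_target,I - F_model,I|^2`,
with the ensemble average read as the empirical mean over dataset frames
and the per-frame normalization applied before averaging. Targets are
delta forces (mapped minus prior). The optimizer is Adam with plateau-based
learning-rate decay (factor 0.5 after 5 stale epochs) and early stopping;
validation split is 10% of frames by default, seeded; the best-validation
parameters are restored at the end. Identical seeds give bitwise-identical
loss histories.

## Simulation

Underdamped Langevin NVT via BAOAB splitting, chosen for its accurate
configurational sampling at large steps (the 20 fs production step). At
T = 0 and zero damping it reduces to velocity Verlet; the tests verify
energy conservation in that limit, the analytic harmonic position variance
kB T/(2k), the free-particle Einstein relation D = kB T/(m gamma), and the
exact Boltzmann bond-length distribution of a harmonic dimer (KS test).
Defaults: 300 K, damping 0.1 ps^-1. Initial velocities are
Maxwell-Boltzmann under the run seed. Center-of-mass motion is not removed
by default (the noise is per-bead); a flag enables it. A step that moves
any bead more than half a box edge — or produces non-finite coordinates —
raises a blow-up error naming the step and displacement, since
minimum-image forces silently wrap otherwise. Trajectories store unwrapped
coordinates: displacement observables need them, and distance observables
re-apply the minimum image themselves.

Units: A, fs, amu, kcal/mol; kB = 1.987204259e-3 kcal/mol/K; the
acceleration factor (kcal/mol/A)/amu = 4.184e-4 A/fs^2 is exact in these
units.

## Analysis

* RDF: 3-D shell-normalized pair histogram under minimum image, averaged
  over frames; same-selection pairs counted once with the n(n-1)/2
  reference.
* z-density: each frame recentered so the mean z of all beads (the bilayer
  midplane) is zero; "area-normalized" is implemented as unit integral
  over z. (A per-xy-area normalization would only rescale profiles by a
  constant.)
* Thickness: leaflets assigned by the sign of z relative to the per-frame
  midplane; per 10 x 10 A cell, mean upper-HG z minus mean lower-HG z;
  cells missing a leaflet are masked, never imputed; the scalar is the
  occupancy-weighted mean. Lipids crossing the midplane (flip-flop) are
  not tracked.
* Order parameter: S = <(3 cos^2 theta - 1)/2> against the box z-axis (the
  planar-bilayer normal); standard errors from the per-frame series.
* MSD: lateral (xy), averaged over all time origins and selected beads
  (MG beads by convention for lipid diffusion); D = slope/4 from a
  least-squares fit over lags in [10%, 50%] of the maximum — late enough
  to avoid the ballistic start, early enough that origins still average
  well. Wrapped input is detected (frame-to-frame jump > box/2) and
  rejected.

## Synthetic fixtures

The toy force field stands in for mapped atomistic reference data: six-bead
lipids, harmonic bonds (k = 3-4 kcal/mol/A^2, r0 = 4.5-5 A), soft
(sigma/r)^6 repulsion everywhere, Gaussian cohesion wells between tail
beads (depth ~ -1.1 to -1.2 kcal/mol at 5.4 A) and mild MG cohesion, bulky
purely repulsive headgroups. These values were chosen once so that a
solvent-free bilayer is metastable over fixture-length runs at 300 K —
the observables presume a bilayer — and they are serialized with every
fixture. Forces are exact analytic gradients and stored frames carry
forces re-evaluated at the stored coordinates, so the training targets are
exact by construction.

Fixtures are sampled with the package's own integrator; the generator uses
damping 1.0 ps^-1 and a 10 fs step (sampling efficiency only — the
stationary distribution does not depend on the damping), stores frames at
intervals of >= 100 steps to reduce autocorrelation, and is
bit-reproducible from (spec, seed). The pseudo-atomistic expansion places
atoms_per_bead atoms per bead with mass-weighted mean position and force
sum equal to the bead values exactly, so mapping round trips are exact.

The closed-loop recovery (`end_to_end_recovery`, `cglipid recover`) runs
map -> fit priors -> delta forces -> train -> simulate -> analyze at desk
scale. Default study conditions: 32 lipids, 60 stored frames, 80 training
epochs at learning rate 1e-2, 6000-step comparison runs (about two minutes
on one CPU). The trained model is the spline implementation by default —
the toy truth is pairwise, so the model family contains it.

What passing these tests shows: every pipeline stage is internally
consistent, the estimators converge to their analytic targets, and the
full loop recovers a known pairwise truth. What they do not show: fidelity
to real atomistic lipid data — the toy force field has no electrostatics,
no solvent-mediated structure, no chemical detail beyond bead types, and
its delta forces are pairwise-representable, which real many-body residuals
are not. Results on real membranes depend on data quality and model
capacity in ways the fixtures cannot probe.

## Known limitations

* Orthorhombic boxes only; NVT only (no barostat, by design for
  solvent-free CG runs).
* Neighbor search is all-pairs O(N^2) — fine at desk scale (10^2-10^3
  beads), not for large membranes.
* The graph potential trains on CPU via the built-in autodiff core; it is
  sized for small systems and validation, not production-scale training.
* Leaflet assignment assumes a planar bilayer normal along z.
* The bending modulus is not computed.
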