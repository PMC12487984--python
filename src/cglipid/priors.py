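"""Prior force field: Boltzmann-inversion parametrization and evaluation.

The prior carries the physics the trained potential should not have to
learn: harmonic bonds

    V_bond(r) = k (r - r0)^2 + V0          (no 1/2 factor; k absorbs it)

and a Lennard-Jones-inspired pairwise repulsive wall

    V_rep(r) = 4 eps r^-6 + V0.

Both are parametrized from mapped trajectories by Boltzmann inversion.  For
bond lengths the radial Jacobian is removed first: the inverted density is
p(r)/r^2, whose Gaussian width sigma gives k = kB*T / (2 sigma^2).  The
repulsive constant eps is a least-squares fit of 4 eps r^-6 to the pair PMF
-kB*T ln g(r) over the rising wall.

Subtracting prior forces from mapped forces yields the delta forces that
the trainable potential is fit to.  A cubic B-spline bonded term is provided
as a more flexible alternative for non-Gaussian (e.g. bimodal tail-bond)
distance distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import LSQUnivariateSpline

from cglipid.geometry import all_pair_distances, pair_displacements
from cglipid.mapping import CGFrame, CGTopology
from cglipid.units import KB

__all__ = [
    "BondPrior",
    "RepulsivePrior",
    "PriorForceField",
    "SplineBondTerm",
    "PriorFitError",
    "fit_bond_prior",
    "fit_repulsive_prior",
    "fit_spline_bond",
    "evaluate_prior",
    "compute_delta_forces",
    "bond_distance_samples",
    "nonbonded_distance_samples",
    "fit_prior_forcefield",
]

FORMAT_VERSION = 1

# Below this separation the r^-7 repulsive force diverges; the potential is
# continued linearly so early training and equilibration stay finite.
R_MIN_GUARD = 0.5


class PriorFitError(ValueError):
    """Raised when Boltzmann inversion cannot be performed on the samples."""


@dataclass(frozen=True)
class BondPrior:
    """Harmonic bond term V(r) = k (r - r0)^2 + V0."""

    bond_type: str
    k: float  # kcal/mol/A^2
    r0: float  # A
    V0: float = 0.0

    def __post_init__(self):
        if self.k <= 0 or self.r0 <= 0:
            raise PriorFitError(f"bond {self.bond_type}: k and r0 must be positive")

    def energy(self, r):
        return self.k * (np.asarray(r) - self.r0) ** 2 + self.V0

    def dvdr(self, r):
        return 2.0 * self.k * (np.asarray(r) - self.r0)


@dataclass(frozen=True)
class RepulsivePrior:
    """Repulsive pair term V(r) = 4 eps r^-6 + V0 (eps in kcal/mol*A^6)."""

    type_pair: str
    epsilon: float
    V0: float = 0.0

    def __post_init__(self):
        if self.epsilon < 0:
            raise PriorFitError(f"pair {self.type_pair}: epsilon must be >= 0")

    def energy(self, r):
        r = np.maximum(np.asarray(r, dtype=np.float64), 1e-12)
        rg = np.maximum(r, R_MIN_GUARD)
        v = 4.0 * self.epsilon * rg**-6 + self.V0
        # linear continuation below the guard: energy stays consistent with
        # the capped force, so the gradient check holds everywhere
        return v + np.where(
            r < R_MIN_GUARD, (-24.0 * self.epsilon * R_MIN_GUARD**-7) * (r - R_MIN_GUARD), 0.0
        )

    def dvdr(self, r):
        r = np.maximum(np.asarray(r, dtype=np.float64), 1e-12)
        rg = np.maximum(r, R_MIN_GUARD)
        return -24.0 * self.epsilon * rg**-7


def _pair_key(a: str, b: str) -> str:
    return "-".join(sorted((a, b)))


@dataclass
class SplineBondTerm:
    """Cubic B-spline bonded potential (flexible alternative to harmonic).

    Outside the knot range the potential continues linearly with the edge
    slope, so forces stay bounded and restoring.
    """

    bond_type: str
    knots: np.ndarray
    coefficients: np.ndarray
    degree: int = 3

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=np.float64)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        interior = self.knots[self.degree : len(self.knots) - self.degree]
        if np.any(np.diff(interior) <= 0):
            raise PriorFitError("spline knots must be strictly increasing")

    def _spline(self):
        from scipy.interpolate import BSpline

        return BSpline(self.knots, self.coefficients, self.degree, extrapolate=False)

    def energy(self, r):
        r = np.asarray(r, dtype=np.float64)
        sp = self._spline()
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        rc = np.clip(r, lo, hi)
        v = sp(rc)
        d = sp.derivative()(rc)
        return v + d * (r - rc)

    def dvdr(self, r):
        r = np.asarray(r, dtype=np.float64)
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        rc = np.clip(r, lo, hi)
        return self._spline().derivative()(rc)

    def local_minima(self, n_grid: int = 2000):
        """Locations of interior local minima on a fine grid (A)."""
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        r = np.linspace(lo, hi, n_grid)
        v = self.energy(r)
        idx = np.nonzero((v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:]))[0] + 1
        return r[idx]


@dataclass
class PriorForceField:
    """Harmonic bond priors per bond type + repulsive priors per type pair.

    Directly bonded (1-2) bead pairs are excluded from the repulsive term;
    1-3 pairs are kept.  Bonded terms may be swapped for spline terms per
    bond type via ``spline_bonds``.
    """

    bonds: dict[str, BondPrior]
    repulsions: dict[str, RepulsivePrior]
    cutoff: float
    exclusion: str = "bonded-1-2"
    spline_bonds: dict[str, SplineBondTerm] = field(default_factory=dict)

    def bond_term(self, label: str):
        if label in self.spline_bonds:
            return self.spline_bonds[label]
        return self.bonds[label]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "cutoff": float(self.cutoff),
            "exclusion": self.exclusion,
            "bonds": {
                k: {"k": float(v.k), "r0": float(v.r0), "V0": float(v.V0)}
                for k, v in self.bonds.items()
            },
            "repulsions": {
                k: {"epsilon": float(v.epsilon), "V0": float(v.V0)}
                for k, v in self.repulsions.items()
            },
            "spline_bonds": {
                k: {
                    "knots": v.knots.tolist(),
                    "coefficients": v.coefficients.tolist(),
                    "degree": int(v.degree),
                }
                for k, v in self.spline_bonds.items()
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "PriorForceField":
        bonds = {k: BondPrior(k, v["k"], v["r0"], v.get("V0", 0.0)) for k, v in doc["bonds"].items()}
        reps = {
            k: RepulsivePrior(k, v["epsilon"], v.get("V0", 0.0))
            for k, v in doc["repulsions"].items()
        }
        splines = {
            k: SplineBondTerm(k, np.array(v["knots"]), np.array(v["coefficients"]), v["degree"])
            for k, v in doc.get("spline_bonds", {}).items()
        }
        return cls(
            bonds=bonds,
            repulsions=reps,
            cutoff=float(doc["cutoff"]),
            exclusion=doc.get("exclusion", "bonded-1-2"),
            spline_bonds=splines,
        )

    @classmethod
    def from_yaml(cls, path) -> "PriorForceField":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# -------------------------------------------------------------------------
# Boltzmann-inversion fits
# -------------------------------------------------------------------------


def fit_bond_prior(
    distances, temperature: float, bond_type: str = "bond", min_samples: int = 100
) -> BondPrior:
    """Harmonic bond prior from observed bond lengths by moment matching.

    The radial Jacobian is removed by weighting each sample with 1/r^2
    before taking moments, i.e. moments of p(r)/r^2.  For that corrected
    Gaussian, r0 is the mean and k = kB*T / (2 sigma^2).
    """
    r = np.asarray(distances, dtype=np.float64)
    if r.size < min_samples:
        raise PriorFitError(f"need >= {min_samples} bond samples, got {r.size}")
    w = r**-2
    r0 = float(np.average(r, weights=w))
    var = float(np.average((r - r0) ** 2, weights=w))
    if not np.isfinite(var) or var <= 1e-14 * r0**2:
        raise PriorFitError("degenerate bond-length distribution (zero variance)")
    k = KB * temperature / (2.0 * var)
    return BondPrior(bond_type=bond_type, k=k, r0=r0, V0=0.0)


def fit_repulsive_prior(
    pair_distances,
    temperature: float,
    fit_range: tuple[float, float] | None = None,
    type_pair: str = "pair",
    n_bins: int = 60,
) -> RepulsivePrior:
    """Repulsive prior from nonbonded pair distances.

    The pair PMF is estimated as -kB*T ln g(r) with g(r) from the
    shell-normalized distance histogram (plateau scaled to 1), and
    4 eps r^-6 + C is fit by linear least squares over ``fit_range``.  The
    default range spans the rising wall: from the smallest observed distance
    to where g(r) first reaches 1.  An attractive fit is clipped to eps = 0.
    """
    r = np.asarray(pair_distances, dtype=np.float64)
    if r.size == 0:
        raise PriorFitError("no pair distances supplied")
    hist, edges = np.histogram(r, bins=n_bins)
    centers = 0.5 * (edges[1:] + edges[:-1])
    shell = centers**2
    gr = hist / shell
    # plateau normalization: mean over the outer third of occupied bins
    occ = np.nonzero(hist > 0)[0]
    tail = occ[max(0, int(len(occ) * 2 / 3)) :]
    plateau = gr[tail].mean()
    if plateau <= 0:
        raise PriorFitError("cannot normalize g(r): empty tail")
    gr = gr / plateau
    if fit_range is None:
        r_lo = float(r.min())
        above = np.nonzero((gr >= 1.0) & (hist > 0))[0]
        r_hi = float(centers[above[0]]) if len(above) else float(centers[occ[-1]])
        fit_range = (r_lo, r_hi)
    lo, hi = fit_range
    sel = (centers >= lo) & (centers <= hi) & (hist > 0)
    if not np.any(sel):
        raise PriorFitError(f"empty repulsive fit range ({lo:.3g}, {hi:.3g}) A")
    pmf = -KB * temperature * np.log(gr[sel])
    basis = np.column_stack([4.0 * centers[sel] ** -6, np.ones(sel.sum())])
    coef, *_ = np.linalg.lstsq(basis, pmf, rcond=None)
    eps = max(float(coef[0]), 0.0)
    return RepulsivePrior(type_pair=type_pair, epsilon=eps, V0=0.0)


def fit_spline_bond(
    distances,
    temperature: float,
    n_knots: int = 8,
    bond_type: str = "bond",
    n_bins: int = 80,
) -> SplineBondTerm:
    """Cubic B-spline bonded term from the Jacobian-corrected bond PMF.

    The PMF w(r) = -kB*T ln(p(r)/r^2) + const is estimated on a histogram
    and approximated by a least-squares cubic spline with ``n_knots``
    equally spaced interior knots.  Bimodal bond-length distributions yield
    a double-well potential, which the harmonic form cannot represent.
    """
    if n_knots < 4:
        raise PriorFitError("need n_knots >= 4")
    r = np.asarray(distances, dtype=np.float64)
    if r.size < 100:
        raise PriorFitError("need >= 100 samples for a spline fit")
    hist, edges = np.histogram(r, bins=n_bins)
    centers = 0.5 * (edges[1:] + edges[:-1])
    good = hist > 0
    if not np.all(good):
        warnings.warn(
            "empty histogram bins inside the spline range; spline interpolates across them",
            RuntimeWarning,
        )
    dens = hist[good] / (centers[good] ** 2)
    w = -KB * temperature * np.log(dens / dens.max())
    x = centers[good]
    interior = np.linspace(x[0], x[-1], n_knots + 2)[1:-1]
    spl = LSQUnivariateSpline(x, w, interior, k=3)
    tck = spl._eval_args
    return SplineBondTerm(
        bond_type=bond_type, knots=np.asarray(tck[0]), coefficients=np.asarray(tck[1]), degree=3
    )


# -------------------------------------------------------------------------
# evaluation
# -------------------------------------------------------------------------


def _nonbonded_pairs(frame: CGFrame, topo: CGTopology, cutoff: float):
    pairs, d = all_pair_distances(frame.coordinates, frame.box)
    keep = d < cutoff
    if len(topo.bond_pairs):
        n = frame.n_beads
        bp = np.sort(topo.bond_pairs, axis=1)
        excl = bp[:, 0] * n + bp[:, 1]
        keep &= ~np.isin(pairs[:, 0] * n + pairs[:, 1], excl)
    return pairs[keep], d[keep]


def evaluate_prior(
    frame: CGFrame, topo: CGTopology, prior: PriorForceField
) -> tuple[float, np.ndarray]:
    """Total prior energy and per-bead forces (exact analytic gradients)."""
    if topo.n_beads != frame.n_beads:
        raise ValueError("topology/frame bead count mismatch")
    coords, box = frame.coordinates, frame.box
    forces = np.zeros_like(coords)
    energy = 0.0

    if len(topo.bond_pairs):
        disp, d = pair_displacements(coords, topo.bond_pairs, box)
        labels = np.asarray(topo.bond_type_labels)
        for label in np.unique(labels):
            term = prior.bond_term(label)
            sel = labels == label
            r = d[sel]
            energy += float(np.sum(term.energy(r)))
            # dV/dr along the unit bond vector; disp points i -> j
            fvec = (term.dvdr(r) / r)[:, None] * disp[sel]
            np.add.at(forces, topo.bond_pairs[sel, 0], fvec)
            np.add.at(forces, topo.bond_pairs[sel, 1], -fvec)

    pairs, d = _nonbonded_pairs(frame, topo, prior.cutoff)
    if len(pairs):
        if np.any(d < R_MIN_GUARD):
            warnings.warn(
                f"{int(np.sum(d < R_MIN_GUARD))} bead pairs below {R_MIN_GUARD} A; "
                "repulsive force capped",
                RuntimeWarning,
            )
        code2label = {v: k for k, v in topo.type_codes.items()}
        nt = len(code2label)
        ta = topo.bead_types[pairs[:, 0]]
        tb = topo.bead_types[pairs[:, 1]]
        pkey = np.minimum(ta, tb) * nt + np.maximum(ta, tb)
        disp = pair_displacements(coords, pairs, box)[0]
        for key in np.unique(pkey):
            a, b = divmod(int(key), nt)
            rep = prior.repulsions[_pair_key(code2label[a], code2label[b])]
            sel = pkey == key
            r = d[sel]
            energy += float(np.sum(rep.energy(r)))
            fvec = (rep.dvdr(r) / r)[:, None] * disp[sel]
            np.add.at(forces, pairs[sel, 0], fvec)
            np.add.at(forces, pairs[sel, 1], -fvec)

    return energy, forces


def compute_delta_forces(mapped: CGFrame, prior_forces: np.ndarray) -> np.ndarray:
    """Delta forces: mapped atomistic forces minus prior forces."""
    if mapped.forces is None:
        raise ValueError("mapped frame carries no forces")
    prior_forces = np.asarray(prior_forces, dtype=np.float64)
    if prior_forces.shape != mapped.forces.shape:
        raise ValueError(
            f"shape mismatch: mapped {mapped.forces.shape} vs prior {prior_forces.shape}"
        )
    return mapped.forces - prior_forces


# -------------------------------------------------------------------------
# dataset-level helpers
# -------------------------------------------------------------------------


def bond_distance_samples(frames, topo: CGTopology) -> dict[str, np.ndarray]:
    """Bond-length samples per bond type, pooled over frames."""
    out: dict[str, list] = {}
    labels = np.array(topo.bond_type_labels)
    for frame in frames:
        _, d = pair_displacements(frame.coordinates, topo.bond_pairs, frame.box)
        for lab in np.unique(labels):
            out.setdefault(lab, []).append(d[labels == lab])
    return {k: np.concatenate(v) for k, v in out.items()}


def nonbonded_distance_samples(
    frames, topo: CGTopology, r_max: float
) -> dict[str, np.ndarray]:
    """Non-excluded pair distances below r_max per bead-type pair."""
    code2label = {v: k for k, v in topo.type_codes.items()}
    nt = len(code2label)
    out: dict[str, list] = {}
    for frame in frames:
        pairs, d = _nonbonded_pairs(frame, topo, r_max)
        ta = topo.bead_types[pairs[:, 0]]
        tb = topo.bead_types[pairs[:, 1]]
        pkey = np.minimum(ta, tb) * nt + np.maximum(ta, tb)
        for key in np.unique(pkey):
            a, b = divmod(int(key), nt)
            out.setdefault(_pair_key(code2label[a], code2label[b]), []).append(d[pkey == key])
    return {k: np.concatenate(v) for k, v in out.items()}


def fit_prior_forcefield(
    frames, topo: CGTopology, temperature: float, cutoff: float
) -> PriorForceField:
    """Fit the full prior (all bond types + all type pairs) from frames."""
    bonds = {
        lab: fit_bond_prior(d, temperature, bond_type=lab)
        for lab, d in bond_distance_samples(frames, topo).items()
    }
    reps = {}
    samples = nonbonded_distance_samples(frames, topo, cutoff)
    labels = sorted(topo.type_codes)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            key = _pair_key(a, b)
            if key in samples and samples[key].size >= 100:
                reps[key] = fit_repulsive_prior(samples[key], temperature, type_pair=key)
            else:
                reps[key] = RepulsivePrior(type_pair=key, epsilon=0.0)
    return PriorForceField(bonds=bonds, repulsions=reps, cutoff=cutoff)
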