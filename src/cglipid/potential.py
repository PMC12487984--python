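"""Trainable CG potentials: graph message-passing network and spline baseline.

Both implementations satisfy the same contract: a potential maps
(coordinates, bead types, box) to a single energy scalar whose exact
negative gradient is the force array.  Energies are translation invariant
and invariant under permutation of identical-type beads by construction.

The graph potential is a continuous-filter convolution network: bead types
are embedded into node features; edges are bead pairs within a cutoff under
the minimum image; each interaction layer filters neighbor features with a
learned function of the pair distance (expanded in Gaussian radial bases and
smoothly enveloped at the cutoff) and aggregates them; a small perceptron
head contracts node features into per-bead energies that sum to E.  Forces
come from reverse-mode differentiation, and training differentiates through
that gradient, so parameter gradients of force-matching losses are exact.

The spline potential is the classical pairwise baseline: per type-pair cubic
B-spline energies, linear in their coefficients, with a smooth cutoff
envelope.  It is fast, convex to fit, and serves as an independent
cross-check on the graph model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from cglipid import autodiff as ad
from cglipid.geometry import minimum_image
from cglipid.mapping import CGFrame, CGTopology

__all__ = [
    "GeometryError",
    "VocabularyError",
    "neighbor_pairs",
    "GraphPotentialConfig",
    "GraphPotential",
    "SplinePairPotentialConfig",
    "SplinePairPotential",
    "total_force_field",
    "load_potential",
]

CHECKPOINT_VERSION = 1


class GeometryError(ValueError):
    """Cutoff incompatible with the periodic box."""


class VocabularyError(KeyError):
    """Bead type outside the model's type vocabulary."""


def neighbor_pairs(coords: np.ndarray, box: np.ndarray, cutoff: float):
    """Unordered pairs (i<j) with minimum-image distance < cutoff.

    Returns (pairs, shifts, distances) where ``shifts`` are the periodic
    image offsets such that x[j] + shift - x[i] is the minimum-image
    displacement.  Requires cutoff <= min(box)/2 so a single image suffices.
    """
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    box = np.asarray(box, dtype=np.float64)
    if cutoff > box.min() / 2:
        raise GeometryError(
            f"cutoff {cutoff} A exceeds half the smallest box edge ({box.min() / 2} A)"
        )
    n = len(coords)
    ii, jj = np.triu_indices(n, k=1)
    raw = coords[jj] - coords[ii]
    shift = -box * np.round(raw / box)
    d = np.linalg.norm(raw + shift, axis=1)
    keep = d < cutoff
    return np.column_stack([ii[keep], jj[keep]]), shift[keep], d[keep]


# -------------------------------------------------------------------------
# graph potential
# -------------------------------------------------------------------------


@dataclass(frozen=True)
class GraphPotentialConfig:
    n_interaction_layers: int = 4
    embedding_width: int = 128
    n_radial_basis: int = 18
    cutoff: float = 12.0
    head_width: int = 64
    n_types: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_interaction_layers < 1:
            raise ValueError("need at least one interaction layer")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


class GraphPotential:
    """Message-passing potential with continuous-filter convolutions."""

    kind = "graph"

    def __init__(self, config: GraphPotentialConfig, params: list[np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()
        c = config
        self._mu = np.linspace(0.0, c.cutoff, c.n_radial_basis)
        spacing = self._mu[1] - self._mu[0]
        self._gamma = 1.0 / (2.0 * spacing**2)

    # -- parameters --------------------------------------------------------
    def _init_params(self) -> list[np.ndarray]:
        c = self.config
        rng = np.random.default_rng(c.seed)
        F, K, H = c.embedding_width, c.n_radial_basis, c.head_width

        def dense(nin, nout, scale=1.0):
            return rng.normal(0.0, scale / np.sqrt(nin), size=(nin, nout))

        params = [rng.normal(0.0, 1.0, size=(c.n_types, F))]  # embedding
        for _ in range(c.n_interaction_layers):
            params += [
                dense(F, F), np.zeros(F),        # pre-message linear
                dense(K, F), np.zeros(F),        # filter net layer 1
                dense(F, F), np.zeros(F),        # filter net layer 2
                dense(F, F), np.zeros(F),        # node update layer 1
                dense(F, F, scale=0.1), np.zeros(F),  # node update layer 2
            ]
        params += [dense(F, H), np.zeros(H), dense(H, 1, scale=0.01), np.zeros(1)]
        return params

    @property
    def cutoff(self) -> float:
        return self.config.cutoff

    @property
    def type_vocabulary(self) -> range:
        return range(self.config.n_types)

    # -- forward -----------------------------------------------------------
    def _forward(self, coords: np.ndarray, types: np.ndarray, box: np.ndarray):
        """Build the energy graph; returns (E tensor, x tensor, param tensors)."""
        types = np.asarray(types, dtype=np.intp)
        if types.min() < 0 or types.max() >= self.config.n_types:
            raise VocabularyError(
                f"bead types outside vocabulary 0..{self.config.n_types - 1}"
            )
        c = self.config
        x = ad.Tensor(coords, requires_grad=True)
        pt = [ad.Tensor(p, requires_grad=True) for p in self.params]
        pairs, shifts, _ = neighbor_pairs(coords, box, c.cutoff)
        # directed edges, both ways
        src = np.concatenate([pairs[:, 1], pairs[:, 0]])
        dst = np.concatenate([pairs[:, 0], pairs[:, 1]])
        sh = np.concatenate([shifts, -shifts])
        n = len(coords)

        rij = ad.gather(x, src) - ad.gather(x, dst) + ad.Tensor(sh)
        d = ad.sqrt(ad.tsum(ad.mul(rij, rij), axis=1))  # (E,)
        dcol = ad.reshape(d, (-1, 1))
        rbf = ad.exp(ad.mul(ad.power(dcol - ad.Tensor(self._mu[None, :]), 2.0), -self._gamma))
        env = ad.mul(ad.add(ad.cos(ad.mul(dcol, np.pi / c.cutoff)), 1.0), 0.5)

        h = ad.gather(pt[0], types)  # (N,F)
        k = 1
        for _ in range(c.n_interaction_layers):
            W1, b1, fW1, fb1, fW2, fb2, U1, c1, U2, c2 = pt[k : k + 10]
            k += 10
            filt = ad.matmul(ad.shifted_softplus(ad.matmul(rbf, fW1) + fb1), fW2) + fb2
            filt = ad.mul(filt, env)
            msg = ad.mul(ad.gather(ad.matmul(h, W1) + b1, src), filt)
            agg = ad.scatter_add(msg, dst, n)
            upd = ad.matmul(ad.shifted_softplus(ad.matmul(agg, U1) + c1), U2) + c2
            h = h + upd
        Wh1, bh1, Wh2, bh2 = pt[k : k + 4]
        e_node = ad.matmul(ad.shifted_softplus(ad.matmul(h, Wh1) + bh1), Wh2) + bh2
        return ad.tsum(e_node), x, pt

    def energy_and_forces(self, frame: CGFrame) -> tuple[float, np.ndarray]:
        E, x, _ = self._forward(frame.coordinates, frame.bead_types, frame.box)
        g = ad.grad(E, x)
        return E.item(), -g.data

    def force_loss_and_grads(self, frame: CGFrame, target: np.ndarray):
        """Force-matching loss 1/(3N) sum |target - F_pred|^2 and its exact
        parameter gradients (differentiating through the force gradient)."""
        E, x, pt = self._forward(frame.coordinates, frame.bead_types, frame.box)
        gx = ad.grad(E, x)  # dE/dx; predicted force is -gx
        resid = ad.Tensor(np.asarray(target)) + gx  # target - (-gx)
        n = frame.n_beads
        loss = ad.mul(ad.tsum(ad.mul(resid, resid)), 1.0 / (3.0 * n))
        grads = ad.grad(loss, pt)
        return loss.item(), [g.data for g in grads]

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        meta = {"version": CHECKPOINT_VERSION, "kind": self.kind, "config": asdict(self.config)}
        arrays = {f"param_{i}": p for i, p in enumerate(self.params)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "GraphPotential":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
        return cls(GraphPotentialConfig(**meta["config"]), params=params)


# -------------------------------------------------------------------------
# spline pair potential
# -------------------------------------------------------------------------


@dataclass(frozen=True)
class SplinePairPotentialConfig:
    cutoff: float = 12.0
    r_min: float = 2.0
    n_basis: int = 14
    n_types: int = 4

    def __post_init__(self):
        if self.cutoff <= self.r_min:
            raise ValueError("cutoff must exceed r_min")


class SplinePairPotential:
    """Pairwise cubic B-spline potential, one coefficient set per type pair.

    The energy is linear in the coefficients.  A cosine envelope takes the
    potential smoothly to zero at the cutoff; below r_min it continues
    linearly so forces stay bounded.
    """

    kind = "spline"

    def __init__(
        self,
        config: SplinePairPotentialConfig,
        coefficients: dict[tuple[int, int], np.ndarray] | None = None,
        exclusions: set[tuple[int, int]] | None = None,
    ):
        self.config = config
        c = config
        # clamped cubic knot vector on [r_min, cutoff]
        n_interior = c.n_basis - 2  # so that n_basis = n_interior + k - 1 with k=3
        grid = np.linspace(c.r_min, c.cutoff, n_interior)
        self.knots = np.concatenate([[grid[0]] * 3, grid, [grid[-1]] * 3])
        self.n_coef = len(self.knots) - 4
        keys = [
            (a, b) for a in range(c.n_types) for b in range(a, c.n_types)
        ]
        if coefficients is None:
            coefficients = {k: np.zeros(self.n_coef) for k in keys}
        self.coefficients = {k: np.asarray(v, dtype=np.float64) for k, v in coefficients.items()}
        self._keys = sorted(self.coefficients)
        self.exclusions = {tuple(sorted(p)) for p in (exclusions or set())}
        self._design_cache: dict[int, tuple] = {}

    @property
    def cutoff(self) -> float:
        return self.config.cutoff

    @property
    def params(self) -> list[np.ndarray]:
        return [self.coefficients[k] for k in self._keys]

    # -- basis -------------------------------------------------------------
    def _basis(self, r: np.ndarray):
        """Enveloped basis values and radial derivatives at distances r."""
        c = self.config
        r = np.asarray(r, dtype=np.float64)
        rc = np.clip(r, c.r_min, c.cutoff)
        B = np.zeros((len(r), self.n_coef))
        dB = np.zeros_like(B)
        for k in range(self.n_coef):
            coef = np.zeros(self.n_coef)
            coef[k] = 1.0
            sp = BSpline(self.knots, coef, 3, extrapolate=False)
            B[:, k] = sp(rc)
            dB[:, k] = sp.derivative()(rc)
        env = 0.5 * (np.cos(np.pi * rc / c.cutoff) + 1.0)
        denv = -0.5 * np.pi / c.cutoff * np.sin(np.pi * rc / c.cutoff)
        Phi = env[:, None] * B
        dPhi = denv[:, None] * B + env[:, None] * dB
        # linear continuation below r_min
        below = r < c.r_min
        if np.any(below):
            Phi[below] += dPhi[below] * (r[below] - c.r_min)[:, None]
        return Phi, dPhi

    def _pair_data(self, frame: CGFrame):
        pairs, shifts, d = neighbor_pairs(frame.coordinates, frame.box, self.config.cutoff)
        if self.exclusions and len(pairs):
            n = frame.n_beads
            excl = np.array([i * n + j for i, j in self.exclusions])
            keep = ~np.isin(pairs[:, 0] * n + pairs[:, 1], excl)
            pairs, shifts, d = pairs[keep], shifts[keep], d[keep]
        t = frame.bead_types
        if len(pairs):
            ta = np.minimum(t[pairs[:, 0]], t[pairs[:, 1]])
            tb = np.maximum(t[pairs[:, 0]], t[pairs[:, 1]])
            keymasks = [(ta == a) & (tb == b) for a, b in self._keys]
            disp = frame.coordinates[pairs[:, 1]] + shifts - frame.coordinates[pairs[:, 0]]
        else:
            keymasks = [np.zeros(0, dtype=bool) for _ in self._keys]
            disp = np.zeros((0, 3))
        return pairs, disp, d, keymasks

    def energy_and_forces(self, frame: CGFrame) -> tuple[float, np.ndarray]:
        if len(frame.bead_types) and frame.bead_types.max() >= self.config.n_types:
            raise VocabularyError("bead type outside vocabulary")
        pairs, disp, d, keymasks = self._pair_data(frame)
        forces = np.zeros_like(frame.coordinates)
        energy = 0.0
        if len(pairs) == 0:
            return energy, forces
        Phi, dPhi = self._basis(d)
        for key, mask in zip(self._keys, keymasks):
            if not mask.any():
                continue
            coef = self.coefficients[key]
            energy += float(np.sum(Phi[mask] @ coef))
            dv = dPhi[mask] @ coef
            fvec = (dv / d[mask])[:, None] * disp[mask]
            np.add.at(forces, pairs[mask, 0], fvec)
            np.add.at(forces, pairs[mask, 1], -fvec)
        return energy, forces

    def _designs(self, frame: CGFrame):
        """Per type-pair force design tensors G (n_basis, n_beads, 3); the
        predicted force is sum_key coef_key . G_key.  Cached per frame
        object since the geometry of a training frame never changes."""
        cached = self._design_cache.get(id(frame))
        if cached is not None:
            return cached
        pairs, disp, d, keymasks = self._pair_data(frame)
        n = frame.n_beads
        designs = []
        if len(pairs) == 0:
            designs = [np.zeros((self.n_coef, n, 3)) for _ in self._keys]
        else:
            Phi, dPhi = self._basis(d)
            for key, mask in zip(self._keys, keymasks):
                G = np.zeros((self.n_coef, n, 3))
                if mask.any():
                    w = dPhi[mask] / d[mask][:, None]  # (m, n_basis)
                    contrib = w[:, :, None] * disp[mask][:, None, :]  # (m, n_basis, 3)
                    for bi in range(self.n_coef):
                        np.add.at(G[bi], pairs[mask, 0], contrib[:, bi, :])
                        np.add.at(G[bi], pairs[mask, 1], -contrib[:, bi, :])
                designs.append(G)
        self._design_cache[id(frame)] = designs
        if len(self._design_cache) > 4096:
            self._design_cache.clear()
        return designs

    def force_loss_and_grads(self, frame: CGFrame, target: np.ndarray):
        """Exact loss and coefficient gradients (energy linear in coefs)."""
        n = frame.n_beads
        target = np.asarray(target)
        designs = self._designs(frame)
        pred = np.zeros((n, 3))
        for key, G in zip(self._keys, designs):
            pred += np.einsum("b,bnd->nd", self.coefficients[key], G)
        resid = target - pred
        loss = float(np.sum(resid**2)) / (3 * n)
        grads = [-2.0 / (3 * n) * np.einsum("nd,bnd->b", resid, G) for G in designs]
        return loss, grads

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "kind": self.kind,
            "config": asdict(self.config),
            "keys": [list(k) for k in self._keys],
            "exclusions": sorted(list(p) for p in self.exclusions),
        }
        arrays = {f"coef_{i}": self.coefficients[k] for i, k in enumerate(self._keys)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SplinePairPotential":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            coefs = {
                tuple(k): data[f"coef_{i}"] for i, k in enumerate(meta["keys"])
            }
        return cls(
            SplinePairPotentialConfig(**meta["config"]),
            coefficients=coefs,
            exclusions={tuple(p) for p in meta["exclusions"]},
        )


def total_force_field(frame: CGFrame, topo: CGTopology, prior, model) -> np.ndarray:
    """Combined force field: prior forces + trained-model forces."""
    from cglipid.priors import evaluate_prior

    if prior is not None:
        _, f_prior = evaluate_prior(frame, topo, prior)
    else:
        f_prior = np.zeros_like(frame.coordinates)
    if model is None:
        return f_prior
    _, f_model = model.energy_and_forces(frame)
    return f_prior + f_model


def load_potential(path):
    """Load a checkpoint, dispatching on the recorded model kind."""
    with np.load(path, allow_pickle=False) as data:
        kind = json.loads(str(data["meta"]))["kind"]
    return {"graph": GraphPotential, "spline": SplinePairPotential}[kind].load(path)
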