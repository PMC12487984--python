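"""Trainable potentials: neighbor search, invariances, exact gradients,
cutoff smoothness, and checkpoint round trips."""

import numpy as np
import pytest

from cglipid.mapping import CGFrame
from cglipid.potential import (
    GeometryError,
    GraphPotential,
    GraphPotentialConfig,
    SplinePairPotential,
    SplinePairPotentialConfig,
    VocabularyError,
    load_potential,
    neighbor_pairs,
    total_force_field,
)


def _frame(coords, types, box):
    coords = np.asarray(coords, float)
    return CGFrame(
        coordinates=coords,
        forces=None,
        bead_types=np.asarray(types, dtype=np.intp),
        lipid_index=np.zeros(len(coords), dtype=np.intp),
        box=np.asarray(box, float),
    )


def _random_frame(rng, n=20, box_edge=14.0, n_types=3):
    # jittered grid: no two beads closer than ~1.5 A
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for i in range(n):
        g = np.array([i % side, (i // side) % side, i // side**2])
        pts.append((g + 0.5) * (box_edge / side) + rng.uniform(-0.8, 0.8, 3))
    types = rng.integers(0, n_types, n)
    return _frame(np.array(pts), types, [box_edge] * 3)


# -- neighbor search -------------------------------------------------------


def test_neighbor_pairs_wraps_across_boundary():
    pairs, _, d = neighbor_pairs(np.array([[0.0, 0, 0], [9.0, 0, 0]]), np.array([10.0] * 3), 2.0)
    assert pairs.tolist() == [[0, 1]]
    assert d[0] == pytest.approx(1.0)


def test_neighbor_pairs_empty_when_cutoff_tiny(rng):
    coords = rng.uniform(0, 10, (8, 3))
    # enforce min separation by spreading on a grid
    coords = np.array([[i * 2.0, 0, 0] for i in range(5)])
    pairs, _, _ = neighbor_pairs(coords, np.array([100.0] * 3), 0.1)
    assert len(pairs) == 0


def test_neighbor_pairs_matches_all_pairs_oracle(rng):
    coords = rng.uniform(0, 12, (50, 3))
    box = np.array([12.0] * 3)
    cutoff = 4.0
    pairs, _, d = neighbor_pairs(coords, box, cutoff)
    got = {tuple(p) for p in pairs.tolist()}
    expected = set()
    for i in range(50):
        for j in range(i + 1, 50):
            disp = coords[j] - coords[i]
            disp -= box * np.round(disp / box)
            if np.linalg.norm(disp) < cutoff:
                expected.add((i, j))
    assert got == expected


def test_cutoff_beyond_half_box_raises():
    with pytest.raises(GeometryError):
        neighbor_pairs(np.zeros((2, 3)), np.array([10.0] * 3), 6.0)


# -- graph potential -------------------------------------------------------


@pytest.fixture(scope="module")
def graph_model():
    cfg = GraphPotentialConfig(
        n_interaction_layers=2,
        embedding_width=16,
        n_radial_basis=8,
        cutoff=5.0,
        head_width=8,
        n_types=3,
        seed=42,
    )
    return GraphPotential(cfg)


def test_graph_translation_invariance(graph_model, rng):
    f1 = _random_frame(rng, n=20)
    e1, g1 = graph_model.energy_and_forces(f1)
    f2 = _frame(f1.coordinates + [1.3, -0.4, 2.0], f1.bead_types, f1.box)
    e2, g2 = graph_model.energy_and_forces(f2)
    assert e2 == pytest.approx(e1, rel=1e-10)
    assert np.allclose(g2, g1, atol=1e-9)


def test_graph_permutation_invariance_same_type(graph_model, rng):
    f1 = _random_frame(rng, n=20)
    types = f1.bead_types.copy()
    same = np.nonzero(types == types[0])[0]
    assert len(same) >= 2
    i, j = same[0], same[1]
    coords = f1.coordinates.copy()
    coords[[i, j]] = coords[[j, i]]
    e1, _ = graph_model.energy_and_forces(f1)
    e2, _ = graph_model.energy_and_forces(_frame(coords, types, f1.box))
    assert e2 == pytest.approx(e1, rel=1e-10)


def _fd_force_check(model, frame, rng, n_checks=20, eps=1e-5, tol=1e-4):
    e0, forces = model.energy_and_forces(frame)
    scale = max(np.abs(forces).max(), 1e-10)
    for idx in rng.choice(frame.coordinates.size, n_checks, replace=False):
        xp = frame.coordinates.copy()
        xm = frame.coordinates.copy()
        xp.ravel()[idx] += eps
        xm.ravel()[idx] -= eps
        ep, _ = model.energy_and_forces(_frame(xp, frame.bead_types, frame.box))
        em, _ = model.energy_and_forces(_frame(xm, frame.bead_types, frame.box))
        num = -(ep - em) / (2 * eps)
        assert abs(num - forces.ravel()[idx]) / scale < tol


def test_graph_forces_match_finite_differences(graph_model, rng):
    _fd_force_check(graph_model, _random_frame(rng, n=20), rng)


def test_graph_unknown_type_raises(graph_model, rng):
    f = _random_frame(rng, n=8)
    f.bead_types[0] = 7
    with pytest.raises(VocabularyError):
        graph_model.energy_and_forces(f)


def test_graph_energy_continuous_at_cutoff(graph_model):
    """Sliding one neighbor across the cutoff must not jump the energy
    (the cosine envelope vanishes there)."""
    rc = graph_model.cutoff
    box = [50.0] * 3
    es = []
    for d in (rc - 1e-6, rc + 1e-6):
        f = _frame([[10.0, 10, 10], [10.0 + d, 10, 10]], [0, 1], box)
        es.append(graph_model.energy_and_forces(f)[0])
    assert abs(es[0] - es[1]) < 1e-4


def test_graph_checkpoint_round_trip_bit_stable(graph_model, tmp_path, rng):
    p = tmp_path / "model.npz"
    graph_model.save(p)
    back = load_potential(p)
    assert all(np.array_equal(a, b) for a, b in zip(graph_model.params, back.params))
    f = _random_frame(rng, n=12)
    assert back.energy_and_forces(f)[0] == graph_model.energy_and_forces(f)[0]


# -- spline potential ------------------------------------------------------


@pytest.fixture(scope="module")
def spline_model():
    cfg = SplinePairPotentialConfig(cutoff=6.0, r_min=1.5, n_basis=10, n_types=3)
    rng = np.random.default_rng(5)
    model = SplinePairPotential(cfg)
    for k in model.coefficients:
        model.coefficients[k][:] = rng.normal(0, 0.5, model.n_coef)
    return model


def test_spline_forces_match_finite_differences(spline_model, rng):
    _fd_force_check(spline_model, _random_frame(rng, n=24), rng)


def test_spline_zero_coefficients_zero_energy(rng):
    model = SplinePairPotential(SplinePairPotentialConfig(cutoff=6.0, n_types=3))
    f = _random_frame(rng, n=10)
    e, forces = model.energy_and_forces(f)
    assert e == 0.0
    assert np.allclose(forces, 0.0)


def test_spline_energy_vanishes_at_cutoff(spline_model):
    rc = spline_model.cutoff
    f = _frame([[10.0, 10, 10], [10.0 + rc - 1e-9, 10, 10]], [0, 0], [40.0] * 3)
    e, _ = spline_model.energy_and_forces(f)
    assert abs(e) < 1e-6


def test_spline_reproduces_tabulated_pair_potential():
    """Least-squares-fit coefficients must reproduce a smooth tabulated
    potential over the fit range within a few percent RMS."""
    cfg = SplinePairPotentialConfig(cutoff=8.0, r_min=2.0, n_basis=14, n_types=1)
    model = SplinePairPotential(cfg)
    r = np.linspace(2.2, 7.8, 300)
    env = 0.5 * (np.cos(np.pi * r / cfg.cutoff) + 1.0)
    target = env * (np.exp(-((r - 4.0) ** 2)) - 0.3 * np.exp(-((r - 6.0) ** 2)))
    Phi, _ = model._basis(r)
    coef, *_ = np.linalg.lstsq(Phi, target, rcond=None)
    model.coefficients[(0, 0)][:] = coef
    fitted = Phi @ coef
    rms = np.sqrt(np.mean((fitted - target) ** 2))
    assert rms / np.sqrt(np.mean(target**2)) < 0.05


def test_spline_checkpoint_round_trip_bit_stable(spline_model, tmp_path, rng):
    p = tmp_path / "spline.npz"
    spline_model.save(p)
    back = load_potential(p)
    for k in spline_model.coefficients:
        assert np.array_equal(spline_model.coefficients[k], back.coefficients[k])
    f = _random_frame(rng, n=12)
    assert back.energy_and_forces(f)[0] == spline_model.energy_and_forces(f)[0]


# -- combined force field --------------------------------------------------


def test_total_force_field_is_componentwise_sum(bilayer_data, spline_model):
    from cglipid.priors import fit_prior_forcefield, evaluate_prior

    topo = bilayer_data.topology
    frames = bilayer_data.frames
    prior = fit_prior_forcefield(frames[:10], topo, 300.0, cutoff=9.0)
    model = SplinePairPotential(
        SplinePairPotentialConfig(cutoff=9.0, r_min=2.0, n_basis=8, n_types=4)
    )
    rng = np.random.default_rng(0)
    for k in model.coefficients:
        model.coefficients[k][:] = rng.normal(0, 0.2, model.n_coef)
    frame = frames[0]
    combined = total_force_field(frame, topo, prior, model)
    _, f_prior = evaluate_prior(frame, topo, prior)
    _, f_model = model.energy_and_forces(frame)
    assert np.allclose(combined, f_prior + f_model, rtol=0, atol=1e-12)
    # zero-parameter model contributes nothing
    zero = SplinePairPotential(SplinePairPotentialConfig(cutoff=9.0, n_types=4))
    assert np.allclose(total_force_field(frame, topo, prior, zero), f_prior)
    # no prior: model alone
    assert np.allclose(total_force_field(frame, topo, None, model), f_model)
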