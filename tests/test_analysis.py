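"""Membrane observables against closed-form and brute-force oracles."""

import numpy as np
import pytest

from cglipid.analysis import (
    AnalysisError,
    bonds_by_label,
    compute_msd,
    compute_order_parameter,
    compute_rdf,
    compute_thickness,
    compute_zdensity,
)
from cglipid.geometry import minimum_image
from cglipid.simulate import Trajectory


def _traj(coords, box, time_per_frame=1000.0):
    coords = np.asarray(coords, float)
    n = coords.shape[1]
    return Trajectory(
        coordinates=coords,
        box=np.asarray(box, float),
        bead_types=np.zeros(n, dtype=np.intp),
        lipid_index=np.arange(n),
        time_per_frame=time_per_frame,
    )


# -- RDF -------------------------------------------------------------------


def test_rdf_two_fixed_particles_single_bin():
    d = 3.3
    traj = _traj([[[0, 0, 0], [d, 0, 0]]], [20.0] * 3)
    res = compute_rdf(traj, np.array([0, 1]), np.array([0, 1]), r_max=8.0, n_bins=40)
    nonzero = np.nonzero(res.g)[0]
    assert len(nonzero) == 1
    lo = res.bin_centers[nonzero[0]] - 0.1
    hi = res.bin_centers[nonzero[0]] + 0.1
    assert lo <= d <= hi


def test_rdf_matches_brute_force_loop_exactly(rng):
    coords = rng.uniform(0, 15, (1, 60, 3))
    box = np.array([15.0] * 3)
    traj = _traj(coords, box)
    sel = np.arange(60)
    n_bins, r_max = 30, 7.0
    res = compute_rdf(traj, sel, sel, r_max=r_max, n_bins=n_bins)
    # explicit-loop histogram with identical normalization
    counts = np.zeros(n_bins)
    edges = np.linspace(0, r_max, n_bins + 1)
    for i in range(60):
        for j in range(i + 1, 60):
            disp = coords[0, j] - coords[0, i]
            disp -= box * np.round(disp / box)
            r = np.linalg.norm(disp)
            if r < r_max:
                b = np.searchsorted(edges, r, side="right") - 1
                counts[b] += 1
    shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = (60 * 59 / 2) * shell / box.prod()
    assert np.allclose(res.g, counts / ideal, rtol=0, atol=1e-12)


def test_rdf_of_ideal_gas_is_unity_within_poisson_error(rng):
    n, n_frames = 200, 25
    box = np.array([30.0] * 3)
    coords = rng.uniform(0, 30, (n_frames, n, 3))
    traj = _traj(coords, box)
    sel = np.arange(n)
    res = compute_rdf(traj, sel, sel, r_max=12.0, n_bins=40)
    edges = np.linspace(0, 12.0, 41)
    shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = (n * (n - 1) / 2) * shell / box.prod() * n_frames
    se = 1.0 / np.sqrt(expected)  # Poisson relative error on each bin
    mask = res.bin_centers > 2.0
    assert np.all(np.abs(res.g[mask] - 1.0) < 3 * se[mask] + 0.02)


def test_rdf_rejects_r_max_beyond_half_box(rng):
    traj = _traj(rng.uniform(0, 10, (1, 10, 3)), [10.0] * 3)
    with pytest.raises(AnalysisError):
        compute_rdf(traj, np.arange(10), np.arange(10), r_max=6.0)


# -- z-density -------------------------------------------------------------


def test_zdensity_point_mass_single_peak_unit_integral():
    coords = np.zeros((1, 10, 3))
    coords[0, :, 2] = 17.0  # all beads at the same z; midplane = 17
    traj = _traj(coords, [40.0] * 3)
    res = compute_zdensity(traj, np.arange(10), n_bins=50)
    assert np.count_nonzero(res.density) == 1
    assert res.integral() == pytest.approx(1.0)


def test_zdensity_recovers_gaussian_parameters(rng):
    n, n_frames, mu, sigma = 400, 10, 20.0, 3.0
    coords = np.zeros((n_frames, 2 * n, 3))
    # symmetric bilayer-like profile so the midplane stays at the center
    coords[:, :n, 2] = rng.normal(mu, sigma, (n_frames, n))
    coords[:, n:, 2] = rng.normal(-mu, sigma, (n_frames, n))
    traj = _traj(coords, [60.0, 60.0, 120.0])
    res = compute_zdensity(traj, np.arange(n), n_bins=200)
    dz = res.bin_centers[1] - res.bin_centers[0]
    mean = np.sum(res.bin_centers * res.density) * dz
    var = np.sum((res.bin_centers - mean) ** 2 * res.density) * dz
    assert res.integral() == pytest.approx(1.0)
    assert abs(mean - mu) < 0.5
    assert abs(np.sqrt(var) - sigma) / sigma < 0.10


def test_zdensity_empty_selection_raises():
    traj = _traj(np.zeros((1, 4, 3)), [10.0] * 3)
    with pytest.raises(AnalysisError):
        compute_zdensity(traj, np.array([], dtype=int))


# -- thickness -------------------------------------------------------------


def _flat_bilayer(nx=8, ny=8, z=20.0, cell=10.0):
    xs = (np.arange(nx) + 0.5) * cell
    ys = (np.arange(ny) + 0.5) * cell
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    upper = np.column_stack([X.ravel(), Y.ravel(), np.full(nx * ny, z)])
    lower = np.column_stack([X.ravel(), Y.ravel(), np.full(nx * ny, -z)])
    return np.concatenate([upper, lower])


def test_thickness_flat_leaflets_is_exact():
    pts = _flat_bilayer(z=20.0)
    traj = _traj(pts[None], [80.0, 80.0, 100.0])
    res = compute_thickness(traj, np.arange(len(pts)), cell_size=10.0)
    assert res.mean_thickness == pytest.approx(40.0)
    assert np.allclose(res.thickness[res.occupied], 40.0)


def test_thickness_translation_invariance():
    pts = _flat_bilayer(z=18.0)
    t1 = _traj(pts[None], [80.0, 80.0, 100.0])
    t2 = _traj((pts + [0.0, 0.0, 13.0])[None], [80.0, 80.0, 100.0])
    r1 = compute_thickness(t1, np.arange(len(pts)))
    r2 = compute_thickness(t2, np.arange(len(pts)))
    assert r2.mean_thickness == pytest.approx(r1.mean_thickness)


def test_thickness_sinusoidal_corrugation_matches_cell_average():
    """Upper leaflet z = z0 + A sin(2 pi x / Lx) sampled densely: each cell
    value must equal the analytic mean of the surface over the cell."""
    Lx, Ly, cell = 80.0, 20.0, 10.0
    A, z0 = 3.0, 20.0
    xs = np.linspace(0, Lx, 800, endpoint=False) + Lx / 1600
    ys = np.array([5.0, 15.0])
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    zu = z0 + A * np.sin(2 * np.pi * X / Lx)
    upper = np.column_stack([X.ravel(), Y.ravel(), zu.ravel()])
    lower = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, -z0)])
    pts = np.concatenate([upper, lower])
    traj = _traj(pts[None], [Lx, Ly, 120.0])
    res = compute_thickness(traj, np.arange(len(pts)), cell_size=cell)
    # analytic cell mean of the corrugated sheet (mean z of lower leaflet
    # shifts the midplane, so compare thickness = upper - lower directly)
    k = 2 * np.pi / Lx
    for ix in range(int(Lx / cell)):
        a, b = ix * cell, (ix + 1) * cell
        mean_sin = (np.cos(k * a) - np.cos(k * b)) / (k * (b - a))
        expected = 2 * z0 + A * mean_sin
        got = res.thickness[ix][res.occupied[ix]]
        assert np.allclose(got, expected, atol=0.02)


def test_thickness_masks_cells_missing_a_leaflet():
    pts = _flat_bilayer(nx=2, ny=2, z=15.0)
    # one lone upper bead far away in its own cell: occupied mask must
    # exclude that cell, and the scalar must ignore it
    lone = np.array([[75.0, 75.0, 15.0]])
    traj = _traj(np.concatenate([pts, lone])[None], [80.0, 80.0, 100.0])
    res = compute_thickness(traj, np.arange(len(pts) + 1), cell_size=10.0)
    assert not res.occupied[7, 7]
    assert res.mean_thickness == pytest.approx(30.0)


def test_thickness_empty_leaflet_raises():
    pts = _flat_bilayer(z=15.0)[: 64]  # upper leaflet only
    traj = _traj(pts[None], [80.0, 80.0, 100.0])
    with pytest.raises(AnalysisError):
        compute_thickness(traj, np.arange(len(pts)))


# -- order parameter -------------------------------------------------------


def _bond_traj(vectors, box=200.0):
    vectors = np.asarray(vectors, float)
    n = len(vectors)
    coords = np.zeros((1, 2 * n, 3))
    base = np.linspace(20, 180, n)[:, None] * np.array([[1.0, 0.0, 0.0]])
    coords[0, 0::2] = base
    coords[0, 1::2] = base + vectors
    pairs = np.column_stack([np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)])
    return _traj(coords, [box] * 3), pairs


def test_order_parameter_parallel_bonds_is_one():
    traj, pairs = _bond_traj([[0, 0, 3.0]] * 10)
    assert compute_order_parameter(traj, pairs).S == pytest.approx(1.0)


def test_order_parameter_in_plane_bonds_is_minus_half(rng):
    ang = rng.uniform(0, 2 * np.pi, 50)
    vecs = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(50)]) * 3.0
    traj, pairs = _bond_traj(vecs)
    assert compute_order_parameter(traj, pairs).S == pytest.approx(-0.5)


def test_order_parameter_magic_angle_is_zero():
    cos_th = np.sqrt(1 / 3)
    sin_th = np.sqrt(2 / 3)
    traj, pairs = _bond_traj([[3 * sin_th, 0.0, 3 * cos_th]] * 5)
    assert compute_order_parameter(traj, pairs).S == pytest.approx(0.0, abs=1e-12)


def test_order_parameter_isotropic_orientations_average_to_zero(rng):
    n = 100_000
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    cos2 = v[:, 2] ** 2
    S = np.mean(0.5 * (3 * cos2 - 1))
    assert abs(S) < 3 * np.sqrt(1 / (5 * n))
    # the estimator itself agrees on the same vectors
    traj, pairs = _bond_traj(v[:500] * 3.0)
    got = compute_order_parameter(traj, pairs).S
    ref = np.mean(0.5 * (3 * cos2[:500] - 1))
    assert got == pytest.approx(ref)


def test_order_parameter_bounded(rng):
    v = rng.normal(size=(300, 3)) * 2.0
    traj, pairs = _bond_traj(v)
    S = compute_order_parameter(traj, pairs).S
    assert -0.5 <= S <= 1.0


def test_order_parameter_zero_length_bond_raises():
    traj, pairs = _bond_traj([[0.0, 0.0, 0.0]])
    with pytest.raises(AnalysisError):
        compute_order_parameter(traj, pairs)


def test_bonds_by_label_selects_tail_bonds(bilayer_data):
    topo = bilayer_data.topology
    tt = bonds_by_label(topo, "T1-T2")
    assert len(tt) == 2 * 16  # two tail bonds per lipid


# -- MSD -------------------------------------------------------------------


def test_msd_stationary_beads_is_zero():
    traj = _traj(np.zeros((20, 5, 3)), [100.0] * 3)
    res = compute_msd(traj, np.arange(5))
    assert np.allclose(res.msd, 0.0)
    assert res.D == pytest.approx(0.0)


def test_msd_ballistic_drift_is_quadratic():
    v = 0.003  # A/fs
    dt = 500.0
    T = 30
    coords = np.zeros((T, 3, 3))
    coords[:, :, 0] = v * dt * np.arange(T)[:, None]
    traj = _traj(coords, [1e6] * 3, time_per_frame=dt)
    res = compute_msd(traj, np.arange(3), max_lag=10)
    expected = (v * res.lag_times) ** 2
    assert np.allclose(res.msd, expected, rtol=1e-10)


def test_msd_random_walk_recovers_diffusion_constant(rng):
    sigma, dt = 0.8, 1000.0
    steps = rng.normal(0, sigma, (400, 100, 2))
    xy = np.cumsum(steps, axis=0)
    coords = np.zeros((400, 100, 3))
    coords[:, :, :2] = xy
    traj = _traj(coords, [1e6] * 3, time_per_frame=dt)
    res = compute_msd(traj, np.arange(100), max_lag=100)
    D_expected = sigma**2 / (2 * dt)
    assert res.D == pytest.approx(D_expected, rel=0.10)


def test_msd_equals_explicit_double_loop(rng):
    coords = np.cumsum(rng.normal(0, 0.5, (12, 4, 3)), axis=0)
    traj = _traj(coords, [1e6] * 3, time_per_frame=100.0)
    res = compute_msd(traj, np.arange(4), max_lag=8)
    for lag in range(1, 9):
        acc, cnt = 0.0, 0
        for t0 in range(12 - lag):
            for b in range(4):
                d = coords[t0 + lag, b, :2] - coords[t0, b, :2]
                acc += d @ d
                cnt += 1
        assert res.msd[lag] == pytest.approx(acc / cnt)


def test_msd_detects_wrapped_coordinates():
    coords = np.zeros((3, 2, 3))
    coords[1, 0, 0] = 9.0  # jump of 9 A in a 10 A box
    traj = _traj(coords, [10.0] * 3)
    with pytest.raises(AnalysisError, match="unwrap"):
        compute_msd(traj, np.arange(2))
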