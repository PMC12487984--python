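"""Membrane observables from CG (or mapped atomistic) trajectories.

Implements the standard bilayer analysis set: radial distribution
functions, area-normalized z-density profiles, grid-based membrane
thickness from headgroup beads, orientational order parameters from the
second-order Legendre polynomial, and lateral mean square displacement with
the diffusion constant taken as one quarter of its slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cglipid.geometry import minimum_image
from cglipid.simulate import Trajectory

__all__ = [
    "RDFResult",
    "DensityProfile",
    "ThicknessMap",
    "OrderParams",
    "MSDResult",
    "AnalysisError",
    "compute_rdf",
    "compute_zdensity",
    "compute_thickness",
    "compute_order_parameter",
    "compute_msd",
    "bonds_by_label",
]


class AnalysisError(ValueError):
    pass


@dataclass
class RDFResult:
    bin_centers: np.ndarray
    g: np.ndarray
    selection_a: str
    selection_b: str
    n_frames: int

    @property
    def first_peak(self) -> float:
        """Position of the global maximum of g(r) (A)."""
        return float(self.bin_centers[np.argmax(self.g)])


@dataclass
class DensityProfile:
    bin_centers: np.ndarray
    density: np.ndarray  # 1/A, integrates to 1 over z

    def integral(self) -> float:
        dz = self.bin_centers[1] - self.bin_centers[0]
        return float(np.sum(self.density) * dz)


@dataclass
class ThicknessMap:
    thickness: np.ndarray  # (nx, ny) cell-averaged HG-HG distance, A
    occupied: np.ndarray  # (nx, ny) bool
    cell_size: float
    mean_thickness: float  # occupancy-weighted scalar, A


@dataclass
class OrderParams:
    S: float
    stderr: float
    per_frame: np.ndarray


@dataclass
class MSDResult:
    lag_times: np.ndarray  # fs
    msd: np.ndarray  # A^2
    D: float  # A^2/fs
    D_stderr: float
    fit_window: tuple[int, int]


# -------------------------------------------------------------------------


def compute_rdf(
    traj: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    r_max: float,
    n_bins: int = 100,
    labels: tuple[str, str] = ("A", "B"),
) -> RDFResult:
    """Shell-normalized pair histogram g(r) under the minimum image.

    For identical selections, each unordered pair is counted once and the
    ideal-gas reference is n(n-1)/2 pairs homogeneously distributed in the
    box; for disjoint selections it is n_a*n_b pairs.
    """
    box = traj.box
    if r_max > box.min() / 2:
        raise AnalysisError(f"r_max {r_max} exceeds half the smallest box edge")
    sel_a = np.asarray(selection_a, dtype=np.intp)
    sel_b = np.asarray(selection_b, dtype=np.intp)
    same = np.array_equal(sel_a, sel_b)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    for fi in range(traj.n_frames):
        xa = traj.coordinates[fi, sel_a]
        xb = traj.coordinates[fi, sel_b]
        if same:
            ii, jj = np.triu_indices(len(sel_a), k=1)
            d = np.linalg.norm(minimum_image(xa[jj] - xa[ii], box), axis=1)
        else:
            disp = xb[None, :, :] - xa[:, None, :]
            d = np.linalg.norm(minimum_image(disp.reshape(-1, 3), box), axis=1)
        counts += np.histogram(d, bins=edges)[0]
    volume = float(np.prod(box))
    n_pairs = len(sel_a) * (len(sel_a) - 1) / 2 if same else len(sel_a) * len(sel_b)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / volume * traj.n_frames
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(centers, g, labels[0], labels[1], traj.n_frames)


def compute_zdensity(
    traj: Trajectory, selection: np.ndarray, n_bins: int = 100, z_range: float | None = None
) -> DensityProfile:
    """Area-normalized z-density: each frame is recentered so the mean z of
    all beads (the bilayer midplane) sits at z = 0; the profile integrates
    to 1 over z."""
    sel = np.asarray(selection, dtype=np.intp)
    if sel.size == 0:
        raise AnalysisError("empty selection")
    half = z_range if z_range is not None else traj.box[2] / 2
    edges = np.linspace(-half, half, n_bins + 1)
    counts = np.zeros(n_bins)
    for fi in range(traj.n_frames):
        z = traj.coordinates[fi, :, 2]
        zc = z[sel] - z.mean()
        counts += np.histogram(zc, bins=edges)[0]
    dz = edges[1] - edges[0]
    total = counts.sum()
    if total == 0:
        raise AnalysisError("no beads fall inside the z range")
    density = counts / (total * dz)
    return DensityProfile(0.5 * (edges[1:] + edges[:-1]), density)


def compute_thickness(
    traj: Trajectory, hg_selection: np.ndarray, cell_size: float = 10.0
) -> ThicknessMap:
    """Bilayer thickness map: per 10x10 A (by default) xy cell, the mean z
    of upper-leaflet HG beads minus the mean z of lower-leaflet HG beads.

    Leaflets are assigned by the sign of z relative to the per-frame
    midplane (mean z over all beads).  Cells missing either leaflet are
    masked, never imputed; the scalar thickness is the occupancy-weighted
    mean over occupied cells and frames.
    """
    sel = np.asarray(hg_selection, dtype=np.intp)
    box = traj.box
    nx = max(1, int(np.floor(box[0] / cell_size)))
    ny = max(1, int(np.floor(box[1] / cell_size)))
    up_sum = np.zeros((nx, ny))
    up_n = np.zeros((nx, ny))
    lo_sum = np.zeros((nx, ny))
    lo_n = np.zeros((nx, ny))
    thick_sum, thick_n = 0.0, 0
    cell_thick_sum = np.zeros((nx, ny))
    cell_thick_n = np.zeros((nx, ny))
    for fi in range(traj.n_frames):
        z_all = traj.coordinates[fi, :, 2]
        mid = z_all.mean()
        xy = np.mod(traj.coordinates[fi, sel, :2], box[:2])
        cx = np.minimum((xy[:, 0] / (box[0] / nx)).astype(int), nx - 1)
        cy = np.minimum((xy[:, 1] / (box[1] / ny)).astype(int), ny - 1)
        z = z_all[sel] - mid
        upper = z >= 0
        if not upper.any() or upper.all():
            raise AnalysisError("one leaflet is empty; cannot assign leaflets")
        fu_sum = np.zeros((nx, ny))
        fu_n = np.zeros((nx, ny))
        fl_sum = np.zeros((nx, ny))
        fl_n = np.zeros((nx, ny))
        np.add.at(fu_sum, (cx[upper], cy[upper]), z[upper])
        np.add.at(fu_n, (cx[upper], cy[upper]), 1)
        np.add.at(fl_sum, (cx[~upper], cy[~upper]), z[~upper])
        np.add.at(fl_n, (cx[~upper], cy[~upper]), 1)
        occ = (fu_n > 0) & (fl_n > 0)
        with np.errstate(invalid="ignore"):
            t = fu_sum / fu_n - fl_sum / fl_n
        cell_thick_sum[occ] += t[occ]
        cell_thick_n[occ] += 1
        thick_sum += float(t[occ].sum())
        thick_n += int(occ.sum())
    occupied = cell_thick_n > 0
    with np.errstate(invalid="ignore"):
        tmap = np.where(occupied, cell_thick_sum / np.maximum(cell_thick_n, 1), np.nan)
    if thick_n == 0:
        raise AnalysisError("no xy cell contains both leaflets")
    return ThicknessMap(tmap, occupied, cell_size, thick_sum / thick_n)


def bonds_by_label(topo, label: str) -> np.ndarray:
    """Bond index pairs of a given bond-type label (e.g. 'T1-T2')."""
    mask = np.array([lab == label for lab in topo.bond_type_labels])
    return topo.bond_pairs[mask]


def compute_order_parameter(
    traj: Trajectory, bond_pairs: np.ndarray, normal_axis: int = 2
) -> OrderParams:
    """Orientational order parameter S = <(3 cos^2 theta - 1)/2> with theta
    the angle between each bond vector and the membrane normal (box z-axis
    by default).  S = 1 for bonds parallel to the normal, -0.5 for in-plane
    bonds, 0 at the magic angle and for isotropic orientations."""
    bond_pairs = np.asarray(bond_pairs, dtype=np.intp).reshape(-1, 2)
    per_frame = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        x = traj.coordinates[fi]
        vec = minimum_image(x[bond_pairs[:, 1]] - x[bond_pairs[:, 0]], traj.box)
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise AnalysisError("zero-length bond vector")
        cos2 = (vec[:, normal_axis] / norm) ** 2
        per_frame[fi] = np.mean(0.5 * (3.0 * cos2 - 1.0))
    S = float(per_frame.mean())
    stderr = float(per_frame.std(ddof=1) / np.sqrt(len(per_frame))) if len(per_frame) > 1 else 0.0
    return OrderParams(S=S, stderr=stderr, per_frame=per_frame)


def compute_msd(
    traj: Trajectory,
    selection: np.ndarray,
    max_lag: int | None = None,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> MSDResult:
    """Lateral (xy) mean square displacement averaged over all time origins
    and selected beads, and the diffusion constant D = slope/4 from a
    least-squares fit over ``fit_window`` (fractions of max lag).

    Coordinates must be unwrapped; a jump larger than half a box edge
    between consecutive frames raises an error.
    """
    sel = np.asarray(selection, dtype=np.intp)
    xy = traj.coordinates[:, sel, :2]
    jumps = np.abs(np.diff(xy, axis=0))
    if jumps.size and np.any(jumps > traj.box[:2] / 2):
        raise AnalysisError(
            "frame-to-frame displacement exceeds half a box edge; "
            "coordinates appear wrapped - unwrap before computing MSD"
        )
    T = traj.n_frames
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)
    msd = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        disp = xy[lag:] - xy[:-lag]
        msd[lag] = np.mean(np.sum(disp**2, axis=2))
    lags = np.arange(max_lag + 1) * traj.time_per_frame
    lo = max(1, int(np.floor(fit_window[0] * max_lag)))
    hi = max(lo + 2, int(np.ceil(fit_window[1] * max_lag)) + 1)
    hi = min(hi, max_lag + 1)
    t_fit, y_fit = lags[lo:hi], msd[lo:hi]
    A = np.column_stack([t_fit, np.ones_like(t_fit)])
    coef, res, *_ = np.linalg.lstsq(A, y_fit, rcond=None)
    slope = float(coef[0])
    dof = len(t_fit) - 2
    if dof > 0 and len(res):
        s2 = float(res[0]) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        slope_se = float(np.sqrt(cov[0, 0]))
    else:
        slope_se = 0.0
    return MSDResult(
        lag_times=lags,
        msd=msd,
        D=slope / 4.0,
        D_stderr=slope_se / 4.0,
        fit_window=(lo, hi - 1),
    )
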