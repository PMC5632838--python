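"""Shared variational solver machinery for the two registration engines.

Both engines minimise an energy of the form

    E(u) = D(fixed, moving o (id + u)) + alpha * sum_r ||grad u(r)||^2

over dense displacement fields u (mm).  The data term D differs: an L1
intensity difference for the mono-modal engine (handled by iteratively
reweighted least squares with a Charbonnier smoothing of |.|), and a
squared descriptor dissimilarity for the multi-modal engine (handled by
Gauss-Newton).  Both reduce, per outer iteration, to the weighted
least-squares problem

    sum_c w_c (rho_c + g_c . du)^2 + alpha ||grad(u + du)||^2

which is solved with vectorised Jacobi sweeps (per-voxel (A + a*k*I) x = b
systems, closed-form 2x2/3x3 inverses).  Every outer iteration ends with a
backtracking step on the *true* energy, which makes the recorded energy
trace non-increasing within each pyramid level by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .geometry import DeformationField, GeomImage, resample_to_geometry

Channels = np.ndarray  # shape (C, *grid_shape)


# ---------------------------------------------------------------------------
# pyramid construction
# ---------------------------------------------------------------------------


def _coarse_geometry(img: GeomImage) -> tuple[np.ndarray, tuple]:
    """Halve the grid, keeping first and last voxel centres fixed in world."""
    new_shape = tuple(max(int(np.ceil(n / 2)), 2) for n in img.shape)
    aff = img.affine.copy()
    for a, (n_old, n_new) in enumerate(zip(img.shape, new_shape)):
        f = (n_old - 1) / (n_new - 1) if n_new > 1 else 1.0
        aff[:3, a] *= f
    return aff, new_shape


def build_pyramid(img: GeomImage, levels: int, min_size: int = 6) -> list[GeomImage]:
    """Gaussian pyramid, finest first.  Stops early if grids get too small."""
    pyr = [img]
    current = img
    for _ in range(levels - 1):
        if min(current.shape) < 2 * min_size:
            break
        smoothed = GeomImage(
            ndimage.gaussian_filter(current.data, sigma=1.0, mode="nearest"),
            current.affine,
        )
        aff, shape = _coarse_geometry(current)
        current = resample_to_geometry(smoothed, aff, shape)
        pyr.append(current)
    return pyr


def upsample_field(fld: DeformationField, target: GeomImage) -> DeformationField:
    """Resample a displacement field onto a finer grid.

    Components are in mm, so no magnitude rescaling is needed.
    """
    world = target.index_to_world(target.index_grid())
    vecs = fld.sample_at_world(world, mode="nearest")
    return DeformationField(vecs, target)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


def gradient_energy(vectors: np.ndarray, spacing: np.ndarray) -> float:
    """sum_r ||grad u(r)||_2^2 with central differences, gradients per mm."""
    total = 0.0
    d = vectors.shape[-1]
    for c in range(d):
        comp = vectors[..., c]
        for a in range(d):
            if comp.shape[a] < 2:
                continue
            g = np.gradient(comp, spacing[a], axis=a)
            total += float(np.sum(g * g))
    return total


def warp_channels_of(
    data: np.ndarray, geom: GeomImage, vectors: np.ndarray
) -> np.ndarray:
    """Pull-back sample of a scalar image at r + u(r), replicate boundary."""
    idx = geom.index_grid()
    coords = np.moveaxis(idx + vectors / geom.voxel_size_mm, -1, 0)
    return ndimage.map_coordinates(data, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# per-level weighted least squares
# ---------------------------------------------------------------------------


def _neighbor_sum(v: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """sum_a (v_plus + v_minus)/h_a^2 with replicated edges (Neumann)."""
    out = np.zeros_like(v)
    d = v.ndim - 1  # trailing axis is the component axis
    for a in range(d):
        h2 = spacing[a] ** 2
        sl_p = [slice(None)] * v.ndim
        sl_m = [slice(None)] * v.ndim
        sl_p[a] = slice(1, None)
        sl_m[a] = slice(0, -1)
        vp = np.concatenate([v[tuple(sl_p)], v.take([-1], axis=a)], axis=a)
        vm = np.concatenate([v.take([0], axis=a), v[tuple(sl_m)]], axis=a)
        out += (vp + vm) / h2
    return out


def _solve_spd(A: np.ndarray, rhs: np.ndarray, d: int) -> np.ndarray:
    """Closed-form solve of per-voxel symmetric d x d systems.

    A has shape (d, d, *grid), rhs (*grid, d); returns (*grid, d).
    """
    if d == 2:
        a, b, c = A[0, 0], A[0, 1], A[1, 1]
        det = a * c - b * b
        x0 = (c * rhs[..., 0] - b * rhs[..., 1]) / det
        x1 = (-b * rhs[..., 0] + a * rhs[..., 1]) / det
        return np.stack([x0, x1], axis=-1)
    a, b, c = A[0, 0], A[0, 1], A[0, 2]
    e, f, i = A[1, 1], A[1, 2], A[2, 2]
    co00 = e * i - f * f
    co01 = c * f - b * i
    co02 = b * f - c * e
    co11 = a * i - c * c
    co12 = b * c - a * f
    co22 = a * e - b * b
    det = a * co00 + b * co01 + c * co02
    r0, r1, r2 = rhs[..., 0], rhs[..., 1], rhs[..., 2]
    x0 = (co00 * r0 + co01 * r1 + co02 * r2) / det
    x1 = (co01 * r0 + co11 * r1 + co12 * r2) / det
    x2 = (co02 * r0 + co12 * r1 + co22 * r2) / det
    return np.stack([x0, x1, x2], axis=-1)


def _level_update(
    fixed_ch: Channels,
    warped_ch: Channels,
    weights: Channels,
    u: np.ndarray,
    alpha: float,
    spacing: np.ndarray,
    n_inner: int,
) -> np.ndarray:
    """One linearisation + Jacobi solve; returns the candidate increment du."""
    d = u.shape[-1]
    grid_shape = u.shape[:-1]
    A = np.zeros((d, d) + grid_shape)
    rhs_data = np.zeros(grid_shape + (d,))
    # accumulate per-channel normal equations
    for c in range(fixed_ch.shape[0]):
        rho = warped_ch[c] - fixed_ch[c]
        gw = np.gradient(warped_ch[c], *spacing)
        gf = np.gradient(fixed_ch[c], *spacing)
        g = [0.5 * (gw[a] + gf[a]) for a in range(d)]
        w = weights[c]
        b = rho - sum(g[a] * u[..., a] for a in range(d))
        for a in range(d):
            rhs_data[..., a] -= w * g[a] * b
            for bx in range(a, d):
                A[a, bx] += w * g[a] * g[bx]
    for a in range(d):
        for bx in range(a):
            A[a, bx] = A[bx, a]
    kappa = float(np.sum(2.0 / spacing[:d] ** 2))
    for a in range(d):
        A[a, a] += alpha * kappa + 1e-12
    v = u.copy()
    for _ in range(n_inner):
        rhs = rhs_data + alpha * _neighbor_sum(v, spacing)
        v = _solve_spd(A, rhs, d)
    return v - u


@dataclass
class LevelTrace:
    energies: list = field(default_factory=list)
    converged: bool = False


@dataclass
class SolveOutcome:
    field: DeformationField
    level_traces: list
    converged: bool


def multires_solve(
    fixed: GeomImage,
    moving: GeomImage,
    *,
    alpha: float,
    levels: int,
    max_iter_per_level: int,
    tol: float,
    n_inner: int,
    channel_fn: Callable[[np.ndarray, GeomImage], Channels],
    data_energy_fn: Callable[[Channels, Channels], float],
    weight_fn: Callable[[Channels, Channels], Channels],
    init: DeformationField | None = None,
) -> SolveOutcome:
    """Coarse-to-fine minimisation shared by both registration engines.

    ``channel_fn`` maps an image (data, geometry) to feature channels (the
    raw intensities for the mono-modal engine, descriptor stacks for the
    multi-modal one); ``data_energy_fn`` evaluates the true data term on
    (fixed channels, warped-moving channels); ``weight_fn`` supplies the
    per-channel IRLS/Gauss-Newton weights from the current residuals.
    """
    fixed_pyr = build_pyramid(fixed, levels)
    moving_pyr = build_pyramid(moving, levels)
    n_levels = min(len(fixed_pyr), len(moving_pyr))
    fixed_pyr, moving_pyr = fixed_pyr[:n_levels], moving_pyr[:n_levels]

    u_field: DeformationField | None = None
    if init is not None:
        u_field = upsample_field(init, fixed_pyr[-1])

    level_traces: list[LevelTrace] = []
    for lvl in range(n_levels - 1, -1, -1):
        f_img, m_img = fixed_pyr[lvl], moving_pyr[lvl]
        spacing = f_img.voxel_size_mm
        if u_field is None:
            u_field = DeformationField.zero(f_img)
        else:
            u_field = upsample_field(u_field, f_img)
        u = u_field.vectors

        fixed_ch = channel_fn(f_img.data, f_img)
        moving_data = m_img.data

        def warped_channels(vecs: np.ndarray) -> Channels:
            warped = warp_channels_of(moving_data, f_img, vecs)
            return channel_fn(warped, f_img)

        def energy(vecs: np.ndarray, wch: Channels | None = None) -> float:
            if wch is None:
                wch = warped_channels(vecs)
            return data_energy_fn(fixed_ch, wch) + alpha * gradient_energy(
                vecs, spacing
            )

        trace = LevelTrace()
        wch = warped_channels(u)
        e_cur = energy(u, wch)
        trace.energies.append(e_cur)
        for _ in range(max_iter_per_level):
            weights = weight_fn(fixed_ch, wch)
            du = _level_update(fixed_ch, wch, weights, u, alpha, spacing, n_inner)
            step = 1.0
            accepted = False
            for _ in range(5):
                cand = u + step * du
                wch_cand = warped_channels(cand)
                e_cand = energy(cand, wch_cand)
                if e_cand <= e_cur:
                    u, wch, e_prev, e_cur = cand, wch_cand, e_cur, e_cand
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            trace.energies.append(e_cur)
            if e_prev > 0 and (e_prev - e_cur) / max(abs(e_prev), 1e-30) < tol:
                trace.converged = True
                break
        level_traces.append(trace)
        u_field = DeformationField(u, f_img)

    return SolveOutcome(
        field=u_field,
        level_traces=level_traces,
        converged=level_traces[-1].converged if level_traces else False,
    )
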