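"""Mono-modal deformable registration (variational optical flow).

The engine minimises, over dense displacement fields u (mm),

    E_OF(u) = sum_r |I(r) - J(r + u(r))| + alpha * ||grad u(r)||_2^2

i.e. an L1 intensity-constancy data term with a first-order quadratic
regulariser.  The L1 term is handled by a Charbonnier smoothing
sqrt(x^2 + eps^2) with iteratively reweighted least squares, inside a
coarse-to-fine pyramid (see :mod:`hifutrack._solver`).  This matches the
functional exactly in the eps -> 0 limit while keeping the scheme
deterministic and derivative based.

Both images are jointly normalised to [0, 1] before solving so that the
regularisation weight alpha transfers across scans with different
intensity scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .geometry import DeformationField, GeomImage, GeometryError


@dataclass
class OFParams:
    """Solver parameters for the optical-flow engine.

    alpha : regularisation weight coupling data and smoothness terms
        (dimensionless after intensity normalisation; default from a grid
        search on the synthetic grid phantom, see docs/methods.md).
    levels : pyramid depth (3 for 3D grids, 4 for 2D by default via
        :func:`default_of_params`).
    max_iter_per_level : outer (warp + relinearise) iteration cap.
    tol : relative energy-decrease stopping threshold.
    epsilon : Charbonnier constant, as a fraction of the normalised
        intensity range (images are scaled to [0, 1] internally).
    n_inner : Jacobi sweeps per linearisation.
    """

    alpha: float = 0.1
    levels: int = 3
    max_iter_per_level: int = 20
    tol: float = 1e-4
    epsilon: float = 0.01
    n_inner: int = 15

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.tol <= 0 or self.epsilon <= 0:
            raise ValueError("tol and epsilon must be > 0")


def default_of_params(ndim: int, **overrides) -> OFParams:
    """Shipped defaults: 3 pyramid levels for 3D grids, 4 for 2D."""
    base = dict(levels=3 if ndim == 3 else 4)
    base.update(overrides)
    return OFParams(**base)


@dataclass
class RegistrationResult:
    """Outcome of a deformable registration run.

    ``energy_trace`` holds the per-outer-iteration energies at the finest
    pyramid level; ``level_traces`` the traces of every level (coarse
    first).  Each trace is non-increasing by construction (backtracking).
    """

    field: DeformationField
    energy_trace: list
    level_traces: list
    converged: bool
    warnings: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _check_pair(fixed: GeomImage, moving: GeomImage) -> None:
    if not fixed.same_grid(moving):
        raise GeometryError(
            f"fixed grid {fixed.shape} and moving grid {moving.shape} differ; "
            "resample onto a common geometry first"
        )
    if not (np.all(np.isfinite(fixed.data)) and np.all(np.isfinite(moving.data))):
        raise ValueError("images contain non-finite voxels")


def _normalize_pair(fixed: GeomImage, moving: GeomImage):
    lo = min(fixed.data.min(), moving.data.min())
    hi = max(fixed.data.max(), moving.data.max())
    scale = hi - lo
    f = GeomImage((fixed.data - lo) / scale, fixed.affine)
    m = GeomImage((moving.data - lo) / scale, moving.affine)
    return f, m


def of_energy(
    fixed: GeomImage,
    moving: GeomImage,
    fld: DeformationField,
    alpha: float,
) -> float:
    """Evaluate E_OF(u) on raw intensities.

    The data term sums |I(r) - J(r + u(r))| over all voxels (J sampled
    linearly with replicated borders); the smoothness term uses central
    differences of u per mm.
    """
    _check_pair(fixed, moving)
    if not fixed.same_grid(fld.geometry):
        raise GeometryError("field geometry does not match the image grid")
    warped = _solver.warp_channels_of(moving.data, fixed, fld.vectors)
    data = float(np.sum(np.abs(fixed.data - warped)))
    return data + alpha * _solver.gradient_energy(fld.vectors, fixed.voxel_size_mm)


def register_of(
    fixed: GeomImage,
    moving: GeomImage,
    params: OFParams | None = None,
    init: DeformationField | None = None,
) -> RegistrationResult:
    """Estimate the dense deformation aligning ``moving`` to ``fixed``.

    Returns a field u such that ``moving`` sampled at r + u(r) approximates
    ``fixed``.  Deterministic given inputs and parameters.  Constant
    (structure-free) images cannot constrain a deformation; they yield the
    zero field with a warning flag instead of an error.
    """
    _check_pair(fixed, moving)
    if params is None:
        params = default_of_params(fixed.ndim)
    if np.ptp(fixed.data) == 0 or np.ptp(moving.data) == 0:
        return RegistrationResult(
            field=init.copy() if init is not None else DeformationField.zero(fixed),
            energy_trace=[],
            level_traces=[],
            converged=False,
            warnings=["degenerate (constant) input image; returning zero field"],
            meta={"params": params},
        )
    f, m = _normalize_pair(fixed, moving)
    eps = params.epsilon  # images are normalised, range == 1

    def channel_fn(data: np.ndarray, geom: GeomImage):
        return data[None]

    def data_energy(fixed_ch, warped_ch) -> float:
        return float(np.sum(np.abs(fixed_ch[0] - warped_ch[0])))

    def weights(fixed_ch, warped_ch):
        rho = warped_ch - fixed_ch
        return 1.0 / (2.0 * np.sqrt(rho * rho + eps * eps))

    out = _solver.multires_solve(
        f,
        m,
        alpha=params.alpha,
        levels=params.levels,
        max_iter_per_level=params.max_iter_per_level,
        tol=params.tol,
        n_inner=params.n_inner,
        channel_fn=channel_fn,
        data_energy_fn=data_energy,
        weight_fn=weights,
        init=init,
    )
    return RegistrationResult(
        field=out.field,
        energy_trace=list(out.level_traces[-1].energies),
        level_traces=[list(t.energies) for t in out.level_traces],
        converged=out.converged,
        meta={"params": params, "engine": "optical_flow"},
    )
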