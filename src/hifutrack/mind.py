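"""Multi-modal deformable registration via modality-independent
neighbourhood descriptors (MIND).

Each voxel of an image I is assigned a self-similarity descriptor

    MIND(I, r, gamma) = (1/Z) exp(-D_p(I, r, r + gamma) / V(I, r)),  gamma in Gamma

where D_p is the sum of squared differences between the patches of
half-width p around r and r + gamma, V is a local variance estimate (the
mean of D_p over the one-voxel axis offsets, floored to stay positive in
flat regions such as gel background), and Z normalises the per-voxel
maximum component to 1.  Descriptors depend only on local self-similarity,
not on absolute intensities, which makes the dissimilarity

    S(I, J)(r) = (1/|Gamma|) sum_gamma |MIND(I,r,gamma) - MIND(J,r,gamma)|

meaningful across MR contrasts.  Registration minimises

    E_MIND(u) = sum_r S(I, J o (id+u))(r)^2 + alpha ||grad u(r)||^2

with a Gauss-Newton scheme on the descriptor channels, sharing the
pyramid/backtracking machinery of the mono-modal engine.  Patches are
clipped (shrunk) at image borders rather than padded; descriptors there
rely on partial neighbourhoods, one reason border voxels are customarily
excluded from validation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _solver
from .geometry import DeformationField, GeomImage, GeometryError
from .optical_flow import RegistrationResult, _check_pair, _normalize_pair


def axis_offsets(ndim: int) -> tuple:
    """One-voxel offsets along each grid axis (4-/6-neighbourhood)."""
    offs = []
    for a in range(ndim):
        for s in (-1, 1):
            o = [0] * ndim
            o[a] = s
            offs.append(tuple(o))
    return tuple(offs)


@dataclass
class MINDParams:
    """Descriptor and solver parameters.

    patch_radius : half-width p of the local patch, voxels.
    search_offsets : the offset set Gamma; defaults to the one-voxel
        4-neighbourhood (2D) / 6-neighbourhood (3D).
    variance_floor_frac : lower bound for V, as a fraction of the squared
        normalised intensity range (images are scaled to [0, 1]).
    alpha, levels, max_iter_per_level, tol, n_inner : as in OFParams.
    """

    patch_radius: int = 1
    search_offsets: tuple | None = None
    alpha: float = 0.7
    variance_floor_frac: float = 1e-3
    levels: int = 3
    max_iter_per_level: int = 25
    tol: float = 1e-4
    n_inner: int = 15

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.variance_floor_frac <= 0:
            raise ValueError("variance floor must be > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.search_offsets is not None:
            offs = [tuple(int(x) for x in o) for o in self.search_offsets]
            if not offs:
                raise ValueError("Gamma must be non-empty")
            if any(all(x == 0 for x in o) for o in offs):
                raise ValueError("Gamma must exclude the zero offset")
            self.search_offsets = tuple(offs)

    def offsets_for(self, ndim: int) -> tuple:
        return self.search_offsets or axis_offsets(ndim)


def default_mind_params(ndim: int, **overrides) -> MINDParams:
    base = dict(levels=3 if ndim == 3 else 4)
    base.update(overrides)
    return MINDParams(**base)


@dataclass
class MINDDescriptorField:
    """Per-voxel descriptor vectors, components in (0, 1], max component 1."""

    components: np.ndarray  # shape (|Gamma|, *grid_shape)
    offsets: tuple
    geometry: GeomImage


# ---------------------------------------------------------------------------
# descriptor construction
# ---------------------------------------------------------------------------


def _shifted_sq_diff(data: np.ndarray, offset: tuple) -> tuple:
    """(I(r) - I(r+offset))^2 with a validity mask (clipped at borders)."""
    sq = np.zeros_like(data)
    valid = np.zeros(data.shape, dtype=bool)
    src = []
    dst = []
    for n, o in zip(data.shape, offset):
        if o >= 0:
            dst.append(slice(0, n - o))
            src.append(slice(o, n))
        else:
            dst.append(slice(-o, n))
            src.append(slice(0, n + o))
    d = data[tuple(dst)] - data[tuple(src)]
    sq[tuple(dst)] = d * d
    valid[tuple(dst)] = True
    return sq, valid


def _patch_sum(arr: np.ndarray, radius: int) -> np.ndarray:
    """Sum over the (2r+1)^d patch, clipped (zero outside) at borders."""
    size = 2 * radius + 1
    kernel_axes = [size] * arr.ndim
    out = arr
    for a, s in enumerate(kernel_axes):
        out = ndimage.correlate1d(out, np.ones(s), axis=a, mode="constant", cval=0.0)
    return out


def patch_distance_field(
    img: GeomImage, offset: tuple, patch_radius: int
) -> np.ndarray:
    """Dense D_p: per-voxel SSD between the patch at r and at r+offset.

    Voxel pairs falling outside the grid are excluded (clipped patches).
    """
    if len(offset) != img.ndim:
        raise GeometryError("offset dimensionality does not match the image")
    if any(abs(o) >= n for o, n in zip(offset, img.shape)):
        raise ValueError(f"offset {offset} is outside the image for all voxels")
    sq, valid = _shifted_sq_diff(img.data, offset)
    return _patch_sum(sq * valid, patch_radius)


def patch_distance(
    img: GeomImage, r: tuple, offset: tuple, patch_radius: int
) -> float:
    """Pointwise D_p at voxel ``r`` (see :func:`patch_distance_field`)."""
    return float(patch_distance_field(img, offset, patch_radius)[tuple(r)])


def local_variance_field(
    img: GeomImage,
    patch_radius: int,
    variance_floor: float,
) -> np.ndarray:
    """Dense V: mean patch distance over the one-voxel axis offsets, floored."""
    offs = axis_offsets(img.ndim)
    acc = np.zeros(img.shape)
    for o in offs:
        acc += patch_distance_field(img, o, patch_radius)
    return np.maximum(acc / len(offs), variance_floor)


def local_variance(
    img: GeomImage,
    r: tuple,
    patch_radius: int,
    variance_floor: float,
) -> float:
    return float(local_variance_field(img, patch_radius, variance_floor)[tuple(r)])


def compute_mind(img: GeomImage, params: MINDParams | None = None) -> MINDDescriptorField:
    """MIND descriptor field of an image.

    The normalisation constant Z is realised per voxel as the maximum
    pre-normalisation component, so the largest descriptor entry is
    exactly 1 everywhere.
    """
    if params is None:
        params = default_mind_params(img.ndim)
    offsets = params.offsets_for(img.ndim)
    rng_sq = max(float(np.ptp(img.data)), 1e-30) ** 2
    floor = params.variance_floor_frac * rng_sq
    v = local_variance_field(img, params.patch_radius, floor)
    comps = np.empty((len(offsets),) + img.shape)
    for i, o in enumerate(offsets):
        dp = patch_distance_field(img, o, params.patch_radius)
        comps[i] = np.exp(-dp / v)
    z = comps.max(axis=0)
    comps /= z
    return MINDDescriptorField(comps, offsets, img)


def mind_distance(
    desc_a: MINDDescriptorField, desc_b: MINDDescriptorField
) -> np.ndarray:
    """S(I, J): per-voxel mean absolute descriptor difference, in [0, 1]."""
    if desc_a.offsets != desc_b.offsets:
        raise GeometryError("descriptor fields use different offset sets Gamma")
    if desc_a.components.shape != desc_b.components.shape:
        raise GeometryError("descriptor fields live on different grids")
    return np.mean(np.abs(desc_a.components - desc_b.components), axis=0)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def mind_energy(
    fixed: GeomImage,
    moving: GeomImage,
    fld: DeformationField,
    params: MINDParams,
) -> float:
    """E_MIND(u): summed squared MIND dissimilarity plus smoothness term."""
    f, m = _normalize_pair(fixed, moving)
    warped = GeomImage(
        _solver.warp_channels_of(m.data, f, fld.vectors), f.affine
    )
    s = mind_distance(compute_mind(f, params), compute_mind(warped, params))
    return float(np.sum(s * s)) + params.alpha * _solver.gradient_energy(
        fld.vectors, fixed.voxel_size_mm
    )


def register_mind(
    fixed: GeomImage,
    moving: GeomImage,
    params: MINDParams | None = None,
    init: DeformationField | None = None,
) -> RegistrationResult:
    """Cross-contrast deformable registration of ``moving`` to ``fixed``.

    The descriptor stack of the warped moving image is recomputed at every
    outer iteration, so the data term always reflects genuine
    self-similarity rather than warped descriptors.  Deterministic.
    """
    _check_pair(fixed, moving)
    if params is None:
        params = default_mind_params(fixed.ndim)
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
    n_gamma = len(params.offsets_for(fixed.ndim))

    def channel_fn(data: np.ndarray, geom: GeomImage):
        return compute_mind(GeomImage(data, geom.affine), params).components

    def data_energy(fixed_ch, warped_ch) -> float:
        s = np.mean(np.abs(fixed_ch - warped_ch), axis=0)
        return float(np.sum(s * s))

    def weights(fixed_ch, warped_ch):
        # Gauss-Newton on (1/|Gamma|) sum_c (delta_c)^2, a Cauchy-Schwarz
        # upper bound of S^2; the true S^2 energy is enforced by the
        # solver's backtracking step.
        return np.full_like(fixed_ch, 1.0 / n_gamma)

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
        meta={"params": params, "engine": "mind"},
    )
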