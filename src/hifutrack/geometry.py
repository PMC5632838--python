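"""Core image/geometry containers and resampling primitives.

All spatial quantities are expressed in world millimetres.  An image is a
2D or 3D scalar grid together with a 4x4 affine that maps 0-based voxel
*centre* indices ``(i, j[, k])`` (padded with zeros to length 3) to world
coordinates in mm.  Displacement fields store, per voxel, one component per
grid axis, measured in mm along the (unit-normalised) direction of the
corresponding affine column.  Grid axes are required to be mutually
orthogonal in world space, which keeps the mm <-> voxel-index conversion a
simple per-axis division by the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when image geometries are inconsistent or degenerate."""


def _check_affine(affine: np.ndarray, ndim: int) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise GeometryError("affine is singular")
    cols = affine[:3, :ndim]
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms <= 0):
        raise GeometryError("voxel sizes must be strictly positive")
    # orthogonality of the active axes (scaled-orthogonal affines only)
    gram = cols.T @ cols
    off = gram - np.diag(np.diag(gram))
    if np.max(np.abs(off)) > 1e-6 * np.max(norms) ** 2:
        raise GeometryError("grid axes must be orthogonal in world space")
    return affine


@dataclass
class GeomImage:
    """Scalar 2D/3D image with voxel-to-world geometry.

    Parameters
    ----------
    data : ndarray
        Scalar grid, 2 or 3 dimensional, arbitrary intensity units.
    affine : ndarray, shape (4, 4)
        Maps the voxel-centre index ``(i, j, k, 1)`` (2D images use
        ``k = 0``) to homogeneous world mm.  For 2D images the third
        column encodes the slice normal; its norm is interpreted as the
        slice thickness by consumers that paint through-plane.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise GeometryError(f"image must be 2D or 3D, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine, self.data.ndim)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis spacing in mm (norms of the active affine columns)."""
        return np.linalg.norm(self.affine[:3, : self.ndim], axis=0)

    @property
    def axes_mm(self) -> np.ndarray:
        """Unit world directions of the grid axes, shape (3, ndim)."""
        cols = self.affine[:3, : self.ndim]
        return cols / np.linalg.norm(cols, axis=0, keepdims=True)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(..., ndim)`` to world mm ``(..., 3)``."""
        idx = np.asarray(idx, dtype=float)
        full = np.zeros(idx.shape[:-1] + (3,))
        full[..., : self.ndim] = idx
        return full @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm points ``(..., 3)`` to fractional indices ``(..., ndim)``.

        For 2D images the returned index drops the out-of-plane coordinate;
        use :meth:`world_to_full_index` to retrieve it.
        """
        return self.world_to_full_index(pts)[..., : self.ndim]

    def world_to_full_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def index_grid(self) -> np.ndarray:
        """Dense grid of voxel indices, shape ``shape + (ndim,)``."""
        axes = [np.arange(n, dtype=float) for n in self.shape]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def same_grid(self, other: "GeomImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def copy(self, data: np.ndarray | None = None) -> "GeomImage":
        return GeomImage(
            self.data.copy() if data is None else np.asarray(data, float),
            self.affine.copy(),
        )


@dataclass
class DeformationField:
    """Dense per-voxel displacement in world mm on a :class:`GeomImage` grid.

    ``vectors[..., a]`` is the displacement component along grid axis ``a``
    (a unit world direction), so a field has 2 components on 2D grids and 3
    on 3D grids.  The zero field acts as the identity under warping.
    """

    vectors: np.ndarray
    geometry: GeomImage

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        expected = self.geometry.shape + (self.geometry.ndim,)
        if self.vectors.shape != expected:
            raise GeometryError(
                f"field shape {self.vectors.shape} does not match grid "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise GeometryError("deformation field contains non-finite values")

    @classmethod
    def zero(cls, geometry: GeomImage) -> "DeformationField":
        return cls(np.zeros(geometry.shape + (geometry.ndim,)), geometry)

    @property
    def ndim(self) -> int:
        return self.geometry.ndim

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm of the displacement, in mm."""
        return np.linalg.norm(self.vectors, axis=-1)

    def sample_at_index(self, idx: np.ndarray, mode: str = "nearest") -> np.ndarray:
        """Linearly interpolate the field at fractional indices ``(..., ndim)``."""
        idx = np.asarray(idx, dtype=float)
        coords = np.moveaxis(idx, -1, 0)
        out = np.empty(idx.shape[:-1] + (self.ndim,))
        for a in range(self.ndim):
            out[..., a] = ndimage.map_coordinates(
                self.vectors[..., a], coords, order=1, mode=mode
            )
        return out

    def sample_at_world(self, pts: np.ndarray, mode: str = "nearest") -> np.ndarray:
        return self.sample_at_index(self.geometry.world_to_index(pts), mode=mode)

    def copy(self) -> "DeformationField":
        return DeformationField(self.vectors.copy(), self.geometry)


@dataclass
class ROIMask:
    """Boolean mask co-registered with a host grid."""

    mask: np.ndarray
    geometry: GeomImage | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.geometry is not None and self.mask.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} does not match host grid "
                f"{self.geometry.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValueError("ROI mask is empty")


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def _displaced_coords(img: GeomImage, fld: DeformationField) -> np.ndarray:
    """Sampling coordinates r + u(r) in fractional voxel indices, (ndim, ...)."""
    idx = img.index_grid()
    disp_idx = fld.vectors / img.voxel_size_mm
    return np.moveaxis(idx + disp_idx, -1, 0)


def _nearest_lower(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves toward the lower index."""
    return np.ceil(x - 0.5)


def warp_image(
    img: GeomImage,
    fld: DeformationField,
    interp: str = "linear",
    fill: float | None = None,
) -> tuple[GeomImage, ROIMask]:
    """Sample ``img`` at ``r + u(r)`` (pull-back warp).

    Returns the warped image together with a validity mask flagging voxels
    whose sampling location fell inside the source grid.  Out-of-bounds
    samples are filled with ``fill`` (default: the source minimum, to avoid
    fabricating bright tissue signal at borders).
    """
    if not img.same_grid(fld.geometry):
        raise GeometryError(
            f"field grid {fld.geometry.shape} does not match image grid "
            f"{img.shape}"
        )
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if fill is None:
        fill = float(img.data.min())
    coords = _displaced_coords(img, fld)
    eps = 1e-9
    valid = np.ones(img.shape, dtype=bool)
    for a in range(img.ndim):
        valid &= (coords[a] >= -eps) & (coords[a] <= img.shape[a] - 1 + eps)
    if interp == "nearest":
        idx = [
            np.clip(_nearest_lower(coords[a]).astype(int), 0, img.shape[a] - 1)
            for a in range(img.ndim)
        ]
        out = img.data[tuple(idx)]
        out = np.where(valid, out, fill)
    else:
        out = ndimage.map_coordinates(
            img.data, coords, order=1, mode="constant", cval=fill
        )
    return GeomImage(out, img.affine.copy()), ROIMask(valid)


def compose_fields(
    outer: DeformationField, inner: DeformationField
) -> DeformationField:
    """Composition ``result(r) = inner(r) + outer(r + inner(r))``.

    Warping an image by the result is equivalent (up to interpolation
    error) to warping by ``inner`` and then sampling through ``outer``,
    i.e. ``warp(img, result) ~ warp(warp(img, outer), inner)`` in the
    pull-back convention used throughout.
    """
    if outer.ndim != inner.ndim:
        raise GeometryError(
            f"cannot compose a {outer.ndim}D field with a {inner.ndim}D field"
        )
    if not np.allclose(outer.geometry.axes_mm, inner.geometry.axes_mm, atol=1e-6):
        raise GeometryError("fields live on grids with different axis directions")
    idx = inner.geometry.index_grid()
    shifted = idx + inner.vectors / inner.geometry.voxel_size_mm
    if inner.geometry.same_grid(outer.geometry):
        outer_at = outer.sample_at_index(shifted)
    else:
        world = inner.geometry.index_to_world(shifted)
        outer_at = outer.sample_at_world(world)
    return DeformationField(inner.vectors + outer_at, inner.geometry)


def resample_to_geometry(
    src: GeomImage,
    target_affine: np.ndarray,
    target_shape: tuple,
    interp: str = "linear",
    fill: float | None = None,
) -> GeomImage:
    """Resample ``src`` onto the grid defined by ``target_affine``/``target_shape``.

    Each target voxel is sampled from ``src`` at the world-equivalent
    location.  The target may have lower dimensionality than the source
    (slice extraction); out-of-bounds samples are filled with ``fill``
    (default: source minimum).
    """
    target_shape = tuple(int(n) for n in target_shape)
    tnd = len(target_shape)
    target_affine = _check_affine(target_affine, tnd)
    if fill is None:
        fill = float(src.data.min())
    probe = GeomImage(np.zeros(target_shape), target_affine)
    world = probe.index_to_world(probe.index_grid())
    src_idx = src.world_to_full_index(world)[..., : src.ndim]
    coords = np.moveaxis(src_idx, -1, 0)
    if interp == "nearest":
        eps = 1e-9
        valid = np.ones(target_shape, dtype=bool)
        idx = []
        for a in range(src.ndim):
            valid &= (coords[a] >= -eps) & (coords[a] <= src.shape[a] - 1 + eps)
            idx.append(
                np.clip(_nearest_lower(coords[a]).astype(int), 0, src.shape[a] - 1)
            )
        out = np.where(valid, src.data[tuple(idx)], fill)
    elif interp == "linear":
        out = ndimage.map_coordinates(
            src.data, coords, order=1, mode="constant", cval=fill
        )
    else:
        raise ValueError(f"unknown interpolation {interp!r}")
    return GeomImage(out, target_affine)


def extract_slices(vol3d: GeomImage, slice_geom: GeomImage) -> GeomImage:
    """Extract the plane covered by a 2D geometry from a 3D volume.

    The output lives on ``slice_geom``'s grid, resampled from ``vol3d``
    (the reformatting step that precedes 2D-to-3D registration refinement).
    """
    if vol3d.ndim != 3:
        raise GeometryError("extract_slices requires a 3D source volume")
    if slice_geom.ndim != 2:
        raise GeometryError("extract_slices requires a 2D target geometry")
    probe_idx = slice_geom.index_grid()
    world = slice_geom.index_to_world(probe_idx)
    src_idx = vol3d.world_to_full_index(world)
    lo = src_idx.reshape(-1, 3).min(axis=0)
    hi = src_idx.reshape(-1, 3).max(axis=0)
    if np.any(hi < 0) or np.any(lo > np.array(vol3d.shape) - 1):
        wlo = vol3d.index_to_world(np.zeros(3))
        whi = vol3d.index_to_world(np.array(vol3d.shape, float) - 1)
        raise GeometryError(
            "slice plane lies outside the volume: volume world extents "
            f"{np.minimum(wlo, whi)} .. {np.maximum(wlo, whi)} mm"
        )
    return resample_to_geometry(vol3d, slice_geom.affine, slice_geom.shape)


def axis_aligned_affine(
    spacing: np.ndarray | tuple,
    origin: np.ndarray | tuple = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Convenience: diagonal affine with given per-axis spacing and origin."""
    spacing = np.asarray(spacing, dtype=float)
    diag = np.ones(3)
    diag[: len(spacing)] = spacing
    aff = np.eye(4)
    aff[:3, :3] = np.diag(diag)
    aff[:3, 3] = np.asarray(origin, dtype=float)
    return aff


def slice_affine(
    axes: tuple[int, int],
    spacing: tuple[float, float],
    origin: np.ndarray,
    thickness_mm: float = 1.0,
) -> np.ndarray:
    """Affine of an axis-aligned 2D plane embedded in 3D world space.

    ``axes`` names the two world axes spanned by the plane (e.g. ``(0, 2)``
    for a coronal x-z plane); the third affine column is the plane normal
    scaled by the slice thickness so that through-plane painting can use
    ``|k| <= 0.5`` as the slab criterion.
    """
    a0, a1 = axes
    normal_axis = ({0, 1, 2} - {a0, a1}).pop()
    aff = np.zeros((4, 4))
    aff[a0, 0] = spacing[0]
    aff[a1, 1] = spacing[1]
    aff[normal_axis, 2] = thickness_mm
    aff[:3, 3] = origin
    aff[3, 3] = 1.0
    return aff
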