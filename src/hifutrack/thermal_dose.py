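"""CEM43 thermal-dose accumulation, lethal masking and plan coverage.

Thermal dose is expressed in cumulative equivalent minutes at 43 degC
(Sapareto-Dean):

    CEM43 = sum_t R^(43 - T_t) * dt/60,   R = 0.5 for T >= 43, 0.25 below

Tissue is conventionally regarded as necrosed beyond 240 CEM43.  Dose is
accumulated per sonication in the 2D thermometry reference frame (after
motion alignment of the temperature maps) and mapped into the 3D planning
frame once per sonication by the framework module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeomImage, GeometryError, ROIMask, warp_image

LETHAL_CEM43 = 240.0
R_ABOVE_43 = 0.5
R_BELOW_43 = 0.25


@dataclass
class TemperatureSeries:
    """Time-ordered absolute-temperature frames (degC) on a fixed 2D grid."""

    frames: list
    dt_s: float
    plane: str = ""

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if not self.frames:
            raise ValueError("temperature series is empty")
        geom = self.frames[0]
        for fr in self.frames:
            if not fr.same_grid(geom):
                raise GeometryError("temperature frames are not on a common grid")
            if not np.all(np.isfinite(fr.data)):
                raise ValueError("temperature frame contains non-finite values")
            if fr.data.min() < 0 or fr.data.max() > 100:
                raise ValueError(
                    "temperatures outside the 0-100 degC physiologic-to-ablative "
                    f"range: [{fr.data.min():.1f}, {fr.data.max():.1f}]"
                )

    @property
    def geometry(self) -> GeomImage:
        return self.frames[0]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DoseMap:
    """Accumulated CEM43 minutes per voxel."""

    image: GeomImage
    lethal_threshold: float = LETHAL_CEM43
    valid: ROIMask | None = None

    def __post_init__(self) -> None:
        if self.lethal_threshold <= 0:
            raise ValueError("lethal threshold must be > 0")
        if self.image.data.min() < 0:
            raise ValueError("dose values must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.image.data


def align_series(
    series: TemperatureSeries, fields: list, baseline_c: float = 37.0
) -> TemperatureSeries:
    """Warp each frame into the 2D reference frame using its motion field.

    ``fields`` must contain one :class:`DeformationField` per frame (zero
    fields are allowed).  Out-of-bounds regions are filled with the
    baseline temperature and excluded via the intersected validity mask,
    which is carried on the returned series as ``valid``.
    """
    if len(fields) != len(series):
        raise ValueError(
            f"{len(series)} frames but {len(fields)} motion fields"
        )
    aligned = []
    valid = np.ones(series.geometry.shape, dtype=bool)
    for frame, fld in zip(series.frames, fields):
        warped, mask = warp_image(frame, fld, interp="linear", fill=baseline_c)
        aligned.append(warped)
        valid &= mask.mask
    out = TemperatureSeries(aligned, series.dt_s, series.plane)
    out.valid = ROIMask(valid)  # type: ignore[attr-defined]
    return out


def cem43(series: TemperatureSeries, temperature_floor_c: float | None = None) -> DoseMap:
    """Accumulate CEM43 dose over an (aligned) temperature series.

    Optionally, temperatures below ``temperature_floor_c`` can be clamped
    out to suppress noise-driven dose; by default the pure formula is used.
    """
    stack = np.stack([fr.data for fr in series.frames])
    if temperature_floor_c is not None:
        stack = np.where(stack < temperature_floor_c, 0.0, stack)
        # 0 degC contributes R^43 * dt ~ 1e-13 min: numerically negligible
    r = np.where(stack >= 43.0, R_ABOVE_43, R_BELOW_43)
    dose = np.sum(r ** (43.0 - stack), axis=0) * (series.dt_s / 60.0)
    return DoseMap(GeomImage(dose, series.geometry.affine.copy()))


def lethal_mask(dose: DoseMap) -> ROIMask:
    """Voxels at or above the lethal threshold (closed at >=)."""
    return ROIMask(dose.values >= dose.lethal_threshold, dose.image)


def rasterize_plan(plan, planning_geom: GeomImage) -> ROIMask:
    """Union of the plan's sonication-cell ellipsoids on the planning grid."""
    if not plan.cells:
        raise ValueError("sonication plan is empty")
    world = planning_geom.index_to_world(planning_geom.index_grid())
    mask = np.zeros(planning_geom.shape, dtype=bool)
    for cell in plan.cells:
        rel = (world - np.asarray(cell.centre_mm)) / np.asarray(cell.semi_axes_mm)
        mask |= np.sum(rel * rel, axis=-1) <= 1.0
    return ROIMask(mask, planning_geom)


def coverage(plan, lethal: ROIMask, planning_geom: GeomImage) -> float:
    """Percentage of the planned ablation volume receiving lethal dose.

    |planned AND lethal| / |planned| * 100, with the planned volume
    rasterized as the union of the plan's cell ellipsoids.
    """
    planned = rasterize_plan(plan, planning_geom)
    planned.require_nonempty()
    if lethal.mask.shape != planned.mask.shape:
        raise GeometryError("lethal mask is not on the planning grid")
    hit = np.count_nonzero(planned.mask & lethal.mask)
    return 100.0 * hit / planned.n_voxels
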