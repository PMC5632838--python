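"""Quantitative evaluation of motion estimates.

Two field-level metrics are provided: the endpoint error between two
displacement fields,

    EE(r) = || u_a(r) - u_b(r) ||_2     [mm]

and the motion-magnitude sample set over an organ/structure ROI,

    M = { || u(r) ||_2 : r in ROI }     [mm]

plus the boxplot-style summary (5/25/50/75/95th percentiles and mean) used
to report them.  Percentiles are computed with linear interpolation
between order statistics.

A note on the magnitude set: it is defined here with the plain (non
squared) Euclidean norm, so that summaries carry mm units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DeformationField, GeometryError, ROIMask


@dataclass
class ErrorSummary:
    """Boxplot-style summary of a sample set, all values in mm."""

    p5: float
    p25: float
    p50: float
    p75: float
    p95: float
    mean: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary requires at least one sample")
        if not (self.p5 <= self.p25 <= self.p50 <= self.p75 <= self.p95):
            raise ValueError("percentiles are not ordered")

    def as_dict(self) -> dict:
        return {
            "p5": self.p5,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "p95": self.p95,
            "mean": self.mean,
            "n": self.n,
        }


def _check_fields(u_a: DeformationField, u_b: DeformationField) -> None:
    if u_a.vectors.shape != u_b.vectors.shape or not u_a.geometry.same_grid(
        u_b.geometry
    ):
        raise GeometryError("endpoint error requires fields on the same grid")


def endpoint_error(
    u_a: DeformationField,
    u_b: DeformationField,
    roi: ROIMask | None = None,
) -> np.ndarray:
    """Per-voxel endpoint error in mm.

    Returns the EE over the ROI voxels as a 1D sample array, or the full
    EE map if ``roi`` is None.
    """
    _check_fields(u_a, u_b)
    ee = np.linalg.norm(u_a.vectors - u_b.vectors, axis=-1)
    if roi is None:
        return ee
    if roi.mask.shape != ee.shape:
        raise GeometryError("ROI shape does not match the field grid")
    roi.require_nonempty()
    return ee[roi.mask]


def motion_magnitude_set(u: DeformationField, roi: ROIMask) -> np.ndarray:
    """Sample set of displacement magnitudes ||u(r)||_2 over the ROI, in mm."""
    if roi.mask.shape != u.geometry.shape:
        raise GeometryError("ROI shape does not match the field grid")
    roi.require_nonempty()
    return u.magnitude()[roi.mask]


def summarize(samples: np.ndarray) -> ErrorSummary:
    """Percentile/mean summary of a sample set (linear-interpolated)."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot summarize an empty sample set")
    p5, p25, p50, p75, p95 = np.percentile(
        samples, [5, 25, 50, 75, 95], method="linear"
    )
    return ErrorSummary(
        p5=float(p5),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p95=float(p95),
        mean=float(samples.mean()),
        n=int(samples.size),
    )
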