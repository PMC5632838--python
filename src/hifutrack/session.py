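"""Domain types for a therapy session: gating, breathing traces,
sonication plans and the scan bundles acquired around each sonication.

A session mirrors the episodic work-flow of an MR-guided HIFU ablation:
a 3D reference anchor at the start, further 3D anatomical anchors during
cool-down intervals (sampling slow drifts), and per-sonication bundles of
2D scans: the 2D thermometry reference, optionally a non-distorted EPI
scan and a sparse anatomical anchor (extended protocol), and the
thermometry time series itself.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeomImage


@dataclass
class GatingWindow:
    """Navigator acceptance band: accept iff |pos - center| <= width/2."""

    center_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.width_mm <= 0:
            raise ValueError("gating window width must be > 0")

    def accepts(self, positions: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(positions) - self.center_mm) <= self.width_mm / 2


@dataclass
class BreathingTrace:
    """Navigator displacement time series with recorded drift events.

    ``position_mm`` is the navigator reading (breathing plus the
    head-foot component of the cumulative drift).  ``drift_events`` is a
    list of ``(time_s, vector_mm)`` step drifts, recorded exactly so the
    generated session keeps a complete ground truth.
    """

    t_s: np.ndarray
    position_mm: np.ndarray
    dt_s: float
    drift_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        if self.t_s.shape != self.position_mm.shape or self.t_s.ndim != 1:
            raise ValueError("trace time and position arrays must match (1D)")
        if self.t_s.size and not np.allclose(np.diff(self.t_s), self.dt_s, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")
        self.drift_events = [
            (float(t), np.asarray(v, dtype=float)) for t, v in self.drift_events
        ]

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1]) if self.t_s.size else 0.0

    def drift_at(self, t: float) -> np.ndarray:
        """Cumulative drift vector (mm) in effect at time t."""
        out = np.zeros(3)
        for te, v in self.drift_events:
            if t >= te:
                out += v
        return out

    def breathing_mm(self) -> np.ndarray:
        """Navigator positions with the drift steps subtracted."""
        drift_z = np.array([self.drift_at(t)[2] for t in self.t_s])
        return self.position_mm - drift_z


@dataclass
class SonicationCell:
    """One ellipsoidal sonication target in planning-frame world mm."""

    centre_mm: np.ndarray
    semi_axes_mm: np.ndarray = (2.0, 2.0, 2.0)
    energy_j: float = 13500.0
    out_of_extent: bool = False

    def __post_init__(self) -> None:
        self.centre_mm = np.asarray(self.centre_mm, dtype=float)
        self.semi_axes_mm = np.asarray(self.semi_axes_mm, dtype=float)
        if np.any(self.semi_axes_mm <= 0):
            raise ValueError("cell semi-axes must be > 0")


@dataclass
class SonicationPlan:
    cells: list

    def __post_init__(self) -> None:
        if not all(isinstance(c, SonicationCell) for c in self.cells):
            raise TypeError("plan cells must be SonicationCell instances")

    def __len__(self) -> int:
        return len(self.cells)

    def total_energy_j(self) -> float:
        return float(sum(c.energy_j for c in self.cells))


@dataclass
class SonicationBundle:
    """Scans acquired around one sonication, keyed by plane name.

    ``ref2d`` is the 2D thermometry reference (EPI contrast, narrow gating
    window); ``nondistorted_epi`` and ``sparse_anchor`` are present only in
    the extended protocol.  Temperature series and the per-dynamic
    magnitude images share the ref2d geometry.
    """

    timestamp_s: float
    cell_index: int
    ref2d: dict
    thermo_magnitude: dict
    thermo_temperature: dict
    nondistorted_epi: dict | None = None
    sparse_anchor: dict | None = None

    @property
    def planes(self) -> list:
        return sorted(self.ref2d.keys())


@dataclass
class TherapySession:
    """A full acquisition: reference anchor, drift anchors, bundles, plan."""

    reference_anchor: GeomImage
    anchor_times_s: list
    anchors: list
    bundles: list
    plan: SonicationPlan
    gating: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.anchors) != len(self.anchor_times_s):
            raise ValueError("anchor list and timestamp list differ in length")
        if list(self.anchor_times_s) != sorted(self.anchor_times_s):
            raise ValueError("anchor timestamps must be increasing")
        for b in self.bundles:
            if b.timestamp_s < self.anchor_times_s[0]:
                raise ValueError(
                    "every bundle must be preceded by at least one anchor"
                )

    def anchor_index_for(self, timestamp_s: float) -> int:
        """Most recent anchor acquired at or before the given time."""
        i = bisect.bisect_right(self.anchor_times_s, timestamp_s) - 1
        if i < 0:
            raise ValueError(f"no anchor precedes timestamp {timestamp_s}")
        return i
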