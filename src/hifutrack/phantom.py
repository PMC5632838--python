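"""Synthetic moving grid phantom and session generator.

Everything the framework consumes can be generated here with exact ground
truth: a gel cylinder containing two orthogonal grid structures (one in
the coronal, one in the sagittal plane), a quasi-periodic breathing trace
with injected step drifts, gated scan acquisition, an EPI-like contrast
transform, phase-encode-directional geometric distortion, and Gaussian
hotspot temperature series.

The phantom is defined as an *analytic* intensity function of world
coordinates; every scan is rendered by sampling that function at
displaced/warped positions.  The motion model is rigid head-foot
translation (breathing + drift steps, mirroring a motorised-platform
experiment), so scan ground truths are exact — no interpolation enters
the truth itself.  World axes: x = left-right (axis 0), y =
anterior-posterior (axis 1), z = head-foot (axis 2); the phantom is
centred at the world origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (
    DeformationField,
    GeomImage,
    ROIMask,
    axis_aligned_affine,
    slice_affine,
)
from .session import (
    BreathingTrace,
    GatingWindow,
    SonicationBundle,
    SonicationCell,
    SonicationPlan,
    TherapySession,
)
from .thermal_dose import TemperatureSeries

PLANE_AXES = {"coronal": (0, 2), "sagittal": (1, 2)}  # in-plane world axes


# ---------------------------------------------------------------------------
# phantom definition
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry and intensity model of the grid phantom.

    The anchor grid is 2 mm isotropic by default.  Edge transitions use a
    linear ramp of ``edge_width_mm`` (sub-voxel) so that analytic
    renderings at shifted positions stay consistent with linear
    interpolation; pure gel/structure plateaus dominate the interior.
    """

    shape: tuple = (96, 96, 40)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    cylinder_radius_mm: float = 80.0
    cylinder_height_mm: float = 48.0
    grid_spacing_mm: float = 16.0
    bar_thickness_mm: float = 4.0
    slab_thickness_mm: float = 6.0
    gel_intensity: float = 1.0
    structure_intensity: float = 0.2
    noise_sd: float = 0.02
    edge_width_mm: float = 1.5
    border_margin_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.bar_thickness_mm >= self.grid_spacing_mm:
            raise ValueError("bar thickness must be below the grid spacing")
        if self.gel_intensity == self.structure_intensity:
            raise ValueError("gel and structure intensities must differ")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        fov = np.asarray(self.shape) * np.asarray(self.spacing_mm)
        if (
            2 * self.cylinder_radius_mm > min(fov[0], fov[1])
            or self.cylinder_height_mm > fov[2]
        ):
            raise ValueError("grid structures/cylinder exceed the field of view")
        if self.slab_thickness_mm > self.cylinder_height_mm:
            raise ValueError("grid structures exceed the cylinder")

    def affine(self) -> np.ndarray:
        origin = -(np.asarray(self.shape) - 1) * np.asarray(self.spacing_mm) / 2
        return axis_aligned_affine(self.spacing_mm, origin)

    def geometry(self) -> GeomImage:
        return GeomImage(np.zeros(self.shape), self.affine())


def _ramp(d: np.ndarray, w: float) -> np.ndarray:
    """0 -> 1 linear transition of width w centred on d = 0."""
    return np.clip(0.5 + np.asarray(d) / w, 0.0, 1.0)


def _gridline_dist(c: np.ndarray, spacing: float) -> np.ndarray:
    return np.abs(((c + spacing / 2) % spacing) - spacing / 2)


def phantom_structure_fraction(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Occupancy (0..1) of the two grid structures at world points (..., 3)."""
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    w = spec.edge_width_mm
    bt, gs, st = spec.bar_thickness_mm, spec.grid_spacing_mm, spec.slab_thickness_mm

    def bars(a, b):
        return np.maximum(
            _ramp(bt / 2 - _gridline_dist(a, gs), w),
            _ramp(bt / 2 - _gridline_dist(b, gs), w),
        )

    coronal = _ramp(st / 2 - np.abs(y), w) * bars(x, z)
    sagittal = _ramp(st / 2 - np.abs(x), w) * bars(y, z)
    return np.maximum(coronal, sagittal)


def phantom_cylinder_fraction(
    spec: PhantomSpec, pts: np.ndarray, margin_mm: float = 0.0
) -> np.ndarray:
    r = np.hypot(pts[..., 0], pts[..., 1])
    w = spec.edge_width_mm
    return _ramp(spec.cylinder_radius_mm - margin_mm - r, w) * _ramp(
        spec.cylinder_height_mm / 2 - margin_mm - np.abs(pts[..., 2]), w
    )


def phantom_intensity(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Analytic phantom intensity at world points (..., 3)."""
    struct = phantom_structure_fraction(spec, pts)
    cyl = phantom_cylinder_fraction(spec, pts)
    inside = spec.gel_intensity + (spec.structure_intensity - spec.gel_intensity) * struct
    return cyl * inside


def structure_mask_at(
    spec: PhantomSpec,
    geom: GeomImage,
    displacement_mm: np.ndarray | None = None,
    margin_mm: float | None = None,
) -> ROIMask:
    """Structure-voxel ROI on an arbitrary grid, borders excluded.

    ``displacement_mm`` shifts the phantom (object displacement);
    ``margin_mm`` erodes the ROI away from the cylinder boundary, where
    the multi-modal assumption (every structure has a counterpart) breaks.
    """
    if margin_mm is None:
        margin_mm = spec.border_margin_mm
    pts = geom.index_to_world(geom.index_grid())
    if displacement_mm is not None:
        pts = pts - np.asarray(displacement_mm)
    mask = (phantom_structure_fraction(spec, pts) > 0.5) & (
        phantom_cylinder_fraction(spec, pts, margin_mm) > 0.5
    )
    return ROIMask(mask)


def make_grid_phantom(
    spec: PhantomSpec | None = None, seed: int | None = None
) -> tuple[GeomImage, ROIMask]:
    """Render the phantom volume at rest; returns the image and structure ROI."""
    if spec is None:
        spec = PhantomSpec()
    geom = spec.geometry()
    pts = geom.index_to_world(geom.index_grid())
    data = phantom_intensity(spec, pts)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return GeomImage(data, geom.affine), structure_mask_at(spec, geom)


# ---------------------------------------------------------------------------
# breathing trace
# ---------------------------------------------------------------------------


def make_breathing_trace(
    duration_s: float,
    period_s: tuple | float = (3.0, 5.0),
    amplitude_mm: float = 5.0,
    drift_events: list | None = None,
    dt_s: float = 0.05,
    seed: int | None = None,
) -> BreathingTrace:
    """Quasi-periodic head-foot navigator trace with step drifts.

    The breathing waveform is a sinusoid whose cycle length is redrawn
    uniformly from ``period_s`` every cycle (pass a scalar or equal bounds
    for a jitter-free sinusoid).  ``amplitude_mm`` is the half
    peak-to-peak excursion (default 5 mm, i.e. 10 mm peak-to-peak).
    Drift events are ``(time_s, vector_mm)`` steps; their head-foot (z)
    component adds to the navigator reading.
    """
    if np.isscalar(period_s):
        lo = hi = float(period_s)
    else:
        lo, hi = (float(period_s[0]), float(period_s[1]))
    if duration_s <= hi:
        raise ValueError("duration must exceed one breathing period")
    drift_events = [
        (float(t), np.asarray(v, dtype=float)) for t, v in (drift_events or [])
    ]
    for t, _ in drift_events:
        if not 0 <= t <= duration_s:
            raise ValueError(f"drift event at {t}s lies outside the trace")
    rng = np.random.default_rng(seed)
    starts = [0.0]
    periods = []
    while starts[-1] < duration_s:
        p = lo if lo == hi else float(rng.uniform(lo, hi))
        periods.append(p)
        starts.append(starts[-1] + p)
    starts_arr = np.asarray(starts)
    periods_arr = np.asarray(periods)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    k = np.clip(np.searchsorted(starts_arr, t, side="right") - 1, 0, len(periods) - 1)
    phase = 2 * np.pi * (t - starts_arr[k]) / periods_arr[k]
    breathing = amplitude_mm * np.sin(phase)
    drift_z = np.zeros_like(t)
    for te, v in drift_events:
        drift_z += np.where(t >= te, v[2], 0.0)
    return BreathingTrace(t, breathing + drift_z, dt_s, drift_events)


# ---------------------------------------------------------------------------
# contrast and distortion transforms
# ---------------------------------------------------------------------------


def epi_intensity_remap(x: np.ndarray, gamma: float = 0.35) -> np.ndarray:
    """Monotone nonlinear remap emulating the EPI contrast (on [0, 1])."""
    return np.clip(x, 0.0, None) ** gamma


def epi_contrast_transform(
    img: GeomImage,
    seed: int | None = None,
    gamma: float = 0.35,
    smooth_sigma_vox: float = 0.5,
    noise_sd: float = 0.01,
) -> GeomImage:
    """Second MR contrast: monotone remap + mild smoothing + noise.

    Structure boundaries are preserved (the remap is strictly monotone on
    the normalised intensities), but absolute intensities and local
    contrast change, defeating intensity-constancy registration.
    """
    rng = np.random.default_rng(seed)
    lo, hi = img.data.min(), img.data.max()
    x = (img.data - lo) / max(hi - lo, 1e-30)
    y = epi_intensity_remap(x, gamma)
    if smooth_sigma_vox > 0:
        y = ndimage.gaussian_filter(y, smooth_sigma_vox, mode="nearest")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return GeomImage(y, img.affine.copy())


def _smooth_basis(pts2: np.ndarray, extent: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Low-order separable cosine combination on normalised coordinates."""
    u = pts2[..., 0] / extent[0]
    v = pts2[..., 1] / extent[1]
    out = np.zeros(pts2.shape[:-1])
    i = 0
    for k in (1, 2):
        for l in (0, 1):
            out += coeffs[i] * np.cos(np.pi * k * u + coeffs[i + 1]) * np.cos(
                np.pi * l * v + coeffs[i + 2]
            )
            i += 3
    return out


def simulate_epi_distortion(
    img2d: GeomImage,
    max_mm: float = 6.0,
    mean_mm: float = 5.0,
    axis: int = 0,
    points: ROIMask | None = None,
    seed: int | None = None,
) -> tuple[GeomImage, DeformationField]:
    """Inject a smooth phase-encode-directional distortion into a 2D image.

    Returns the distorted image together with the true correction field u
    (all displacement on ``axis``; the orthogonal component is exactly
    zero) satisfying ``undistorted(r) = distorted(r + u(r))``.  The field
    is calibrated so that |u| over ``points`` (default: all voxels) has
    exactly the requested mean and maximum.
    """
    if img2d.ndim != 2:
        raise ValueError("distortion simulation expects a 2D image")
    if max_mm < mean_mm or mean_mm < 0:
        raise ValueError(
            f"infeasible distortion magnitudes: mean {mean_mm} > max {max_mm}"
        )
    geom = img2d
    idx = geom.index_grid()
    pts = geom.index_to_world(idx)
    inplane = np.stack(
        [pts @ geom.axes_mm[:, 0], pts @ geom.axes_mm[:, 1]], axis=-1
    )
    sel = points.mask if points is not None else np.ones(geom.shape, bool)
    if mean_mm == 0.0:
        g = np.zeros(geom.shape)
    else:
        rng = np.random.default_rng(seed)
        extent = (np.asarray(geom.shape) - 1) * geom.voxel_size_mm
        coeffs = rng.uniform(-1.0, 1.0, size=12)
        s = _smooth_basis(inplane, extent, coeffs)
        centred = s - s[sel].mean()
        peak = np.abs(centred[sel]).max()
        if peak < 1e-12:
            centred = np.zeros_like(s)
            peak = 1.0
        g = mean_mm + centred / peak * (max_mm - mean_mm)
    vectors = np.zeros(geom.shape + (2,))
    vectors[..., axis] = g
    fld = DeformationField(vectors, geom)
    # distorted(q) = undistorted(phi(q)) with phi the inverse of (id + u),
    # found by fixed-point iteration in index space along the one axis
    h = geom.voxel_size_mm[axis]
    p = idx[..., axis].copy()
    for _ in range(30):
        g_at = ndimage.map_coordinates(
            g,
            [p if a == axis else idx[..., a] for a in range(2)],
            order=1,
            mode="nearest",
        )
        p = idx[..., axis] - g_at / h
    coords = [p if a == axis else idx[..., a] for a in range(2)]
    distorted = ndimage.map_coordinates(
        img2d.data, coords, order=1, mode="nearest"
    )
    return GeomImage(distorted, geom.affine.copy()), fld


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------


def simulate_temperature_series(
    geom2d: GeomImage,
    focal_centre_mm: np.ndarray,
    peak_c: float = 57.0,
    n_frames: int = 20,
    dt_s: float = 2.0,
    residuals_mm: np.ndarray | None = None,
    sigma_mm: float = 3.0,
    baseline_c: float = 37.0,
    heat_fraction: float = 0.6,
    decay_tau_s: float = 12.0,
    plane: str = "",
) -> TemperatureSeries:
    """Gaussian hotspot with a linear heat-up ramp and exponential decay.

    ``residuals_mm``: per-frame in-plane translation of the hotspot
    (shape (n_frames, 2), components along the grid axes), emulating
    residual gated respiratory motion; None means a static hotspot.  The
    configured peak temperature is attained exactly at the last heating
    frame at the focal centre.
    """
    if residuals_mm is None:
        residuals_mm = np.zeros((n_frames, 2))
    residuals_mm = np.asarray(residuals_mm, dtype=float)
    if residuals_mm.shape != (n_frames, 2):
        raise ValueError("need one 2D residual per frame")
    n_heat = max(int(round(heat_fraction * n_frames)), 1)
    pts = geom2d.index_to_world(geom2d.index_grid())
    frames = []
    centre = np.asarray(focal_centre_mm, dtype=float)
    for f in range(n_frames):
        env = (f + 1) / n_heat if f < n_heat else float(
            np.exp(-(f + 1 - n_heat) * dt_s / decay_tau_s)
        )
        c = centre + residuals_mm[f] @ geom2d.axes_mm.T
        d2 = np.sum((pts - c) ** 2, axis=-1)
        temp = baseline_c + (peak_c - baseline_c) * env * np.exp(-d2 / (2 * sigma_mm**2))
        frames.append(GeomImage(temp, geom2d.affine.copy()))
    return TemperatureSeries(frames, dt_s, plane)


# ---------------------------------------------------------------------------
# gated session acquisition
# ---------------------------------------------------------------------------


@dataclass
class ProtocolConfig:
    """Scan schedule and acquisition settings of a synthetic session.

    Defaults mirror the phantom experiment the generator emulates: nine
    3D anchors (the first being the reference), a sonication bundle
    between consecutive anchors, 2.5 mm in-plane / 7 mm thick 2D scans in
    a coronal and a sagittal plane, a 5 mm gating window for thermometry
    and 2 mm for the reference-type scans, and EPI distortions of ~5 mm
    mean / 6 mm max at the structure grid points.
    """

    n_anchors: int = 9
    anchor_interval_s: float = 240.0
    bundle_offset_s: float = 120.0
    n_bundles: int = 8
    planes: tuple = ("coronal", "sagittal")
    inplane_spacing_mm: float = 2.5
    slice_thickness_mm: float = 7.0
    thermo_window_mm: float = 5.0
    narrow_window_mm: float = 2.0
    extended: bool = True
    distortion_mean_mm: float = 5.0
    distortion_max_mm: float = 6.0
    n_dynamics: int = 8
    dynamic_dt_s: float = 2.0
    hotspot_peak_c: float = 60.0
    hotspot_sigma_mm: float = 3.0
    noise_sd: float = 0.02
    epi_gamma: float = 0.35
    epi_smooth_vox: float = 0.5

    def duration_s(self) -> float:
        return self.n_anchors * self.anchor_interval_s


def default_drift_events(protocol: ProtocolConfig, step_mm: float = 5.0) -> list:
    """Two head-foot step drifts after the 3rd and the 6th anchor.

    For shortened protocols the drift anchors are clamped so both steps
    still fall inside the schedule.
    """
    i = protocol.anchor_interval_s
    k1 = min(2, protocol.n_anchors - 2)
    k2 = min(5, protocol.n_anchors - 2)
    events = [((k1 + 0.5) * i, np.array([0.0, 0.0, step_mm]))]
    if k2 > k1:
        events.append(((k2 + 0.5) * i, np.array([0.0, 0.0, step_mm])))
    return events


def slice_geometry(
    spec: PhantomSpec, plane: str, protocol: ProtocolConfig
) -> GeomImage:
    """Axis-aligned 2D scan geometry through the phantom centre."""
    a0, a1 = PLANE_AXES[plane]
    sp = protocol.inplane_spacing_mm
    fov = np.asarray(spec.shape) * np.asarray(spec.spacing_mm)
    n0 = int(fov[a0] / sp) - 2
    n1 = int(fov[a1] / sp) - 2
    origin = np.zeros(3)
    origin[a0] = -(n0 - 1) * sp / 2
    origin[a1] = -(n1 - 1) * sp / 2
    aff = slice_affine((a0, a1), (sp, sp), origin, protocol.slice_thickness_mm)
    return GeomImage(np.zeros((n0, n1)), aff)


class _Gater:
    """Serves gated acquisition times from a breathing trace.

    Scans are modelled as frozen at the first navigator-accepted sample at
    or after their nominal start time; back-to-back acquisition is
    obtained by starting the next search just after the previous sample.
    """

    def __init__(self, trace: BreathingTrace):
        self.trace = trace
        self.breathing = trace.breathing_mm()
        self.trough = float(self.breathing.min())

    def window(self, width_mm: float) -> GatingWindow:
        # navigator window anchored at the exhale trough (re-centred after
        # drifts, as a navigator tracking the diaphragm would be)
        return GatingWindow(self.trough + width_mm / 2, width_mm)

    def next_state(self, t_start: float, width_mm: float):
        """First accepted sample at/after t_start; returns (time, displacement)."""
        w = self.window(width_mm)
        i = int(np.ceil(round(t_start / self.trace.dt_s, 9)))
        while i < self.trace.t_s.size:
            if abs(self.breathing[i] - w.center_mm) <= width_mm / 2:
                t = float(self.trace.t_s[i])
                disp = self.trace.drift_at(t) + np.array(
                    [0.0, 0.0, self.breathing[i]]
                )
                return t, disp
            i += 1
        raise ValueError("breathing trace ended before the scan schedule")


def _render_scan(
    spec: PhantomSpec,
    geom: GeomImage,
    displacement_mm: np.ndarray,
    rng: np.random.Generator,
    contrast: str = "anchor",
    distortion_g: np.ndarray | None = None,
    distortion_axis: int = 0,
    noise_sd: float = 0.0,
    gamma: float = 0.35,
    smooth_vox: float = 0.5,
) -> GeomImage:
    """Sample the analytic phantom on a grid at a given motion state.

    ``distortion_g`` (scalar mm along in-plane ``distortion_axis``) bends
    the sampling positions through the inverse map of (id + g), so that
    the returned scan satisfies undistorted(r) = distorted(r + g(r))
    exactly for the analytic phantom.
    """
    idx = geom.index_grid()
    if distortion_g is not None:
        h = geom.voxel_size_mm[distortion_axis]
        p = idx[..., distortion_axis].copy()
        for _ in range(30):
            g_at = ndimage.map_coordinates(
                distortion_g,
                [p if a == distortion_axis else idx[..., a] for a in range(2)],
                order=1,
                mode="nearest",
            )
            p = idx[..., distortion_axis] - g_at / h
        idx = idx.copy()
        idx[..., distortion_axis] = p
    pts = geom.index_to_world(idx) - np.asarray(displacement_mm)
    data = phantom_intensity(spec, pts)
    if contrast == "epi":
        data = epi_intensity_remap(data / max(spec.gel_intensity, 1e-30), gamma)
        if smooth_vox > 0:
            data = ndimage.gaussian_filter(data, smooth_vox, mode="nearest")
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return GeomImage(data, geom.affine.copy())


@dataclass
class SessionGroundTruth:
    """Exact injected transforms for every generated scan.

    ``anchor_displacements`` are absolute object displacements (mm, world);
    relative truths are differences against the reference displacement.
    ``bundles[i][plane]`` carries the per-bundle truths: the scan states,
    the injected distortion correction field (including the tiny gated
    residual between the back-to-back narrow-window scans), and the
    per-dynamic residuals.
    """

    trace: BreathingTrace
    reference_displacement: np.ndarray
    anchor_displacements: list
    bundles: list
    spec: PhantomSpec
    protocol: ProtocolConfig

    def rs1_truth(self, anchor_index: int) -> np.ndarray:
        """True RS#1 displacement (anchor vs reference), world mm."""
        return self.anchor_displacements[anchor_index] - self.reference_displacement


def acquire_session(
    spec: PhantomSpec | None = None,
    trace: BreathingTrace | None = None,
    protocol: ProtocolConfig | None = None,
    seed: int | None = None,
) -> tuple[TherapySession, SessionGroundTruth]:
    """Run the full gated acquisition protocol on the moving phantom.

    Every scan freezes the phantom at the first navigator-accepted trace
    sample after its nominal time; scans within a bundle are acquired
    back-to-back (successive accepted samples), which keeps the residual
    motion between the narrow-window scans small, as in gated practice.
    """
    if spec is None:
        spec = PhantomSpec()
    if protocol is None:
        protocol = ProtocolConfig()
    if trace is None:
        trace = make_breathing_trace(
            protocol.duration_s(),
            drift_events=default_drift_events(protocol),
            seed=seed,
        )
    if protocol.n_bundles > protocol.n_anchors - 1:
        raise ValueError("at most one bundle between consecutive anchors")
    rng = np.random.default_rng(None if seed is None else seed + 1)
    gater = _Gater(trace)
    geom3d = spec.geometry()

    anchors = []
    anchor_times = []
    anchor_disp = []
    for k in range(protocol.n_anchors):
        t, disp = gater.next_state(k * protocol.anchor_interval_s,
                                   protocol.narrow_window_mm)
        anchors.append(
            _render_scan(spec, geom3d, disp, rng, noise_sd=protocol.noise_sd)
        )
        anchor_times.append(t)
        anchor_disp.append(disp)

    slice_geoms = {p: slice_geometry(spec, p, protocol) for p in protocol.planes}

    # sonication plan: cells along the slab intersection line (in both planes)
    n_cells = 3
    z_half = spec.cylinder_height_mm / 4
    zs = np.linspace(-z_half, z_half, n_cells)
    plan = SonicationPlan(
        [SonicationCell(np.array([0.0, 0.0, z])) for z in zs]
    )

    bundles = []
    truth_bundles = []
    for j in range(protocol.n_bundles):
        t_b = anchor_times[j] + protocol.bundle_offset_s
        bundle_truth: dict = {}
        ref2d, nde, sparse, mags, temps = {}, {}, {}, {}, {}
        cell = plan.cells[j % len(plan.cells)]
        for plane in protocol.planes:
            sg = slice_geoms[plane]
            a0, a1 = PLANE_AXES[plane]
            ptruth: dict = {}
            # back-to-back narrow-window scans: sparse anchor, non-distorted
            # EPI, then the (distorted) 2D reference scan
            dt = trace.dt_s
            t_sp, d_sp = gater.next_state(t_b, protocol.narrow_window_mm)
            t_nd, d_nd = gater.next_state(t_sp + dt, protocol.narrow_window_mm)
            t_rf, d_rf = gater.next_state(t_nd + dt, protocol.narrow_window_mm)
            if protocol.extended:
                sparse[plane] = _render_scan(
                    spec, sg, d_sp, rng, noise_sd=protocol.noise_sd
                )
                nde_img = _render_scan(
                    spec, sg, d_nd, rng, contrast="epi",
                    noise_sd=protocol.noise_sd, gamma=protocol.epi_gamma,
                    smooth_vox=protocol.epi_smooth_vox,
                )
                nde[plane] = nde_img
            # injected distortion: calibrated at the structure grid points
            # of the (fixed-frame) non-distorted state
            struct = structure_mask_at(spec, sg, displacement_mm=d_nd)
            g_fld = _calibrated_distortion(
                sg, struct, protocol.distortion_mean_mm,
                protocol.distortion_max_mm, rng,
            )
            g = g_fld.vectors[..., 0]
            # rs4 truth: distortion plus the tiny gated offset between the
            # back-to-back scans (exact for a rigid offset: u = delta + g(.))
            delta = d_rf - d_nd
            ptruth["distortion_truth"] = _rs4_truth_field(sg, g, delta, (a0, a1))
            ptruth["g_injected"] = g_fld
            ref2d[plane] = _render_scan(
                spec, sg, d_rf, rng, contrast="epi",
                distortion_g=g, distortion_axis=0,
                noise_sd=protocol.noise_sd, gamma=protocol.epi_gamma,
                smooth_vox=protocol.epi_smooth_vox,
            )
            # thermometry dynamics in the wide gating window
            mag_frames = []
            temp_frames = []
            dyn_disp = []
            dyn_times = []
            t_prev = t_rf
            material = cell.centre_mm  # reference-frame target position
            for _ in range(protocol.n_dynamics):
                t_d, d_d = gater.next_state(
                    t_prev + protocol.dynamic_dt_s, protocol.thermo_window_mm
                )
                dyn_disp.append(d_d)
                dyn_times.append(t_d)
                mag_frames.append(
                    _render_scan(
                        spec, sg, d_d, rng, contrast="epi",
                        distortion_g=g, distortion_axis=0,
                        noise_sd=protocol.noise_sd, gamma=protocol.epi_gamma,
                        smooth_vox=protocol.epi_smooth_vox,
                    )
                )
                t_prev = t_d
            n_heat = max(int(round(0.6 * protocol.n_dynamics)), 1)
            for f, d_d in enumerate(dyn_disp):
                env = (
                    (f + 1) / n_heat
                    if f < n_heat
                    else float(np.exp(-(f + 1 - n_heat) * protocol.dynamic_dt_s / 12.0))
                )
                temp_frames.append(
                    _render_hotspot_frame(
                        sg, material + (d_d - anchor_disp[0]), env,
                        protocol.hotspot_peak_c, protocol.hotspot_sigma_mm,
                        g, 0,
                    )
                )
            temps[plane] = TemperatureSeries(
                temp_frames, protocol.dynamic_dt_s, plane
            )
            mags[plane] = mag_frames
            ptruth["sparse_displacement"] = d_sp
            ptruth["nde_displacement"] = d_nd
            ptruth["ref2d_displacement"] = d_rf
            ptruth["dynamic_displacements"] = dyn_disp
            ptruth["dynamic_times_s"] = dyn_times
            bundle_truth[plane] = ptruth
        bundle_truth["timestamp_s"] = t_b
        bundle_truth["cell_index"] = j % len(plan.cells)
        bundles.append(
            SonicationBundle(
                timestamp_s=t_b,
                cell_index=j % len(plan.cells),
                ref2d=ref2d,
                thermo_magnitude=mags,
                thermo_temperature=temps,
                nondistorted_epi=nde if protocol.extended else None,
                sparse_anchor=sparse if protocol.extended else None,
            )
        )
        truth_bundles.append(bundle_truth)

    session = TherapySession(
        reference_anchor=anchors[0],
        anchor_times_s=anchor_times,
        anchors=anchors,
        bundles=bundles,
        plan=plan,
        gating={
            "thermometry_mm": protocol.thermo_window_mm,
            "reference_mm": protocol.narrow_window_mm,
        },
    )
    truth = SessionGroundTruth(
        trace=trace,
        reference_displacement=anchor_disp[0],
        anchor_displacements=anchor_disp,
        bundles=truth_bundles,
        spec=spec,
        protocol=protocol,
    )
    return session, truth


def _calibrated_distortion(
    sg: GeomImage,
    struct: ROIMask,
    mean_mm: float,
    max_mm: float,
    rng: np.random.Generator,
) -> DeformationField:
    pts = sg.index_to_world(sg.index_grid())
    inplane = np.stack([pts @ sg.axes_mm[:, 0], pts @ sg.axes_mm[:, 1]], axis=-1)
    extent = (np.asarray(sg.shape) - 1) * sg.voxel_size_mm
    coeffs = rng.uniform(-1.0, 1.0, size=12)
    s = _smooth_basis(inplane, extent, coeffs)
    sel = struct.mask if struct.n_voxels else np.ones(sg.shape, bool)
    centred = s - s[sel].mean()
    peak = max(np.abs(centred[sel]).max(), 1e-12)
    g = mean_mm + centred / peak * (max_mm - mean_mm)
    vectors = np.zeros(sg.shape + (2,))
    vectors[..., 0] = g
    return DeformationField(vectors, sg)


def _rs4_truth_field(
    sg: GeomImage, g: np.ndarray, delta_world: np.ndarray, axes: tuple
) -> DeformationField:
    """Exact RS#4 truth u(r) = delta + g(world(r) + delta) for rigid delta.

    delta is the object displacement of the distorted scan relative to the
    non-distorted one (back-to-back gated scans, typically < 0.5 mm).
    """
    idx = sg.index_grid()
    delta_inplane = np.array([delta_world[axes[0]], delta_world[axes[1]]])
    shifted = idx + delta_inplane / sg.voxel_size_mm
    g_at = ndimage.map_coordinates(
        g, np.moveaxis(shifted, -1, 0), order=1, mode="nearest"
    )
    vectors = np.zeros(sg.shape + (2,))
    vectors[..., 0] = delta_inplane[0] + g_at
    vectors[..., 1] = delta_inplane[1]
    return DeformationField(vectors, sg)


def _render_hotspot_frame(
    sg: GeomImage,
    centre_world: np.ndarray,
    env: float,
    peak_c: float,
    sigma_mm: float,
    distortion_g: np.ndarray | None,
    axis: int,
    baseline_c: float = 37.0,
) -> GeomImage:
    """Temperature frame in the (possibly distorted) scan geometry."""
    idx = sg.index_grid()
    if distortion_g is not None:
        h = sg.voxel_size_mm[axis]
        p = idx[..., axis].copy()
        for _ in range(30):
            g_at = ndimage.map_coordinates(
                distortion_g,
                [p if a == axis else idx[..., a] for a in range(2)],
                order=1,
                mode="nearest",
            )
            p = idx[..., axis] - g_at / h
        idx = idx.copy()
        idx[..., axis] = p
    pts = sg.index_to_world(idx)
    d2 = np.sum((pts - centre_world) ** 2, axis=-1)
    temp = baseline_c + (peak_c - baseline_c) * env * np.exp(-d2 / (2 * sigma_mm**2))
    return GeomImage(temp, sg.affine.copy())
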