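"""Orchestration of the linked registration steps.

The five steps and their roles:

* RS#1  3D-to-3D optical flow between an anatomical anchor and the
        reference anchor: slow physiological drift.
* RS#2  2D-to-2D optical flow between each thermometry magnitude dynamic
        and the 2D reference scan: residual respiratory motion.
* RS#3  2D-to-3D: the anchor volume is reformatted into the 2D scan's
        geometry and the alignment refined with the multi-modal (MIND)
        engine: residual displacement between the 2D scan and its
        preceding anchor, across contrasts.
* RS#4  optical flow between the 2D reference scan and the non-distorted
        EPI scan (both in a narrow gating window): EPI geometric
        distortion, kept separate from motion proper.
* RS#5  like RS#3 but with a sparse anatomical anchor (anchor contrast)
        and the mono-modal engine: a silver standard used only to
        validate RS#3.

Estimated fields flow two ways: sonication plans are propagated
*down-stream* (reference frame -> current anatomy) using the latest RS#1
drift, and per-sonication thermal dose is propagated *up-stream* into the
3D planning frame, correcting distortion first (undoing the scanner-space
warp), then the RS#3 residual, then the RS#1 drift — the order mirroring
acquisition causality.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    DeformationField,
    GeomImage,
    GeometryError,
    compose_fields,
    extract_slices,
    warp_image,
)
from .mind import MINDParams, register_mind
from .optical_flow import OFParams, RegistrationResult, register_of
from .session import (
    BreathingTrace,
    GatingWindow,
    SonicationCell,
    SonicationPlan,
    TherapySession,
)
from .thermal_dose import DoseMap, align_series, cem43


@dataclass
class GatingResult:
    mask: np.ndarray
    duty_cycle: float


def gate(trace: BreathingTrace, window: GatingWindow) -> GatingResult:
    """Acceptance mask over the trace samples plus the duty-cycle fraction."""
    if trace.t_s.size == 0:
        raise ValueError("cannot gate an empty breathing trace")
    mask = window.accepts(trace.position_mm)
    return GatingResult(mask=mask, duty_cycle=float(mask.mean()))


# ---------------------------------------------------------------------------
# registration steps
# ---------------------------------------------------------------------------


def rs1_estimate_drift(
    anchor: GeomImage,
    reference_anchor: GeomImage,
    params: OFParams | None = None,
) -> RegistrationResult:
    """RS#1: 3D drift of an anatomical anchor w.r.t. the reference anchor.

    The returned field u lives on the reference grid and satisfies
    reference(r) ~ anchor(r + u(r)): it carries reference-frame positions
    to the current anatomy, which is exactly what down-stream plan
    propagation needs.
    """
    if not reference_anchor.same_grid(anchor):
        raise GeometryError("anchor and reference anchor are not on one grid")
    return register_of(reference_anchor, anchor, params)


def rs2_estimate_respiratory(
    thermo_magnitude: GeomImage,
    ref2d: GeomImage,
    params: OFParams | None = None,
) -> RegistrationResult:
    """RS#2: per-dynamic residual respiratory motion (2D, same contrast).

    Warping the dynamic's temperature map by the returned field aligns it
    to the 2D reference scan.
    """
    return register_of(ref2d, thermo_magnitude, params)


def rs4_estimate_distortion(
    ref2d_epi: GeomImage,
    nondistorted_epi: GeomImage,
    params: OFParams | None = None,
) -> RegistrationResult:
    """RS#4: EPI geometric distortion of the 2D reference scan.

    Both scans are acquired in a narrow gating window, so the recovered
    field is interpreted as geometric distortion rather than motion.
    Warping the distorted scan (or its dose map) by the field restores
    the undistorted geometry.
    """
    return register_of(nondistorted_epi, ref2d_epi, params)


def _reformat_anchor(anchor3d: GeomImage, scan2d: GeomImage) -> GeomImage:
    if scan2d.ndim != 2:
        raise GeometryError("2D-to-3D registration needs a 2D scan geometry")
    return extract_slices(anchor3d, scan2d)


def rs3_estimate_residual(
    scan2d: GeomImage,
    anchor3d: GeomImage,
    params: MINDParams | None = None,
) -> RegistrationResult:
    """RS#3: residual displacement between a 2D scan and its anchor.

    Two steps: the anchor volume is reformatted into the 2D scan's
    coordinate system (plane extraction), then the in-plane alignment is
    refined with the multi-modal engine since the contrasts differ.
    """
    anchor_slice = _reformat_anchor(anchor3d, scan2d)
    return register_mind(anchor_slice, scan2d, params)


def rs5_silver_standard(
    sparse_anchor: GeomImage,
    anchor3d: GeomImage,
    params: OFParams | None = None,
) -> RegistrationResult:
    """RS#5: mono-modal counterpart of RS#3 on the sparse anatomical anchor.

    The sparse anchor shares the anchor contrast, so optical flow applies;
    by design its field should match the RS#3 field, providing an
    independent (silver standard) validation of the multi-modal step.
    """
    anchor_slice = _reformat_anchor(anchor3d, sparse_anchor)
    return register_of(anchor_slice, sparse_anchor, params)


# ---------------------------------------------------------------------------
# plan and dose propagation
# ---------------------------------------------------------------------------


def propagate_plan_downstream(
    plan: SonicationPlan, drift: DeformationField
) -> SonicationPlan:
    """Re-target sonication cells with the latest drift estimate.

    Each centre is displaced by the drift interpolated at the centre;
    semi-axes and energies are untouched.  Centres displaced outside the
    drift field's grid are flagged (``out_of_extent``), never dropped.
    """
    geom = drift.geometry
    lo = np.zeros(geom.ndim)
    hi = np.asarray(geom.shape, dtype=float) - 1
    cells = []
    for cell in plan.cells:
        disp_axes = drift.sample_at_world(cell.centre_mm[None])[0]
        disp_world = geom.axes_mm @ disp_axes
        new_centre = cell.centre_mm + disp_world
        idx = geom.world_to_index(new_centre[None])[0]
        flagged = bool(np.any(idx < lo) or np.any(idx > hi))
        cells.append(
            SonicationCell(
                centre_mm=new_centre,
                semi_axes_mm=cell.semi_axes_mm.copy(),
                energy_j=cell.energy_j,
                out_of_extent=flagged,
            )
        )
    return SonicationPlan(cells)


def paint_slice_dose(
    dose_slice: GeomImage,
    drift: DeformationField | None,
    planning_geom: GeomImage,
) -> np.ndarray:
    """Deposit a 2D dose plane into a 3D grid through its slice profile.

    Planning voxels whose drift-displaced position falls within half a
    slice thickness of the plane (|normal coordinate| <= 0.5 in the slice's
    full index space; the third affine column is the normal scaled by the
    thickness) sample the plane linearly; everything else receives zero.
    """
    world = planning_geom.index_to_world(planning_geom.index_grid())
    if drift is not None:
        disp_axes = drift.sample_at_world(world)
        world = world + disp_axes @ drift.geometry.axes_mm.T
    full_idx = dose_slice.world_to_full_index(world)
    in_slab = np.abs(full_idx[..., 2]) <= 0.5
    coords = np.moveaxis(full_idx[..., :2], -1, 0)
    vals = ndimage.map_coordinates(
        dose_slice.data, coords, order=1, mode="constant", cval=0.0
    )
    return np.where(in_slab, np.maximum(vals, 0.0), 0.0)


def propagate_dose_upstream(
    dose2d: DoseMap,
    distortion: DeformationField | None,
    residual: DeformationField,
    drift: DeformationField,
    planning_geom: GeomImage,
) -> DoseMap:
    """Map a per-sonication 2D dose into the 3D planning frame.

    The dose (accumulated in the distorted 2D scan frame) is corrected for
    geometric distortion, pulled through the RS#3 residual into the anchor
    frame, and painted into the planning grid through the slice profile
    using the RS#1 drift.  A missing distortion field degrades gracefully
    to the identity (non-extended protocol) with a warning; residual and
    drift are mandatory.
    """
    if residual is None:
        raise ValueError("missing residual (RS#3) field for dose propagation")
    if drift is None:
        raise ValueError("missing drift (RS#1) field for dose propagation")
    if distortion is None:
        _warnings.warn(
            "no distortion (RS#4) field supplied; assuming undistorted scans",
            stacklevel=2,
        )
        total2d = residual
    else:
        total2d = compose_fields(outer=distortion, inner=residual)
    dose_slice, _ = warp_image(dose2d.image, total2d, interp="linear", fill=0.0)
    vol = paint_slice_dose(dose_slice, drift, planning_geom)
    return DoseMap(
        GeomImage(vol, planning_geom.affine.copy()),
        lethal_threshold=dose2d.lethal_threshold,
    )


def combine_plane_doses(doses: list) -> DoseMap:
    """Voxelwise maximum of per-plane dose maps of one sonication.

    The coronal and sagittal thermometry planes observe the same heating
    event; taking the maximum where their slabs overlap avoids double
    counting along the intersection line.
    """
    if not doses:
        raise ValueError("no dose maps to combine")
    geom = doses[0].image
    vals = np.maximum.reduce([d.values for d in doses])
    return DoseMap(GeomImage(vals, geom.affine.copy()), doses[0].lethal_threshold)


def accumulate_doses(doses: list) -> DoseMap:
    """Additive CEM43 accumulation across sonications (planning frame)."""
    if not doses:
        raise ValueError("no dose maps to accumulate")
    geom = doses[0].image
    vals = np.sum([d.values for d in doses], axis=0)
    return DoseMap(GeomImage(vals, geom.affine.copy()), doses[0].lethal_threshold)


# ---------------------------------------------------------------------------
# whole-session run
# ---------------------------------------------------------------------------


@dataclass
class SessionResult:
    drift_results: list
    bundle_results: list
    downstream_plans: list
    dose_corrected: DoseMap
    dose_uncorrected: DoseMap
    report: dict


def run_session(
    session: TherapySession,
    of_params: OFParams | None = None,
    mind_params: MINDParams | None = None,
    planning_geom: GeomImage | None = None,
) -> SessionResult:
    """Execute the complete work-flow on a therapy session.

    Runs RS#1 on every anchor, and per bundle RS#4 (if the extended
    protocol scans are present), RS#3, RS#2 on every thermometry dynamic,
    dose accumulation, and up-stream propagation — once with the estimated
    fields ("corrected") and once with all fields zero ("uncorrected") for
    comparison.  Down-stream propagated plans are produced per anchor.
    """
    if planning_geom is None:
        planning_geom = session.reference_anchor
    reference = session.reference_anchor

    drift_results: list = []
    for anchor in session.anchors:
        if anchor is reference:
            drift_results.append(None)
        else:
            drift_results.append(rs1_estimate_drift(anchor, reference, of_params))

    plans = []
    for i, res in enumerate(drift_results):
        if res is None:
            plans.append(session.plan)
        else:
            plans.append(propagate_plan_downstream(session.plan, res.field))

    bundle_results = []
    corrected: list = []
    uncorrected: list = []
    for bundle in session.bundles:
        ai = session.anchor_index_for(bundle.timestamp_s)
        anchor = session.anchors[ai]
        drift_res = drift_results[ai]
        drift_field = (
            drift_res.field
            if drift_res is not None
            else DeformationField.zero(reference)
        )
        plane_doses = []
        plane_doses_unc = []
        binfo = {"anchor_index": ai, "planes": {}}
        for plane in bundle.planes:
            ref2d = bundle.ref2d[plane]
            dist_res = None
            scan_for_rs3 = ref2d
            if bundle.nondistorted_epi is not None:
                nde = bundle.nondistorted_epi[plane]
                dist_res = rs4_estimate_distortion(ref2d, nde, of_params)
                scan_for_rs3 = nde
            rs3_res = rs3_estimate_residual(scan_for_rs3, anchor, mind_params)
            rs2_fields = [
                rs2_estimate_respiratory(mag, ref2d, of_params).field
                for mag in bundle.thermo_magnitude[plane]
            ]
            series = bundle.thermo_temperature[plane]
            aligned = align_series(series, rs2_fields)
            dose2d = cem43(aligned)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                plane_doses.append(
                    propagate_dose_upstream(
                        dose2d,
                        dist_res.field if dist_res is not None else None,
                        rs3_res.field,
                        drift_field,
                        planning_geom,
                    )
                )
                dose2d_unc = cem43(series)
                plane_doses_unc.append(
                    propagate_dose_upstream(
                        dose2d_unc,
                        None,
                        DeformationField.zero(ref2d),
                        DeformationField.zero(reference),
                        planning_geom,
                    )
                )
            binfo["planes"][plane] = {
                "rs3_mean_mm": float(rs3_res.field.magnitude().mean()),
                "rs4_mean_mm": (
                    float(dist_res.field.magnitude().mean())
                    if dist_res is not None
                    else None
                ),
                "n_dynamics": len(rs2_fields),
            }
        corrected.append(combine_plane_doses(plane_doses))
        uncorrected.append(combine_plane_doses(plane_doses_unc))
        bundle_results.append(binfo)

    dose_c = accumulate_doses(corrected)
    dose_u = accumulate_doses(uncorrected)
    report = {
        "n_anchors": len(session.anchors),
        "n_bundles": len(session.bundles),
        "drift_mean_mm": [
            float(r.field.magnitude().mean()) if r is not None else 0.0
            for r in drift_results
        ],
        "bundles": bundle_results,
    }
    return SessionResult(
        drift_results=drift_results,
        bundle_results=bundle_results,
        downstream_plans=plans,
        dose_corrected=dose_c,
        dose_uncorrected=dose_u,
        report=report,
    )
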