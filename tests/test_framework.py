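import numpy as np
import pytest

from hifutrack.framework import (
    combine_plane_doses,
    accumulate_doses,
    gate,
    paint_slice_dose,
    propagate_dose_upstream,
    propagate_plan_downstream,
    rs1_estimate_drift,
    rs2_estimate_respiratory,
    rs3_estimate_residual,
    rs4_estimate_distortion,
    rs5_silver_standard,
)
from hifutrack.geometry import (
    DeformationField,
    GeomImage,
    axis_aligned_affine,
    extract_slices,
)
from hifutrack.metrics import endpoint_error
from hifutrack.phantom import PLANE_AXES, make_breathing_trace, structure_mask_at
from hifutrack.session import GatingWindow, SonicationCell, SonicationPlan
from hifutrack.thermal_dose import DoseMap


class TestGating:
    def test_trace_inside_window_has_unit_duty_cycle(self):
        trace = make_breathing_trace(60.0, period_s=4.0, amplitude_mm=1.0, seed=0)
        res = gate(trace, GatingWindow(0.0, 10.0))
        assert res.duty_cycle == 1.0
        assert res.mask.all()

    def test_narrowing_window_never_increases_acceptance(self):
        trace = make_breathing_trace(120.0, amplitude_mm=5.0, seed=1)
        wide = gate(trace, GatingWindow(-5.0, 5.0))
        narrow = gate(trace, GatingWindow(-5.0, 2.0))
        assert narrow.duty_cycle <= wide.duty_cycle
        assert not np.any(narrow.mask & ~wide.mask)

    def test_sinusoid_duty_cycle_matches_closed_form(self):
        # window centred on zero: accepted fraction = (2/pi) arcsin(w / 2A)
        amp, width = 5.0, 4.0
        trace = make_breathing_trace(400.0, period_s=4.0, amplitude_mm=amp,
                                     dt_s=0.01, seed=0)
        res = gate(trace, GatingWindow(0.0, width))
        expect = 2.0 / np.pi * np.arcsin(width / (2 * amp))
        assert res.duty_cycle == pytest.approx(expect, abs=0.01)

    def test_empty_trace_rejected(self):
        from hifutrack.session import BreathingTrace

        empty = BreathingTrace(np.array([]), np.array([]), 0.1)
        with pytest.raises(ValueError, match="empty"):
            gate(empty, GatingWindow(0.0, 5.0))


class TestRegistrationSteps:
    def test_rs1_identical_anchor_gives_zero_field(self, tiny_session):
        _, _, session, _ = tiny_session
        res = rs1_estimate_drift(session.reference_anchor, session.reference_anchor)
        assert np.abs(res.field.vectors).max() < 0.2

    def test_rs1_recovers_injected_drift_magnitude(self, tiny_session):
        spec, _, session, truth = tiny_session
        roi = structure_mask_at(
            spec, session.reference_anchor,
            displacement_mm=truth.reference_displacement,
        )
        k = len(session.anchors) - 1
        res = rs1_estimate_drift(session.anchors[k], session.reference_anchor)
        gt = truth.rs1_truth(k)
        rec = res.field.vectors[roi.mask].mean(axis=0)
        assert abs(np.linalg.norm(rec) - np.linalg.norm(gt)) < 0.5

    def test_rs1_drift_is_cumulative_across_events(self, tiny_session):
        spec, _, session, truth = tiny_session
        # truth bookkeeping: later anchors carry the sum of both steps
        drifts = [np.linalg.norm(truth.rs1_truth(k)) for k in range(len(session.anchors))]
        assert drifts[-1] > drifts[1] - 1.0
        events = truth.trace.drift_events
        total = np.linalg.norm(sum(v for _, v in events))
        assert np.linalg.norm(truth.trace.drift_at(1e9)) == pytest.approx(total)

    def test_rs2_recovers_residual_translation(self, tiny_session):
        _, _, session, truth = tiny_session
        b = session.bundles[0]
        bt = truth.bundles[0]
        plane = "coronal"
        a0, a1 = PLANE_AXES[plane]
        ref2d = b.ref2d[plane]
        mag = b.thermo_magnitude[plane][0]
        gt3 = bt[plane]["dynamic_displacements"][0] - bt[plane]["ref2d_displacement"]
        res = rs2_estimate_respiratory(mag, ref2d)
        inner = res.field.vectors[4:-4, 3:-3].reshape(-1, 2)
        np.testing.assert_allclose(
            inner.mean(axis=0), [gt3[a0], gt3[a1]], atol=0.6
        )

    def test_rs4_zero_distortion_gives_near_zero_field(self, tiny_session):
        _, _, session, _ = tiny_session
        nde = session.bundles[0].nondistorted_epi["coronal"]
        res = rs4_estimate_distortion(nde, nde)
        assert np.abs(res.field.vectors).max() < 0.1

    def test_rs4_recovers_injected_distortion(self, tiny_session):
        spec, _, session, truth = tiny_session
        b, bt = session.bundles[0], truth.bundles[0]
        plane = "sagittal"
        res = rs4_estimate_distortion(b.ref2d[plane], b.nondistorted_epi[plane])
        gt = bt[plane]["distortion_truth"]
        pts = structure_mask_at(
            spec, b.nondistorted_epi[plane],
            displacement_mm=bt[plane]["nde_displacement"],
        )
        resid = np.linalg.norm((res.field.vectors - gt.vectors)[pts.mask], axis=-1)
        assert resid.mean() < 1.0
        assert np.percentile(resid, 95) < 2.5

    def test_injected_distortion_is_phase_encode_only(self, tiny_session):
        _, _, _, truth = tiny_session
        gt = truth.bundles[0]["coronal"]["g_injected"]
        np.testing.assert_array_equal(gt.vectors[..., 1], 0.0)

    def test_rs3_and_rs5_silver_standard_agree_sub_voxel(self, tiny_session):
        spec, _, session, truth = tiny_session
        b = session.bundles[0]
        plane = "coronal"
        anchor = session.anchors[session.anchor_index_for(b.timestamp_s)]
        rs3 = rs3_estimate_residual(b.nondistorted_epi[plane], anchor)
        rs5 = rs5_silver_standard(b.sparse_anchor[plane], anchor)
        roi = structure_mask_at(
            spec, b.nondistorted_epi[plane],
            displacement_mm=truth.anchor_displacements[
                session.anchor_index_for(b.timestamp_s)
            ],
        )
        ee = endpoint_error(rs3.field, rs5.field, roi)
        voxel = b.nondistorted_epi[plane].voxel_size_mm.min()
        assert np.percentile(ee, 95) < voxel

    def test_rs3_near_zero_for_zero_residual(self, tiny_session):
        spec, _, session, truth = tiny_session
        # synthesise a scan exactly at the anchor state: residual is zero
        from hifutrack.phantom import _render_scan, slice_geometry

        _, protocol, _, _ = tiny_session
        sg = slice_geometry(spec, "coronal", protocol)
        rng = np.random.default_rng(0)
        scan = _render_scan(
            spec, sg, truth.anchor_displacements[0], rng, contrast="epi",
            noise_sd=0.01,
        )
        res = rs3_estimate_residual(scan, session.anchors[0])
        roi = structure_mask_at(spec, sg, displacement_mm=truth.anchor_displacements[0])
        assert res.field.magnitude()[roi.mask].mean() < 0.5


class TestPlanPropagation:
    def _plan(self):
        return SonicationPlan(
            [
                SonicationCell(np.array([0.0, 0.0, 0.0]), (2.0, 2.0, 2.0), 5000.0),
                SonicationCell(np.array([10.0, -5.0, 5.0]), (2.0, 3.0, 2.0), 7000.0),
            ]
        )

    def _geom(self):
        return GeomImage(
            np.zeros((20, 20, 20)),
            axis_aligned_affine((2.0, 2.0, 2.0), origin=(-19.0, -19.0, -19.0)),
        )

    def test_zero_drift_leaves_plan_unchanged(self):
        plan = self._plan()
        out = propagate_plan_downstream(plan, DeformationField.zero(self._geom()))
        for a, b in zip(out.cells, plan.cells):
            np.testing.assert_allclose(a.centre_mm, b.centre_mm)
            assert a.energy_j == b.energy_j

    def test_uniform_translation_shifts_all_centres(self):
        geom = self._geom()
        v = np.zeros(geom.shape + (3,))
        v[..., 2] = 5.0
        out = propagate_plan_downstream(self._plan(), DeformationField(v, geom))
        for a, b in zip(out.cells, self._plan().cells):
            np.testing.assert_allclose(a.centre_mm - b.centre_mm, [0, 0, 5.0])

    def test_smooth_field_matches_pointwise_interpolation(self, rng):
        from scipy.ndimage import gaussian_filter

        geom = self._geom()
        v = 5.0 * np.stack(
            [gaussian_filter(rng.normal(size=geom.shape), 4.0) for _ in range(3)], -1
        )
        fld = DeformationField(v, geom)
        plan = self._plan()
        out = propagate_plan_downstream(plan, fld)
        for a, b in zip(out.cells, plan.cells):
            expect = b.centre_mm + fld.sample_at_world(b.centre_mm[None])[0]
            np.testing.assert_allclose(a.centre_mm, expect, atol=1e-9)

    def test_cell_count_and_energy_preserved(self):
        plan = self._plan()
        out = propagate_plan_downstream(plan, DeformationField.zero(self._geom()))
        assert len(out) == len(plan)
        assert out.total_energy_j() == plan.total_energy_j()

    def test_centre_leaving_extent_is_flagged_not_dropped(self):
        geom = self._geom()
        v = np.zeros(geom.shape + (3,))
        v[..., 0] = 100.0
        out = propagate_plan_downstream(self._plan(), DeformationField(v, geom))
        assert len(out) == 2
        assert all(c.out_of_extent for c in out.cells)


def make_dose_slice(offset_idx=(10, 10), value=300.0):
    from hifutrack.geometry import slice_affine

    aff = slice_affine((0, 2), (2.0, 2.0), origin=(-20.0, 0.0, -20.0), thickness_mm=7.0)
    data = np.zeros((21, 21))
    data[offset_idx] = value
    return DoseMap(GeomImage(data, aff))


def planning_geom_3d():
    return GeomImage(
        np.zeros((21, 21, 21)),
        axis_aligned_affine((2.0, 2.0, 2.0), origin=(-20.0, -20.0, -20.0)),
    )


class TestDosePropagation:
    def test_zero_fields_place_dose_at_nominal_location(self):
        dose = make_dose_slice()
        pg = planning_geom_3d()
        with pytest.warns(UserWarning, match="distortion"):
            out = propagate_dose_upstream(
                dose, None, DeformationField.zero(dose.image),
                DeformationField.zero(pg), pg,
            )
        peak = np.unravel_index(np.argmax(out.values), out.values.shape)
        world = pg.index_to_world(np.asarray(peak, float)[None])[0]
        expect = dose.image.index_to_world(np.array([10.0, 10.0])[None])[0]
        assert abs(world[0] - expect[0]) <= 2.0
        assert abs(world[2] - expect[2]) <= 2.0
        # deposited through the 7 mm slab: ~3 planes of 2 mm voxels
        planes = np.unique(np.nonzero(out.values)[1])
        assert 2 <= planes.size <= 5

    def test_pure_drift_moves_dose_centroid(self):
        dose = make_dose_slice()
        pg = planning_geom_3d()
        drift = np.zeros(pg.shape + (3,))
        drift[..., 2] = 5.0

        def centroid(vol):
            w = vol.values
            idx = pg.index_grid()
            return (w[..., None] * idx).sum(axis=(0, 1, 2)) / w.sum()

        with pytest.warns(UserWarning):
            base = propagate_dose_upstream(
                dose, None, DeformationField.zero(dose.image),
                DeformationField.zero(pg), pg,
            )
            moved = propagate_dose_upstream(
                dose, None, DeformationField.zero(dose.image),
                DeformationField(drift, pg), pg,
            )
        shift_mm = (centroid(base) - centroid(moved)) * 2.0
        # a +5 mm drift means the anatomy at reference z sits at z+5 in the
        # current frame, so its dose is pulled back 5 mm up-stream
        assert shift_mm[2] == pytest.approx(5.0, abs=1.0)

    def test_missing_required_fields_raise_named_errors(self):
        dose = make_dose_slice()
        pg = planning_geom_3d()
        with pytest.raises(ValueError, match="RS#3"):
            propagate_dose_upstream(dose, None, None, DeformationField.zero(pg), pg)
        with pytest.raises(ValueError, match="RS#1"):
            propagate_dose_upstream(
                dose, None, DeformationField.zero(dose.image), None, pg
            )

    def test_dose_mass_preserved_for_inbounds_hotspot(self):
        from hifutrack.geometry import slice_affine

        aff = slice_affine((0, 2), (2.0, 2.0), origin=(-20.0, 0.0, -20.0), thickness_mm=7.0)
        x = np.arange(21) * 2.0 - 20.0
        X, Z = np.meshgrid(x, x, indexing="ij")
        dose2d = 500.0 * np.exp(-(X**2 + Z**2) / 30.0)
        dose = DoseMap(GeomImage(dose2d, aff))
        pg = planning_geom_3d()
        with pytest.warns(UserWarning):
            out = propagate_dose_upstream(
                dose, None, DeformationField.zero(dose.image),
                DeformationField.zero(pg), pg,
            )
        # integral conservation: 2D dose * in-plane area * slab thickness
        # versus 3D dose * voxel volume
        mass2d = dose.values.sum() * 2.0 * 2.0 * 7.0
        mass3d = out.values.sum() * 2.0 * 2.0 * 2.0
        assert mass3d == pytest.approx(mass2d, rel=0.15)

    def test_plane_combination_and_accumulation(self):
        d1 = make_dose_slice(value=100.0)
        d2 = make_dose_slice(value=300.0)
        pg = planning_geom_3d()
        zero2 = DeformationField.zero(d1.image)
        zero3 = DeformationField.zero(pg)
        with pytest.warns(UserWarning):
            v1 = propagate_dose_upstream(d1, None, zero2, zero3, pg)
            v2 = propagate_dose_upstream(d2, None, zero2, zero3, pg)
        combined = combine_plane_doses([v1, v2])
        np.testing.assert_allclose(
            combined.values, np.maximum(v1.values, v2.values)
        )
        total = accumulate_doses([v1, v2])
        np.testing.assert_allclose(total.values, v1.values + v2.values)
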