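import numpy as np
import pytest

from hifutrack.geometry import GeomImage, axis_aligned_affine, warp_image
from hifutrack.mind import compute_mind, mind_distance
from hifutrack.phantom import (
    PLANE_AXES,
    PhantomSpec,
    ProtocolConfig,
    acquire_session,
    epi_contrast_transform,
    epi_intensity_remap,
    make_breathing_trace,
    make_grid_phantom,
    phantom_intensity,
    simulate_epi_distortion,
    simulate_temperature_series,
    structure_mask_at,
)
from hifutrack.thermal_dose import cem43


class TestGridPhantom:
    def test_same_seed_is_bit_identical(self, small_spec):
        a, _ = make_grid_phantom(small_spec, seed=3)
        b, _ = make_grid_phantom(small_spec, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_noise_two_intensity_levels_inside_cylinder(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, noise_sd=0.0)
        img, _ = make_grid_phantom(spec)
        geom = spec.geometry()
        pts = geom.index_to_world(geom.index_grid())
        # interior of the cylinder, away from all transition ramps
        from hifutrack.phantom import phantom_cylinder_fraction, phantom_structure_fraction

        cyl = phantom_cylinder_fraction(spec, pts, margin_mm=3.0) >= 1.0
        frac = phantom_structure_fraction(spec, pts)
        plateau = (frac == 0.0) | (frac == 1.0)
        values = np.unique(np.round(img.data[cyl & plateau], 12))
        assert set(values) == {spec.structure_intensity, spec.gel_intensity}

    def test_central_coronal_slice_shows_grid_cross_section(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, noise_sd=0.0)
        img, _ = make_grid_phantom(spec)
        j_mid = spec.shape[1] // 2  # slab plane y ~ -1 mm, inside slab
        sl = img.data[:, j_mid, :]
        geom = spec.geometry()
        xs = geom.index_to_world(geom.index_grid())[:, j_mid, :, 0]
        zs = geom.index_to_world(geom.index_grid())[:, j_mid, :, 2]
        on_bar = (
            np.abs(((xs + 8.0) % 16.0) - 8.0) < 1.2
        ) | (np.abs(((zs + 8.0) % 16.0) - 8.0) < 1.2)
        inside = np.hypot(
            geom.index_to_world(geom.index_grid())[:, j_mid, :, 0],
            geom.index_to_world(geom.index_grid())[:, j_mid, :, 1],
        ) < spec.cylinder_radius_mm - 4
        inside &= np.abs(zs) < spec.cylinder_height_mm / 2 - 4
        assert (sl[on_bar & inside] < 0.5).mean() > 0.95
        assert (sl[~on_bar & inside] > 0.5).mean() > 0.95

    def test_structure_roi_nonempty_and_on_structures(self, small_spec):
        img, roi = make_grid_phantom(small_spec, seed=0)
        assert roi.n_voxels > 100
        assert img.data[roi.mask].mean() < 0.5  # structures are dark

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="bar thickness"):
            PhantomSpec(bar_thickness_mm=20.0, grid_spacing_mm=16.0)
        with pytest.raises(ValueError, match="field of view|cylinder"):
            PhantomSpec(shape=(32, 32, 10), cylinder_radius_mm=80.0)


class TestBreathingTrace:
    def test_pure_sinusoid_without_jitter(self):
        trace = make_breathing_trace(40.0, period_s=4.0, amplitude_mm=5.0, seed=0)
        assert trace.position_mm.max() == pytest.approx(5.0, abs=0.01)
        assert trace.position_mm.min() == pytest.approx(-5.0, abs=0.01)
        # extrema at quarter-period offsets
        t_peak = trace.t_s[np.argmax(trace.position_mm)]
        assert (t_peak % 4.0) == pytest.approx(1.0, abs=0.1)

    def test_single_drift_shifts_post_event_mean_by_5mm(self):
        ev = [(30.0, np.array([0.0, 0.0, 5.0]))]
        trace = make_breathing_trace(
            60.0, period_s=4.0, amplitude_mm=5.0, drift_events=ev, seed=0
        )
        pre = trace.position_mm[trace.t_s < 28.0]
        post = trace.position_mm[trace.t_s >= 32.0]
        assert post.mean() - pre.mean() == pytest.approx(5.0, abs=0.4)

    def test_two_drifts_accumulate_to_10mm(self):
        ev = [(20.0, np.array([0, 0, 5.0])), (40.0, np.array([0, 0, 5.0]))]
        trace = make_breathing_trace(60.0, drift_events=ev, seed=1)
        np.testing.assert_allclose(trace.drift_at(59.0), [0, 0, 10.0])
        np.testing.assert_allclose(trace.drift_at(30.0), [0, 0, 5.0])
        np.testing.assert_allclose(trace.drift_at(10.0), [0, 0, 0.0])

    def test_drift_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_breathing_trace(
                30.0, drift_events=[(50.0, np.array([0, 0, 5.0]))], seed=0
            )

    def test_quasi_periodic_jitter_is_seeded(self):
        a = make_breathing_trace(60.0, seed=5)
        b = make_breathing_trace(60.0, seed=5)
        np.testing.assert_array_equal(a.position_mm, b.position_mm)


class TestEpiContrast:
    def test_remap_is_monotone(self):
        x = np.linspace(0, 1, 200)
        y = epi_intensity_remap(x)
        assert (np.diff(y) > 0).all()

    def test_order_statistics_preserved_pre_noise(self, rng):
        vals = rng.uniform(size=(20, 20))
        img = GeomImage(vals, axis_aligned_affine((1.0, 1.0)))
        out = epi_contrast_transform(img, smooth_sigma_vox=0.0, noise_sd=0.0)
        np.testing.assert_array_equal(
            np.argsort(vals.ravel()), np.argsort(out.data.ravel())
        )

    def test_mind_descriptors_stable_across_contrast(self, small_spec):
        img, roi = make_grid_phantom(small_spec, seed=0)
        j_mid = small_spec.shape[1] // 2
        sl = GeomImage(img.data[:, j_mid, :], axis_aligned_affine((2.0, 2.0)))
        other = epi_contrast_transform(sl, seed=1, noise_sd=0.0)
        s = mind_distance(compute_mind(sl), compute_mind(other))
        assert s[roi.mask[:, j_mid, :]].mean() < 0.1


class TestDistortionSimulation:
    def _slice(self, small_spec):
        img, roi = make_grid_phantom(small_spec, seed=0)
        j_mid = small_spec.shape[1] // 2
        return (
            GeomImage(img.data[:, j_mid, :], axis_aligned_affine((2.0, 2.0))),
            roi.mask[:, j_mid, :],
        )

    def test_zero_amplitude_is_identity(self, small_spec):
        sl, _ = self._slice(small_spec)
        out, fld = simulate_epi_distortion(sl, max_mm=0.0, mean_mm=0.0, seed=0)
        np.testing.assert_allclose(out.data, sl.data, atol=1e-9)
        np.testing.assert_array_equal(fld.vectors, 0.0)

    def test_off_axis_component_exactly_zero(self, small_spec):
        sl, mask = self._slice(small_spec)
        from hifutrack.geometry import ROIMask

        _, fld = simulate_epi_distortion(sl, axis=0, points=ROIMask(mask), seed=0)
        np.testing.assert_array_equal(fld.vectors[..., 1], 0.0)

    def test_calibrated_mean_and_max_at_grid_points(self, small_spec):
        sl, mask = self._slice(small_spec)
        from hifutrack.geometry import ROIMask

        _, fld = simulate_epi_distortion(
            sl, max_mm=4.0, mean_mm=3.0, points=ROIMask(mask), seed=2
        )
        mags = np.linalg.norm(fld.vectors[mask], axis=-1)
        assert mags.mean() == pytest.approx(3.0, rel=0.05)
        assert mags.max() == pytest.approx(4.0, rel=0.05)

    def test_true_field_undoes_the_distortion(self, small_spec):
        sl, mask = self._slice(small_spec)
        from hifutrack.geometry import ROIMask

        distorted, fld = simulate_epi_distortion(
            sl, max_mm=4.0, mean_mm=3.0, points=ROIMask(mask), seed=2
        )
        undone, valid = warp_image(distorted, fld)
        interior = valid.mask.copy()
        interior[:3] = interior[-3:] = False
        interior[:, :3] = interior[:, -3:] = False
        err = np.abs(undone.data - sl.data)[interior]
        # two linear interpolations across sub-voxel edge ramps bound the
        # achievable agreement; displacements themselves are exact
        assert np.percentile(err, 95) < 0.25 * np.ptp(sl.data)
        assert err.mean() < 0.1 * np.ptp(sl.data)

    def test_infeasible_magnitudes_rejected(self, small_spec):
        sl, _ = self._slice(small_spec)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_epi_distortion(sl, max_mm=3.0, mean_mm=5.0)


class TestTemperatureSeries:
    def _geom(self):
        return GeomImage(
            np.zeros((41, 41)),
            axis_aligned_affine((1.0, 1.0), origin=(-20.0, -20.0, 0.0)),
        )

    def test_peak_frame_attains_configured_peak(self):
        series = simulate_temperature_series(
            self._geom(), (0.0, 0.0, 0.0), peak_c=56.0, n_frames=10, dt_s=3.0
        )
        peaks = [f.data.max() for f in series.frames]
        assert max(peaks) == pytest.approx(56.0, abs=0.01)

    def test_static_hotspot_centroid_fixed(self):
        series = simulate_temperature_series(
            self._geom(), (2.0, -3.0, 0.0), n_frames=8, dt_s=2.0
        )
        for f in series.frames:
            i, j = np.unravel_index(np.argmax(f.data), f.data.shape)
            world = f.index_to_world(np.array([i, j], float)[None])[0]
            np.testing.assert_allclose(world[:2], [2.0, -3.0], atol=1.0)

    def test_static_56c_hotspot_is_lethal_at_centre(self):
        # 30 s at up to 56 degC: compare against the term-by-term closed form
        series = simulate_temperature_series(
            self._geom(), (0.0, 0.0, 0.0), peak_c=56.0, n_frames=15, dt_s=2.0
        )
        dose = cem43(series)
        centre = dose.values[20, 20]
        temps = [f.data[20, 20] for f in series.frames]
        expect = sum(
            (0.5 if t >= 43 else 0.25) ** (43.0 - t) * 2.0 / 60.0 for t in temps
        )
        assert centre == pytest.approx(expect, rel=1e-9)
        assert centre > 240.0

    def test_residual_motion_translates_hotspot(self):
        res = np.zeros((6, 2))
        res[:, 0] = 4.0
        series = simulate_temperature_series(
            self._geom(), (0.0, 0.0, 0.0), n_frames=6, dt_s=2.0, residuals_mm=res
        )
        f = series.frames[3]
        i, j = np.unravel_index(np.argmax(f.data), f.data.shape)
        world = f.index_to_world(np.array([i, j], float)[None])[0]
        assert world[0] == pytest.approx(4.0, abs=1.0)


class TestSessionBookkeeping:
    def test_anchor_drift_states_follow_the_two_events(self, tiny_session):
        _, _, session, truth = tiny_session
        # 4 anchors with drifts injected after anchors 3 and... clamped: the
        # generated events are recorded exactly in the trace
        events = truth.trace.drift_events
        for k, t in enumerate(session.anchor_times_s):
            expect = sum((v for te, v in events if te <= t), np.zeros(3))
            drift_part = truth.anchor_displacements[k] - np.array(
                [0, 0, truth.trace.breathing_mm()[0]]
            )
            got = truth.trace.drift_at(t)
            np.testing.assert_allclose(got, expect)

    def test_full_protocol_drift_schedule(self):
        spec = PhantomSpec(
            shape=(48, 48, 20), cylinder_radius_mm=40.0,
            cylinder_height_mm=28.0, border_margin_mm=6.0,
        )
        protocol = ProtocolConfig(n_anchors=9, n_bundles=0, n_dynamics=0)
        session, truth = acquire_session(spec, None, protocol, seed=2)
        mags = [np.linalg.norm(truth.rs1_truth(k)) for k in range(9)]
        # anchors 1-3 (0-based 0-2): no drift; 4-6: ~5 mm; 7-9: ~10 mm
        for k in (1, 2):
            assert mags[k] < 2.5
        for k in (3, 4, 5):
            assert mags[k] == pytest.approx(5.0, abs=2.5)
        for k in (6, 7, 8):
            assert mags[k] == pytest.approx(10.0, abs=2.5)

    def test_thermo_residuals_bounded_by_gating_window(self, tiny_session):
        _, protocol, session, truth = tiny_session
        trough = truth.trace.breathing_mm().min()
        for bt in truth.bundles:
            for plane in ("coronal", "sagittal"):
                for d, t in zip(
                    bt[plane]["dynamic_displacements"], bt[plane]["dynamic_times_s"]
                ):
                    breathing = d[2] - truth.trace.drift_at(t)[2]
                    # within the acceptance band above the exhale trough
                    assert breathing >= trough - 1e-9
                    assert breathing <= trough + protocol.thermo_window_mm + 1e-9

    def test_session_is_deterministic_under_seed(self, small_spec):
        protocol = ProtocolConfig(n_anchors=2, n_bundles=1, n_dynamics=2)
        s1, t1 = acquire_session(small_spec, None, protocol, seed=11)
        s2, t2 = acquire_session(small_spec, None, protocol, seed=11)
        np.testing.assert_array_equal(
            s1.reference_anchor.data, s2.reference_anchor.data
        )
        b1, b2 = s1.bundles[0], s2.bundles[0]
        np.testing.assert_array_equal(
            b1.ref2d["coronal"].data, b2.ref2d["coronal"].data
        )
        np.testing.assert_array_equal(
            b1.thermo_temperature["sagittal"].frames[0].data,
            b2.thermo_temperature["sagittal"].frames[0].data,
        )

    def test_every_scan_has_a_ground_truth_record(self, tiny_session):
        _, _, session, truth = tiny_session
        assert len(truth.anchor_displacements) == len(session.anchors)
        assert len(truth.bundles) == len(session.bundles)
        for bt, b in zip(truth.bundles, session.bundles):
            for plane in b.planes:
                assert "distortion_truth" in bt[plane]
                assert len(bt[plane]["dynamic_displacements"]) == len(
                    b.thermo_magnitude[plane]
                )
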