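"""Synthetic renderer: profile constructions, photometry, scripted ramps."""

import numpy as np
import pytest

import dropwet as dw
from dropwet.synthetic import make_side_profile

from conftest import side_config, top_config


class TestSideProfile:
    def test_semicircular_profile_for_90_degree_cap(self):
        geom = dw.DropletGeometry.spherical_cap(90, 4.0, rear_pinned_x=0.0)
        prof = make_side_profile(geom, 2001)
        # points lie on the circle of radius L/2 centred mid-chord
        r = np.hypot(prof[:, 0] - 2.0, prof[:, 1])
        assert np.allclose(r, 2.0, atol=1e-12)
        assert prof[:, 1].max() == pytest.approx(2.0, abs=1e-12)
        # near-edge tangent is vertical (90 deg)
        d = prof[1] - prof[0]
        ang = np.degrees(np.arctan2(d[1], d[0]))
        assert ang == pytest.approx(90.0, abs=1.0)

    def test_symmetric_cap_matches_analytic_circle(self):
        theta, L = 67.0, 3.0
        geom = dw.DropletGeometry.spherical_cap(theta, L, rear_pinned_x=0.0)
        prof = make_side_profile(geom, 1001)
        R = L / (2 * np.sin(np.deg2rad(theta)))
        zc = -R * np.cos(np.deg2rad(theta))
        assert np.allclose(np.hypot(prof[:, 0] - L / 2, prof[:, 1] - zc), R,
                           atol=1e-12)
        # endpoint tangents measured through the liquid equal theta
        d0 = prof[1] - prof[0]
        d1 = prof[-1] - prof[-2]
        rear = np.degrees(np.arctan2(d0[1], d0[0]))
        front = np.degrees(np.arctan2(-d1[1], d1[0]))
        assert rear == pytest.approx(theta, abs=0.1)
        assert front == pytest.approx(theta, abs=0.1)

    def test_asymmetric_quartic_edge_slopes(self):
        geom = dw.DropletGeometry.tear(40, 5, 3.0, rear_pinned_x=0.0)
        prof = make_side_profile(geom, 20001)
        d0 = prof[1] - prof[0]
        d1 = prof[-1] - prof[-2]
        rear = np.degrees(np.arctan2(d0[1], d0[0]))
        front = np.degrees(np.arctan2(-d1[1], d1[0]))
        assert rear == pytest.approx(5.0, abs=0.1)
        assert front == pytest.approx(40.0, abs=0.1)
        assert prof[:, 1].max() == pytest.approx(geom.max_height, rel=1e-6)

    def test_steep_asymmetric_profile_rejected(self):
        geom = dw.DropletGeometry(theta_front=110, theta_rear=40,
                                  contact_length=3.0, bulky_length=3.0,
                                  max_height=1.5)
        with pytest.raises(ValueError, match="multivalued"):
            make_side_profile(geom)

    def test_cap_volume_of_revolution_matches_closed_form(self):
        theta, L = 67.0, 3.0
        geom = dw.DropletGeometry.spherical_cap(theta, L, rear_pinned_x=0.0)
        prof = make_side_profile(geom, 801)
        R = L / (2 * np.sin(np.deg2rad(theta)))
        h = geom.max_height
        v_exact = np.pi * h ** 2 * (3 * R - h) / 3
        baseline = dw.Baseline((0.0, 0.0), (L, 0.0))
        # profile z is up; geometry uses image coordinates (y down)
        contour = np.column_stack([prof[:, 0], -prof[:, 1]])
        v = dw.estimate_volume(contour, baseline)
        assert v == pytest.approx(v_exact, rel=0.01)

    def test_geometry_invariants_enforced(self):
        with pytest.raises(ValueError):
            dw.DropletGeometry(theta_front=0, theta_rear=10, contact_length=3,
                               bulky_length=3, max_height=1)
        with pytest.raises(ValueError):
            dw.DropletGeometry(theta_front=60, theta_rear=10, contact_length=3,
                               bulky_length=4, max_height=1)
        with pytest.raises(ValueError):
            dw.DropletGeometry(theta_front=60, theta_rear=10, contact_length=3,
                               bulky_length=3, max_height=1,
                               body_gray=200, tail_gray=100)


class TestRenderSide:
    def test_noiseless_image_has_exactly_three_tones(self, tailed_side):
        _, frame = tailed_side
        grays = np.unique(frame.pixels)
        assert set(grays.tolist()) == {10, 180, 230}

    def test_rendering_is_deterministic_under_fixed_seed(self):
        geom = dw.DropletGeometry.spherical_cap(67, 3.0, rear_pinned_x=0.7)
        cfg = side_config(noise_sigma=2.0, seed=42)
        a = dw.render_side_view(geom, cfg)
        b = dw.render_side_view(geom, cfg)
        assert np.array_equal(a.pixels, b.pixels)

    def test_column_mean_intensity_decreases_from_tail_to_body(self, tailed_side):
        geom, frame = tailed_side
        s = frame.mm_per_px
        cols = frame.pixels.mean(axis=0)
        tail_cols = cols[int((geom.x_rear + 0.3) / s):int((geom.x_bulky_rear - 0.1) / s)]
        body_cols = cols[int((geom.x_bulky_rear + 0.3) / s):int((geom.x_front - 0.3) / s)]
        assert tail_cols.mean() > body_cols.mean()
        assert frame.pixels.max() == 230  # background is the brightest tone

    def test_out_of_frame_error_names_direction(self):
        geom = dw.DropletGeometry.spherical_cap(67, 3.0, rear_pinned_x=4.0)
        with pytest.raises(ValueError, match="right"):
            dw.render_side_view(geom, side_config())
        tall = dw.DropletGeometry.spherical_cap(110, 3.0, rear_pinned_x=0.7)
        with pytest.raises(ValueError, match="top"):
            dw.render_side_view(tall, side_config(image_height_px=200))

    def test_tail_pixels_stay_behind_the_bulky_region(self, tailed_side):
        geom, frame = tailed_side
        tail = frame.pixels == 180
        body = frame.pixels == 10
        assert tail.any() and body.any()
        last_tail_col = np.nonzero(tail.any(axis=0))[0].max()
        first_body_col = np.nonzero(body.any(axis=0))[0].min()
        assert last_tail_col < first_body_col
        # tail is a thin wedge, at most ~2 px tall
        assert tail.sum(axis=0).max() <= 3


class TestRenderTop:
    def test_no_rotation_projects_to_major_axis(self):
        geom = dw.DropletGeometry(theta_front=67, theta_rear=30,
                                  contact_length=4.0, bulky_length=4.0,
                                  max_height=1.0, alpha_A=0.0,
                                  top_minor_axis=2.4, rear_pinned_x=1.0)
        _, truth = dw.render_top_view(geom, top_config(jaggedness_amplitude=0))
        assert truth["A_max"] == pytest.approx(4.0, abs=1e-12)
        assert truth["whole"]["phi_deg"] == 0.0

    def test_smooth_boundary_recovered_by_ellipse_fit(self, smooth_top):
        _, frame, truth = smooth_top
        seg = dw.segment_regions(frame, dw.ThresholdPair(95, 205))
        fit = dw.fit_ellipse(seg.contour_whole)
        px = frame.mm_per_px
        assert abs(fit.a - truth["whole"]["a"]) < 0.5 * px
        assert abs(fit.b - truth["whole"]["b"]) < 0.5 * px

    def test_jagged_contour_area_close_to_ellipse_area(self):
        geom = dw.DropletGeometry(theta_front=67, theta_rear=30,
                                  contact_length=4.0, bulky_length=3.0,
                                  max_height=1.0, alpha_A=2.0,
                                  top_minor_axis=2.4, rear_pinned_x=1.0)
        cfg = top_config(jaggedness_amplitude=0.02 * 2.4, seed=11)
        frame, _ = dw.render_top_view(geom, cfg)
        seg = dw.segment_regions(frame, dw.ThresholdPair(95, 205))
        c = seg.contour_whole
        x, y = c[:, 0], c[:, 1]
        area_poly = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        fit = dw.fit_ellipse(c)
        assert abs(area_poly - fit.area) / area_poly < 0.02

    def test_tail_annulus_never_forward_of_bulky_region(self, jagged_top):
        _, frame, _ = jagged_top
        tail = frame.pixels == 180
        body = frame.pixels == 10
        assert tail.any() and body.any()
        assert np.nonzero(tail.any(axis=0))[0].max() <= \
            np.nonzero(body.any(axis=0))[0].max()

    def test_background_never_inside_whole_contour(self, jagged_top):
        _, frame, _ = jagged_top
        seg = dw.segment_regions(frame, dw.ThresholdPair(95, 205))
        inside = seg.mask_whole
        assert not (frame.pixels[inside] > 205).any()


class TestScriptRamp:
    def make(self, **kw):
        init = dw.DropletGeometry.spherical_cap(45, 3.0, rear_pinned_x=1.0,
                                                top_minor_axis=3.0)
        sc = dw.RampScenario(**kw)
        return dw.script_ramp(sc, init)

    def test_front_edge_fixed_then_strictly_increasing(self):
        frames, _ = self.make(front_depin_rs=54)
        rs = np.array([f.rotation_speed for f in frames])
        xf = np.array([f.geometry.x_front for f in frames])
        assert np.all(xf[rs < 54] == xf[0])
        after = xf[rs >= 54]
        assert np.all(np.diff(after) > 0)
        # event table consistent with frame-wise geometry: first moved frame
        # at the onset within one frame's rpm increment
        moved = np.nonzero(xf != xf[0])[0]
        assert abs(rs[moved[0]] - 54) <= 0.1 + 1e-9

    def test_pinned_rear_never_moves(self):
        frames, events = self.make(rear_depin_rs_whole="never",
                                   rear_depin_rs_bulky="never")
        xr = np.array([f.geometry.rear_pinned_x for f in frames])
        assert np.all(xr == xr[0])
        assert events["rear_depin_rs_whole"] is None
        assert "sliding" not in events["regimes"]

    def test_frame_index_maps_to_rotation_speed(self):
        frames, _ = self.make()
        assert frames[600].rotation_speed == pytest.approx(60.0)
        assert frames[600].time == pytest.approx(60.0)

    def test_front_angle_clamps_at_advancing_value(self):
        frames, events = self.make(front_depin_rs=55, theta_adv=67)
        rs = np.array([f.rotation_speed for f in frames])
        thf = np.array([f.geometry.theta_front for f in frames])
        assert np.all(thf[rs >= 55] == pytest.approx(67.0))
        assert thf[0] == pytest.approx(45.0)
        assert events["theta_adv"] == 67

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            dw.RampScenario(front_depin_rs=80, runoff_rs=60)
        with pytest.raises(ValueError):
            dw.RampScenario(rear_depin_rs_bulky=80, rear_depin_rs_whole=60)


class TestCoverageImage:
    def test_target_zero_gives_blank_image(self):
        frame, frac = dw.render_coverage_image(0.0)
        assert frac == 0.0

    def test_target_one_gives_fully_dark_image(self):
        frame, frac = dw.render_coverage_image(1.0)
        assert frac == 1.0

    def test_realized_fraction_close_to_target(self):
        cfg = dw.RenderConfig(image_width_px=512, image_height_px=512, seed=5)
        _, frac = dw.render_coverage_image(0.3478, config=cfg)
        assert abs(frac - 0.3478) < 0.01
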