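"""Cobb-angle computation, end-vertebra selection, endplate cross-check,
overlay rendering, and the angle invariances."""

import numpy as np
import pytest
from numpy.polynomial import Polynomial

import cobbcurve as cc
from cobbcurve import cobbmeas, detect, midline
from conftest import sequence_from_boxes


def model_from_poly(p, ys, degree):
    return midline.fit_midline([(float(p(y)), float(y)) for y in ys], degree=degree)


class TestTangentAndCobb:
    def test_tangent_angles(self):
        for slope, expected in [(0.0, 0.0), (1.0, 45.0), (np.tan(np.radians(33.0)), 33.0)]:
            p = Polynomial([450.0, slope])
            model = model_from_poly(p, np.linspace(100, 1000, 5), 1)
            assert cobbmeas.tangent_angle(model, 500.0) == pytest.approx(expected, abs=1e-9)

    def test_straight_model_zero_everywhere(self):
        model = model_from_poly(Polynomial([450.0]), np.linspace(100, 1000, 5), 1)
        assert cobbmeas.cobb_angle(model, 150.0, 900.0) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_quadratic_33_degrees(self):
        # boundary slopes -/+ tan(16.5 deg) over [100, 1100]
        s = np.tan(np.radians(16.5))
        p = Polynomial([450.0 + s * 150, -1.2 * s, s / 1000.0])
        model = model_from_poly(p, np.linspace(100, 1100, 9), 2)
        assert cobbmeas.cobb_angle(model, 100.0, 1100.0) == pytest.approx(33.0, abs=1e-9)

    def test_swapped_boundaries_are_a_contract_error(self):
        model = model_from_poly(Polynomial([450.0, 0.1]), np.linspace(0, 1000, 5), 1)
        with pytest.raises(ValueError, match="y_upper"):
            cobbmeas.cobb_angle(model, 900.0, 100.0)


class TestEndVertebrae:
    def _sequence(self, ys):
        boxes = [
            detect.VertebraBox(index=i, x_min=400, y_min=y - 30, x_max=500, y_max=y + 30)
            for i, y in enumerate(ys)
        ]
        return sequence_from_boxes(boxes)

    def test_segment_spanning_exact_centers(self):
        seq = self._sequence(np.arange(100, 1300, 100))
        assert cobbmeas.select_end_vertebrae((300.0, 800.0), seq) == (2, 7)

    def test_midway_tie_breaks_toward_interior(self):
        seq = self._sequence(np.arange(100, 1300, 100))
        # upper boundary midway between centers 3 (400) and 4 (500)
        upper, _ = cobbmeas.select_end_vertebrae((450.0, 900.0), seq)
        assert upper == 4

    def test_straight_spine_full_span(self, straight_spec):
        boxes, _ = cc.layout_phantom(straight_spec)
        seq = sequence_from_boxes(boxes)
        model = midline.fit_midline([b.center for b in boxes], degree=1)
        seg = midline.segment_spine(model)[0]
        assert cobbmeas.select_end_vertebrae(seg, seq) == (0, len(boxes) - 1)


class TestMeasureSpine:
    def test_straight_phantom_measures_zero(self, straight_spec):
        boxes, _ = cc.layout_phantom(straight_spec)
        seq = sequence_from_boxes(boxes)
        model = midline.fit_midline([b.center for b in boxes])
        ms = cobbmeas.measure_spine(model, seq)
        assert len(ms) == 1
        assert ms[0].angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_s_curve_matches_analytic_truth(self, s_curve_layout):
        seq, truth = s_curve_layout
        model = midline.fit_midline([b.center for b in seq.boxes])
        ms = cobbmeas.measure_spine(model, seq)
        assert len(ms) == 2
        for m, (region, angle, side) in zip(ms, truth.segment_angles):
            assert m.angle_deg == pytest.approx(angle, abs=1e-6)
            assert m.region == region
            assert m.side == side

    def test_quartic_yields_three_measurements(self):
        p = Polynomial([0.0, 0.1, -0.5, 0.0, 0.12], domain=[200, 1700], window=[-1, 1])
        p = p * 400 + 450
        ys = np.linspace(200, 1700, 15)
        boxes = [
            detect.VertebraBox(index=i, x_min=p(y) - 55, y_min=y - 35, x_max=p(y) + 55, y_max=y + 35)
            for i, y in enumerate(ys)
        ]
        seq = sequence_from_boxes(boxes)
        model = midline.fit_midline([b.center for b in boxes], degree=4)
        ms = cobbmeas.measure_spine(model, seq)
        assert len(ms) == 3
        assert [m.y_upper for m in ms] == sorted(m.y_upper for m in ms)

    def test_tangent_at_vertebra_mode(self, s_curve_layout):
        seq, truth = s_curve_layout
        model = midline.fit_midline([b.center for b in seq.boxes])
        ms = cobbmeas.measure_spine(model, seq, tangent_at="vertebra")
        ys = [b.center[1] for b in seq.boxes]
        for m in ms:
            assert m.y_upper in ys or m.y_upper in (model.domain[0], model.domain[1])


class TestEndplateMethod:
    def _tilted_phantom(self):
        spec0 = cc.spec_from_angles(1, angle_up=20.0, n_vertebrae=12, blur_sigma=1.0)
        boxes0, truth0 = cc.layout_phantom(spec0)
        d1 = Polynomial(spec0.curve_coefficients).deriv(1)
        tilts = [float(np.degrees(np.arctan(d1(y)))) for _, y in truth0.box_centers]
        kwargs = spec0.to_dict()
        kwargs["tilts"] = tilts
        return cc.PhantomSpec(**kwargs)

    def test_zero_tilts_give_zero_angle(self):
        boxes = [
            detect.VertebraBox(index=i, x_min=400, y_min=100 + 120 * i, x_max=500, y_max=160 + 120 * i)
            for i in range(4)
        ]
        for b in boxes:
            b.endplate_tilts = (0.0, 0.0)
        seq = sequence_from_boxes(boxes)
        assert cobbmeas.cobb_from_endplates(seq, 0, 3) == 0.0

    def test_tilt_arithmetic(self):
        boxes = [
            detect.VertebraBox(index=i, x_min=400, y_min=100 + 120 * i, x_max=500, y_max=160 + 120 * i)
            for i in range(3)
        ]
        boxes[0].endplate_tilts = (12.0, 11.0)
        boxes[2].endplate_tilts = (-20.0, -21.0)
        seq = sequence_from_boxes(boxes)
        assert cobbmeas.cobb_from_endplates(seq, 0, 2) == pytest.approx(33.0)

    def test_missing_tilts_direct_user_to_refinement(self, straight_spec):
        boxes, _ = cc.layout_phantom(straight_spec)
        seq = sequence_from_boxes(boxes)
        with pytest.raises(ValueError, match="refine_endplates_hough"):
            cobbmeas.cobb_from_endplates(seq, 0, 11)

    def test_agrees_with_midline_method_on_tilted_phantom(self):
        spec = self._tilted_phantom()
        image, _, _ = cc.generate_phantom(spec)
        seq = detect.detect_classical(image)
        seq = detect.refine_endplates_hough(image, seq)
        model = midline.fit_midline(detect.centers(seq))
        m = cobbmeas.measure_spine(model, seq)[0]
        ep = cobbmeas.cobb_from_endplates(seq, m.upper_vertebra_index, m.lower_vertebra_index)
        assert abs(ep - m.angle_deg) <= 2.5


class TestOverlay:
    def test_render_is_deterministic(self, tmp_path, s_curve_layout):
        seq, _ = s_curve_layout
        model = midline.fit_midline([b.center for b in seq.boxes])
        ms = cobbmeas.measure_spine(model, seq)
        image = np.full((1900, 900), 0.3)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        cobbmeas.render_overlay(image, model, seq, ms, p1)
        cobbmeas.render_overlay(image, model, seq, ms, p2)
        assert p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_measurements_draw_boxes_and_midline(self, tmp_path, s_curve_layout):
        seq, _ = s_curve_layout
        model = midline.fit_midline([b.center for b in seq.boxes])
        p = tmp_path / "bare.png"
        cobbmeas.render_overlay(np.full((1900, 900), 0.3), model, seq, [], p)
        assert p.stat().st_size > 0


class TestAngleInvariances:
    def _measure(self, boxes):
        seq = sequence_from_boxes(boxes)
        model = midline.fit_midline([b.center for b in boxes])
        return cobbmeas.measure_spine(model, seq)

    def test_uniform_scale_invariance(self, s_curve_layout):
        seq, _ = s_curve_layout
        base = self._measure(seq.boxes)
        for s in (0.5, 2.0, 3.7):
            scaled = [
                detect.VertebraBox(
                    index=b.index, x_min=b.x_min * s, y_min=b.y_min * s,
                    x_max=b.x_max * s, y_max=b.y_max * s,
                )
                for b in seq.boxes
            ]
            ms = self._measure(scaled)
            for m0, m1 in zip(base, ms):
                assert abs(m1.angle_deg - m0.angle_deg) <= 1e-9

    def test_mirror_invariance_flips_sides(self, s_curve_layout):
        seq, _ = s_curve_layout
        W = seq.image_size[0]
        base = self._measure(seq.boxes)
        mirrored = [
            detect.VertebraBox(
                index=b.index, x_min=W - b.x_max, y_min=b.y_min,
                x_max=W - b.x_min, y_max=b.y_max,
            )
            for b in seq.boxes
        ]
        ms = self._measure(mirrored)
        for m0, m1 in zip(base, ms):
            assert m1.angle_deg == pytest.approx(m0.angle_deg, abs=1e-9)
            assert m1.side == -m0.side

    def test_triangle_property(self, s_curve_layout):
        seq, _ = s_curve_layout
        model = midline.fit_midline([b.center for b in seq.boxes])
        lo, hi = model.domain
        a, b_, c = lo + 10, 0.5 * (lo + hi), hi - 10
        assert cobbmeas.cobb_angle(model, a, c) <= (
            cobbmeas.cobb_angle(model, a, b_) + cobbmeas.cobb_angle(model, b_, c) + 1e-12
        )

    def test_noise_free_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for i in range(20):
            spec = cc.random_polynomial_spec(rng, n_vertebrae=14, seed=i)
            boxes, truth = cc.layout_phantom(spec)
            ms = self._measure(boxes)
            got = sorted(m.angle_deg for m in ms)
            want = sorted(a for _, a, _ in truth.segment_angles)
            assert len(got) == len(want)
            assert got == pytest.approx(want, abs=1e-6)
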