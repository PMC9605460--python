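"""Tortuosity metric estimators against analytic oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesseltort.metrics import (DegenerateSegmentError, MetricConfig,
                                compute_record, count_inflections,
                                estimate_curvature, resample_uniform, soam,
                                smooth_points, subdivide_segment)
from vesseltort.synthetic import CurveSpec, sample_curve

from conftest import sine_quadrature_truth

PL = MetricConfig.for_point_lists(resample_step=0.05)


def straight_line(n=101, length=10.0):
    t = np.linspace(0, length, n)
    return np.column_stack([t, np.zeros_like(t)])


class TestResampling:
    def test_straight_line_unit_step(self):
        sam = resample_uniform(straight_line(), 1.0)
        assert len(sam.points) == 11
        assert np.allclose(sam.points[:, 0], np.arange(11))
        assert np.allclose(np.diff(sam.arc_positions), 1.0)

    def test_quarter_circle_arc_position(self):
        ang = np.linspace(0, math.pi / 2, 100)
        pts = np.column_stack([10 * np.sin(ang), 10 * (1 - np.cos(ang))])
        sam = resample_uniform(pts, 0.5)
        assert sam.total_arc == pytest.approx(math.pi / 2 * 10, rel=0.01)

    def test_length_conserved_within_step(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(50, 2)), axis=0)
        raw = np.hypot(*np.diff(pts, axis=0).T).sum()
        sam = resample_uniform(pts, 0.5)
        assert abs(sam.total_arc - raw) <= 0.5

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSegmentError):
            resample_uniform(np.zeros((5, 2)), 1.0)
        with pytest.raises(DegenerateSegmentError):
            resample_uniform(np.zeros((1, 2)), 1.0)


class TestCurvature:
    def test_straight_line_zero(self):
        sam = resample_uniform(straight_line(), 0.1)
        c = estimate_curvature(sam)
        assert np.all(np.abs(c) < 1e-9)

    @pytest.mark.parametrize("radius", [1.0, 5.0, 20.0])
    def test_circle_curvature_magnitude(self, radius):
        ang = np.linspace(0, math.pi, 2000)
        pts = np.column_stack([radius * np.sin(ang),
                               radius * (1 - np.cos(ang))])
        sam = resample_uniform(pts, radius / 100)
        c = estimate_curvature(sam)
        interior = np.abs(c[5:-5])
        assert np.all(np.abs(interior - 1 / radius) / (1 / radius) < 0.02)

    def test_sine_crest_curvature(self):
        x = np.linspace(0, math.pi, 4000)
        pts = np.column_stack([x, np.sin(x)])
        sam = resample_uniform(pts, 0.01)
        c = estimate_curvature(sam)
        crest = np.argmin(np.abs(sam.points[:, 0] - math.pi / 2))
        assert abs(abs(c[crest]) - 1.0) < 0.02

    def test_too_few_samples(self):
        sam = resample_uniform(straight_line(5, 2.0), 1.0)
        assert len(sam.points) < 5
        with pytest.raises(DegenerateSegmentError):
            estimate_curvature(sam)


class TestSubdivision:
    def test_straight_single_run(self):
        sam = resample_uniform(straight_line(), 0.1)
        estimate_curvature(sam)
        assert len(subdivide_segment(sam)) == 1

    def test_s_curve_two_runs(self):
        pts, _ = sample_curve(CurveSpec("composite_S", {"radius": 1.0},
                                        step=0.01))
        sam = resample_uniform(pts, 0.01)
        estimate_curvature(sam)
        subs = subdivide_segment(sam)
        assert len(subs) == 2
        for sub_arc, sub_chord in subs:
            assert sub_arc / sub_chord == pytest.approx(math.pi / 2, rel=0.01)

    def test_two_period_sine_four_runs(self):
        pts, _ = sample_curve(CurveSpec(
            "sine", {"amplitude": 1, "frequency": 1, "span": 4 * math.pi},
            step=0.01))
        sam = resample_uniform(pts, 0.02)
        estimate_curvature(sam)
        assert len(subdivide_segment(sam)) == 4
        assert count_inflections(sam) == 3


class TestSoam:
    def test_right_angle_elbow(self):
        pts = np.array([(x, 0.0) for x in range(6)]
                       + [(5.0, y) for y in range(1, 6)])
        sam = resample_uniform(pts, 1.0)
        assert soam(sam) == pytest.approx(9.0, rel=1e-6)

    def test_dense_circle_limit(self):
        r = 7.0
        ang = np.linspace(0, math.pi, 5000)
        pts = np.column_stack([r * np.sin(ang), r * (1 - np.cos(ang))])
        sam = resample_uniform(pts, 0.05)
        assert soam(sam) == pytest.approx(math.degrees(1 / r), rel=0.02)


ANALYTIC_CASES = [
    ("line", {"length": 25.0}),
    ("circular_arc", {"radius": 5.0, "angle": math.pi}),
    ("circular_arc", {"radius": 10.0, "angle": math.pi / 2}),
    ("sine", {"amplitude": 2.0, "frequency": 1.0, "span": 2 * math.pi}),
]


class TestComputeRecord:
    def test_straight_segment_trivials(self):
        rec = compute_record(straight_line(), PL)
        assert rec.dm == pytest.approx(1.0, abs=1e-9)
        assert abs(rec.td) < 1e-9 and abs(rec.tau1) < 1e-9
        for t in (rec.tau2, rec.tau3, rec.tau4, rec.tau5, rec.tau6, rec.tau7):
            assert abs(t) < 1e-9
        assert rec.soam < 1e-9
        assert rec.icm == pytest.approx(1.0, abs=1e-9)
        assert rec.inflection_count == 0
        assert rec.sd_avc < 1e-9 and rec.n_avc < 1e-9

    @pytest.mark.parametrize("family,params", ANALYTIC_CASES)
    def test_analytic_oracles(self, family, params):
        pts, oracle = sample_curve(CurveSpec(family, params, step=0.02))
        rec = compute_record(pts, MetricConfig.for_point_lists(0.05))
        assert rec.arc == pytest.approx(oracle.arc, rel=0.02)
        assert rec.chord == pytest.approx(oracle.chord, rel=1e-6)
        assert rec.dm == pytest.approx(oracle.dm, rel=0.02)
        if oracle.total_curvature > 0.1:
            assert abs(rec.tau2) == pytest.approx(oracle.total_curvature,
                                                  rel=0.02)
        assert rec.inflection_count == oracle.inflection_count

    def test_circular_arc_curvature_integrals(self):
        r, theta = 5.0, math.pi
        pts, _ = sample_curve(CurveSpec("circular_arc",
                                        {"radius": r, "angle": theta},
                                        step=0.02))
        rec = compute_record(pts, MetricConfig.for_point_lists(0.05))
        assert abs(rec.tau2) == pytest.approx(theta, rel=0.02)
        assert rec.tau3 == pytest.approx(theta / r, rel=0.02)
        assert abs(rec.tau4) == pytest.approx(1 / r, rel=0.02)
        assert rec.tau5 == pytest.approx(1 / r ** 2, rel=0.02)
        assert rec.soam == pytest.approx(math.degrees(1 / r), rel=0.02)
        assert rec.sd_avc == pytest.approx(0.0, abs=0.01)
        assert rec.n_avc == pytest.approx(1 / r, rel=0.02)

    def test_sine_against_quadrature(self):
        a, w, span = 2.0, 1.0, 2 * math.pi
        truth = sine_quadrature_truth(a, w, span)
        pts, _ = sample_curve(CurveSpec(
            "sine", {"amplitude": a, "frequency": w, "span": span},
            step=0.01))
        rec = compute_record(pts, MetricConfig.for_point_lists(0.02))
        assert rec.arc == pytest.approx(truth["arc"], rel=0.02)
        assert rec.dm == pytest.approx(truth["dm"], rel=0.02)
        assert rec.tau3 == pytest.approx(truth["tau3"], rel=0.02)
        assert rec.soam == pytest.approx(truth["soam"], rel=0.02)

    def test_formula_identities(self):
        for family, params in ANALYTIC_CASES:
            pts, _ = sample_curve(CurveSpec(family, params, step=0.05))
            rec = compute_record(pts, PL)
            assert rec.tau1 == rec.df - 1.0
            assert rec.tau4 * rec.arc == pytest.approx(rec.tau2, rel=1e-12)
            assert rec.tau5 * rec.arc == pytest.approx(rec.tau3, rel=1e-12)
            assert rec.tau6 * rec.chord == pytest.approx(rec.tau2, rel=1e-12)
            assert rec.tau7 * rec.chord == pytest.approx(rec.tau3, rel=1e-12)
            assert rec.icm / rec.dm == pytest.approx(
                rec.inflection_count + 1, rel=1e-12)

    def test_degenerate_chord_flagged_not_zero(self):
        ang = np.linspace(0, 2 * math.pi, 500)
        loop = np.column_stack([np.cos(ang), np.sin(ang)])
        loop[-1] = loop[0]
        rec = compute_record(loop, PL)
        assert "degenerate_chord" in rec.flags
        assert math.isnan(rec.dm) and math.isnan(rec.icm)
        assert math.isfinite(rec.tau3)   # arc-normalised metrics survive


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(0, 2 * math.pi), dx=st.floats(-50, 50),
           dy=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, angle, dx, dy):
        pts, _ = sample_curve(CurveSpec(
            "sine", {"amplitude": 2, "frequency": 1, "span": 5.0}, step=0.05))
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = pts @ rot.T + (dx, dy)
        r0, r1 = compute_record(pts, PL), compute_record(moved, PL)
        for name in ("arc", "chord", "dm", "df", "td", "tau1", "tau3",
                     "tau5", "tau7", "soam", "icm", "sd_avc", "n_avc"):
            assert getattr(r1, name) == pytest.approx(
                getattr(r0, name), abs=1e-9, rel=1e-9), name
        assert abs(r1.tau2) == pytest.approx(abs(r0.tau2), abs=1e-9)
        assert r1.inflection_count == r0.inflection_count

    def test_reversal_invariance(self):
        pts, _ = sample_curve(CurveSpec(
            "sine", {"amplitude": 2, "frequency": 1.3, "span": 7.0},
            step=0.02))
        r0, r1 = compute_record(pts, PL), compute_record(pts[::-1], PL)
        for name in ("arc", "chord", "dm", "df", "td", "tau1", "tau3",
                     "tau5", "tau7", "soam", "icm", "sd_avc", "n_avc"):
            assert getattr(r1, name) == pytest.approx(
                getattr(r0, name), abs=1e-9, rel=1e-9), name
        assert abs(r1.tau2) == pytest.approx(abs(r0.tau2), abs=1e-9)
        assert r1.inflection_count == r0.inflection_count

    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_scale_laws(self, scale):
        pts, _ = sample_curve(CurveSpec(
            "sine", {"amplitude": 2, "frequency": 1, "span": 6.0}, step=0.02))
        cfg0 = MetricConfig.for_point_lists(0.05)
        cfg1 = MetricConfig(resample_step=0.05 * scale, smoothing_sigma=0.0,
                            eps_kappa=cfg0.eps_kappa / scale)
        r0 = compute_record(pts, cfg0)
        r1 = compute_record(pts * scale, cfg1)
        for name in ("dm", "tau1", "icm"):
            assert getattr(r1, name) == pytest.approx(getattr(r0, name),
                                                      rel=1e-9), name
        assert r1.arc == pytest.approx(r0.arc * scale, rel=1e-9)
        assert r1.chord == pytest.approx(r0.chord * scale, rel=1e-9)
        assert r1.td * r1.arc == pytest.approx(r0.td * r0.arc, rel=1e-9)
        assert r1.inflection_count == r0.inflection_count


def test_smoothing_preserves_straight_lines():
    sam = resample_uniform(straight_line(), 0.5)
    sm = smooth_points(sam, 2.0)
    resid = np.abs(sm.points[:, 1])
    assert resid.max() < 1e-9
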