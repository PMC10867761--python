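"""Resampling, turning angles and the CTI/IC/OC metrics against analytic
oracles (closed forms and numerical quadrature)."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from vasctort import (
    TortuosityConfig,
    ValidationError,
    VesselSegment,
    image_tortuosity,
    resample_chain,
    segment_tortuosity,
    turning_angles,
)
from vasctort.tortuosity import SegmentTortuosity


def make_segment(points, segment_id="s000"):
    pts = [tuple(p) for p in points]
    arc = float(np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1).sum())
    chord = float(np.linalg.norm(np.asarray(points[-1], float) - np.asarray(points[0], float)))
    return VesselSegment(segment_id=segment_id, chain=tuple(pts), arc_length_px=arc, chord_length_px=chord)


class TestResampleChain:
    def test_straight_chain_100px_spacing5_gives_21_collinear_points(self):
        chain = [(0, c) for c in range(100)]  # arc length 99
        poly = resample_chain(chain, spacing_px=5.0)
        assert poly.n_points == 21
        assert np.allclose(poly.points[:, 0], 0.0)
        steps = np.diff(poly.points[:, 1])
        assert np.all(steps[:-1] == pytest.approx(5.0))

    def test_two_point_chain_unchanged(self):
        poly = resample_chain([(0, 0), (3, 4)])
        np.testing.assert_array_equal(poly.points, [[0, 0], [3, 4]])

    def test_short_chain_rejected(self):
        with pytest.raises(ValidationError):
            resample_chain([(0, 0)])

    def test_smoothing_reduces_jitter_deviation(self):
        rng = np.random.default_rng(42)
        cols = np.arange(200)
        rows = rng.integers(-1, 2, size=200)  # +-1 px staircase jitter
        chain = list(zip(rows.tolist(), cols.tolist()))
        raw = np.asarray(chain, float)
        poly = resample_chain(chain, spacing_px=5.0, smoothing_window=21)
        # perpendicular deviation from the ideal line row = 0
        assert np.abs(poly.points[:, 0]).max() < np.abs(raw[:, 0]).max()

    def test_spacing_invariant_between_samples(self):
        t = np.linspace(0, 2 * math.pi, 400)
        chain = np.column_stack([30 * np.sin(t), 60 * t / (2 * math.pi)])
        poly = resample_chain(chain, spacing_px=5.0, smoothing_window=1)
        steps = np.linalg.norm(np.diff(poly.points, axis=0), axis=1)
        assert np.all(steps[:-1] > 0.5 * 5.0)
        assert np.all(steps[:-1] < 1.5 * 5.0)


class TestTurningAngles:
    def test_collinear_zero(self):
        pts = np.column_stack([np.zeros(10), np.arange(10.0)])
        assert np.allclose(turning_angles(pts), 0.0)

    def test_right_angle(self):
        theta = turning_angles(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]))
        assert theta == pytest.approx([math.pi / 2])

    def test_fewer_than_three_points_empty(self):
        assert turning_angles(np.array([[0.0, 0.0], [1.0, 1.0]])).size == 0

    @pytest.mark.parametrize("k", [7, 13, 25])
    def test_regular_polyline_on_circle(self, k):
        """k points spanning a full circle turn by 2*pi/(k-1) at each interior."""
        phi = np.linspace(0, 2 * math.pi, k)
        pts = np.column_stack([np.cos(phi), np.sin(phi)])
        theta = turning_angles(pts)
        assert theta.shape == (k - 2,)
        assert np.allclose(theta, 2 * math.pi / (k - 1), atol=1e-12)

    def test_angles_bounded_by_pi(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(50, 2))
        theta = turning_angles(pts)
        assert np.all((theta >= 0) & (theta <= math.pi))


class TestSegmentTortuosity:
    def test_straight_segment_identity(self):
        seg = make_segment([(0, c) for c in range(60)])
        st = segment_tortuosity(seg)
        assert st.cti == pytest.approx(1.0, abs=1e-6)
        assert st.ic == pytest.approx(0.0, abs=1e-6)
        assert st.oc == pytest.approx(0.0, abs=1e-6)
        assert not st.flagged

    def test_semicircle_arc_chord(self):
        # analytic: arc/chord = pi*r / 2r = pi/2
        t = np.linspace(0, math.pi, 400)
        pts = np.column_stack([100 * np.sin(t), 100 * np.cos(t)])
        st = segment_tortuosity(make_segment(pts))
        assert st.cti == pytest.approx(math.pi / 2, rel=0.01)

    def test_sinusoid_against_quadrature_oracle(self):
        a, lam = 10.0, 100.0
        k = 2 * math.pi / lam
        x = np.linspace(0, lam, 500)
        pts = np.column_stack([a * np.sin(k * x), x])
        st = segment_tortuosity(make_segment(pts))
        arc, _ = quad(lambda u: math.hypot(1.0, a * k * math.cos(k * u)), 0, lam)
        assert st.cti == pytest.approx(arc / lam, rel=0.01)
        # total absolute turning oracle: integral of |curvature| ds
        def abs_curv(u):
            yp = a * k * math.cos(k * u)
            ypp = -a * k * k * math.sin(k * u)
            return abs(ypp) / (1 + yp * yp)
        tot, _ = quad(abs_curv, 0, lam, limit=200)
        assert st.ic == pytest.approx(tot, rel=0.05)

    def test_angle_sum_formula_variant(self):
        t = np.linspace(0, math.pi, 400)
        pts = np.column_stack([100 * np.sin(t), 100 * np.cos(t)])
        st = segment_tortuosity(
            make_segment(pts), TortuosityConfig(cti_formula="angle_sum")
        )
        # 1 + total turning / arc: semicircle turns pi over arc pi*100
        assert st.cti == pytest.approx(1 + math.pi / (math.pi * 100), rel=0.02)

    def test_closed_loop_flagged(self):
        t = np.linspace(0, 2 * math.pi, 300)
        pts = np.column_stack([30 * np.sin(t), 30 * np.cos(t)])
        st = segment_tortuosity(make_segment(pts))
        assert st.flagged

    def test_cti_scale_invariance(self):
        a, lam = 10.0, 100.0
        k = 2 * math.pi / lam
        x = np.linspace(0, lam, 500)
        small = np.column_stack([a * np.sin(k * x), x])
        st1 = segment_tortuosity(make_segment(small))
        st2 = segment_tortuosity(make_segment(small * 2.0))
        assert st2.cti == pytest.approx(st1.cti, rel=0.005)


class TestImageTortuosity:
    @staticmethod
    def fake(segment_id, cti, ic=0.0, oc=0.0, arc=100.0, flagged=False):
        return SegmentTortuosity(
            segment_id=segment_id, theta=np.empty(0), cti=cti, ic=ic, oc=oc,
            arc_length_px=arc, flagged=flagged,
        )

    def test_single_segment_passthrough(self):
        res = image_tortuosity([self.fake("s0", 1.07, 2.0, 0.1)], "img")
        assert (res.cti, res.ic, res.oc) == (1.07, 2.0, 0.1)
        assert res.n_segments == 1

    def test_two_segment_mean(self):
        res = image_tortuosity([self.fake("a", 1.0), self.fake("b", 1.2)], "img")
        assert res.cti == pytest.approx(1.1)

    def test_flagged_excluded(self):
        res = image_tortuosity(
            [self.fake("a", 1.0), self.fake("bad", 99.0, flagged=True)], "img"
        )
        assert res.cti == 1.0
        assert res.n_segments == 1

    def test_no_usable_segments_error(self):
        with pytest.raises(ValidationError, match="img9"):
            image_tortuosity([self.fake("a", 2.0, flagged=True)], "img9")
        with pytest.raises(ValidationError):
            image_tortuosity([], "img9")

    def test_length_weighted_aggregate(self):
        cfg = TortuosityConfig(aggregate="length_weighted")
        res = image_tortuosity(
            [self.fake("a", 1.0, arc=300.0), self.fake("b", 1.2, arc=100.0)],
            "img", cfg,
        )
        assert res.cti == pytest.approx(0.75 * 1.0 + 0.25 * 1.2)
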