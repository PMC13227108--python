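"""Spline fitting, equidistant sampling, parallel transport, writhe, twist."""

import numpy as np
import pytest

from dnaforge.exceptions import (
    DegenerateInputError,
    TooFewPointsError,
    TopologyError,
    WritheUndefinedError,
)
from dnaforge.geometry import step_from_frames
from dnaforge.spline import (
    apply_twist,
    compute_writhe,
    fit_spline,
    sample_equidistant,
    transport_frames,
)


def trefoil(n, scale=1.0):
    u = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return scale * np.c_[np.sin(u) + 2 * np.sin(2 * u),
                         np.cos(u) - 2 * np.cos(2 * u),
                         -np.sin(3 * u)]


class TestFitSpline:
    def test_three_points_rejected_four_accepted(self):
        pts = [[0, 0, 0], [1, 0, 0], [2, 0.5, 0], [3, 0, 1]]
        with pytest.raises(TooFewPointsError):
            fit_spline(pts[:3])
        assert fit_spline(pts).arc_length > 0

    def test_duplicate_consecutive_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_spline([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]])

    def test_collinear_points_give_straight_line(self):
        pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]
        path = fit_spline(pts)
        assert path.arc_length == pytest.approx(3.0, abs=1e-8)
        ts = np.linspace(0, path.t_knots[-1], 17)
        tangents = path.tangent(ts)
        assert np.allclose(tangents, [1, 0, 0], atol=1e-9)

    def test_closed_circle_arc_length(self):
        th = np.linspace(0, 2 * np.pi, 13)[:-1]
        radius = 7.0
        pts = np.c_[radius * np.cos(th), radius * np.sin(th), np.zeros(12)]
        path = fit_spline(pts, closed=True)
        assert path.arc_length == pytest.approx(2 * np.pi * radius, rel=1e-3)


class TestSampleEquidistant:
    def test_default_spacing_on_straight_path(self):
        pts = [[0, 0, 0], [0, 0, 1.0], [0, 0, 2.2], [0, 0, 3.4]]
        origins, tangents, eff = sample_equidistant(fit_spline(pts))
        assert len(origins) == 11
        gaps = np.linalg.norm(np.diff(origins, axis=0), axis=1)
        assert np.allclose(gaps, 0.34, atol=1e-6)
        assert np.allclose(tangents, [0, 0, 1], atol=1e-9)

    def test_closed_circle_closing_gap_uniform(self):
        th = np.linspace(0, 2 * np.pi, 17)[:-1]
        radius = 200 * 0.34 / (2 * np.pi)
        pts = np.c_[radius * np.cos(th), radius * np.sin(th), np.zeros(16)]
        origins, _, eff = sample_equidistant(fit_spline(pts, closed=True), n_bp=200)
        assert len(origins) == 200
        wrapped = np.vstack([origins, origins[:1]])
        gaps = np.linalg.norm(np.diff(wrapped, axis=0), axis=1)
        assert np.ptp(gaps) < 1e-6

    def test_arc_length_separations_equal_on_wiggly_path(self):
        t = np.linspace(0, 3, 9)
        pts = np.c_[t, 0.8 * np.sin(t), 0.5 * np.cos(1.7 * t)]
        path = fit_spline(pts)
        origins, _, eff = sample_equidistant(path, spacing=0.34)
        # quadrature oracle: arc length between consecutive sample parameters
        ss = [path.arc_length_at(path.param_at_arclength(i * eff))
              for i in range(len(origins))]
        seps = np.diff(ss)
        assert np.allclose(seps, eff, atol=1e-6)

    def test_bad_requests_rejected(self):
        path = fit_spline([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]])
        with pytest.raises(DegenerateInputError):
            sample_equidistant(path, n_bp=1)
        with pytest.raises(DegenerateInputError):
            sample_equidistant(path, spacing=10.0)


class TestTransportFrames:
    def test_straight_line_all_triads_identical(self):
        origins = np.c_[np.zeros(10), np.zeros(10), 0.34 * np.arange(10)]
        tangents = np.tile([0.0, 0.0, 1.0], (10, 1))
        pf = transport_frames(origins, tangents, closed=False)
        triads = np.array([f.triad for f in pf.frames])
        assert np.allclose(triads, triads[0], atol=1e-12)

    def test_planar_circle_zero_holonomy(self):
        n = 100
        phi = 2 * np.pi * np.arange(n) / n
        origins = np.c_[np.cos(phi), np.sin(phi), np.zeros(n)] * 10
        tangents = np.c_[-np.sin(phi), np.cos(phi), np.zeros(n)]
        pf = transport_frames(origins, tangents, closed=True)
        # transporting once more around the wrap must return the start normal
        first, last = pf.frames[0], pf.frames[-1]
        # rotate last x through the wrap (tangent change last -> first)
        from dnaforge.geometry import rotvec_to_matrix
        z0, z1 = last.triad[2], first.triad[2]
        axis = np.cross(z0, z1)
        ang = np.arctan2(np.linalg.norm(axis), z0 @ z1)
        x_back = rotvec_to_matrix(axis / np.linalg.norm(axis) * ang) @ last.triad[0]
        mismatch = np.degrees(np.arctan2(
            np.cross(x_back, first.triad[0]) @ z1, x_back @ first.triad[0]))
        assert abs(mismatch) < 1e-6

    def test_helical_path_carries_zero_twist(self):
        t = np.linspace(0, 4 * np.pi, 120)
        r, pitch = 3.0, 0.5
        origins = np.c_[r * np.cos(t), r * np.sin(t), pitch * t]
        d = np.c_[-r * np.sin(t), r * np.cos(t), np.full_like(t, pitch)]
        pf = transport_frames(origins, d / np.linalg.norm(d, axis=1)[:, None],
                              closed=False)
        for a, b in zip(pf.frames[:-1], pf.frames[1:]):
            twist = step_from_frames(a, b).rotation[2]
            assert abs(twist) < 1e-6

    def test_zero_tangent_rejected(self):
        with pytest.raises(DegenerateInputError):
            transport_frames(np.zeros((3, 3)), np.zeros((3, 3)), closed=False)


class TestWrithe:
    def test_planar_circle_zero(self):
        phi = 2 * np.pi * np.arange(200) / 200
        origins = np.c_[np.cos(phi), np.sin(phi), np.zeros(200)]
        assert abs(compute_writhe(origins, closed=True)) < 1e-10

    def test_refined_quadrature_oracle(self):
        # 10x-refined discretization of the same smooth curve as oracle
        coarse = compute_writhe(trefoil(200), closed=True)
        fine = compute_writhe(trefoil(2000), closed=True)
        assert coarse == pytest.approx(fine, abs=1e-3)

    def test_mirror_negates(self):
        pts = trefoil(150)
        mirrored = pts.copy()
        mirrored[:, 2] *= -1
        assert compute_writhe(pts) == pytest.approx(-compute_writhe(mirrored),
                                                    abs=1e-12)

    def test_open_chain_requires_flag(self):
        pts = trefoil(50)[:30]
        with pytest.raises(WritheUndefinedError):
            compute_writhe(pts, closed=False)
        assert np.isfinite(compute_writhe(pts, closed=False, allow_open=True))


class TestApplyTwist:
    def _transported_circle(self, n):
        phi = 2 * np.pi * np.arange(n) / n
        radius = n * 0.34 / (2 * np.pi)
        origins = radius * np.c_[np.cos(phi), np.sin(phi), np.zeros(n)]
        tangents = np.c_[-np.sin(phi), np.cos(phi), np.zeros(n)]
        return transport_frames(origins, tangents, closed=True)

    def test_open_default_helical_repeat(self):
        origins = np.c_[np.zeros(22), np.zeros(22), 0.34 * np.arange(22)]
        tangents = np.tile([0.0, 0.0, 1.0], (22, 1))
        pf = apply_twist(transport_frames(origins, tangents, closed=False))
        for a, b in zip(pf.frames[:-1], pf.frames[1:]):
            assert step_from_frames(a, b).rotation[2] == pytest.approx(
                360 / 10.5, abs=1e-9)

    def test_planar_210_circle_exact_repeat(self):
        pf = apply_twist(self._transported_circle(210), dLk=0)
        assert pf.twist_per_step == pytest.approx(360 * 20 / 210, abs=1e-9)

    def test_planar_200_circle_with_dlk(self):
        pf = apply_twist(self._transported_circle(200), dLk=6)
        # Tw0 = round(200/10.5) = 19 turns; 6 extra turns over 200 steps
        assert pf.twist_per_step == pytest.approx(360 * 25 / 200, abs=1e-8)

    def test_non_integer_dlk_rejected_closed(self):
        with pytest.raises(TopologyError):
            apply_twist(self._transported_circle(105), dLk=0.5)

    def test_dlk_on_open_chain_warned_and_ignored(self):
        origins = np.c_[np.zeros(22), np.zeros(22), 0.34 * np.arange(22)]
        tangents = np.tile([0.0, 0.0, 1.0], (22, 1))
        pf0 = transport_frames(origins, tangents, closed=False)
        with pytest.warns(UserWarning):
            pf = apply_twist(pf0, dLk=3)
        assert pf.twist_per_step == pytest.approx(360 / 10.5)

    def test_bad_bp_per_turn(self):
        with pytest.raises(DegenerateInputError):
            apply_twist(self._transported_circle(105), bp_per_turn=0)


class TestWhiteFullerClosure:
    """Generated closed chains must realize Lk = Tw0 + dLk exactly."""

    @pytest.mark.parametrize("dlk", [-3, 0, 6])
    @pytest.mark.parametrize("shape", ["circle", "ellipse", "saddle"])
    def test_lk_equals_tw0_plus_dlk(self, shape, dlk):
        import dnaforge as df

        n = 210
        if shape == "circle":
            cp = None
        elif shape == "ellipse":
            th = np.linspace(0, 2 * np.pi, 25)[:-1]
            cp = np.c_[14 * np.cos(th), 9 * np.sin(th), np.zeros(24)]
        else:  # saddle: non-planar closed loop
            th = np.linspace(0, 2 * np.pi, 25)[:-1]
            cp = np.c_[12 * np.cos(th), 12 * np.sin(th), 1.8 * np.cos(2 * th)]
        s = df.make(n_bp=n, circular=True, dLk=dlk, control_points=cp)
        topo = df.compute_linking_number(s)
        assert topo.Lk == pytest.approx(round(n / 10.5) + dlk, abs=1e-6)

    def test_chirality_mirroring_control_points(self):
        import dnaforge as df

        cp = trefoil(24, scale=8.0)
        mirrored = cp.copy()
        mirrored[:, 2] *= -1
        s1 = df.make(n_bp=300, circular=True, control_points=cp)
        s2 = df.make(n_bp=300, circular=True, control_points=mirrored)
        w1 = compute_writhe(s1.origins(), closed=True)
        w2 = compute_writhe(s2.origins(), closed=True)
        assert w1 == pytest.approx(-w2, abs=1e-6)
        assert abs(w1) > 2.0  # the trefoil projection is strongly writhed
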