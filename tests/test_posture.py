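import math

import numpy as np
import pytest

from rheopipe.segmentation import Blob
from rheopipe import posture as po
from rheopipe import synthdata as sd


def ellipse_blob(a_px, b_px, angle, center=(150.0, 150.0), shape=(300, 300)):
    """Uniformly filled ideal ellipse as a Blob (pixel units)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cc + 0.5 - center[0]
    y = rr + 0.5 - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = x * ca + y * sa
    v = -x * sa + y * ca
    mask = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    pix = np.stack(np.nonzero(mask), axis=1)
    return Blob(pixels=pix, values=np.ones(len(pix)))


def rect_blob(w_px, h_px, origin=(50, 50)):
    rr, cc = np.mgrid[origin[0] : origin[0] + h_px, origin[1] : origin[1] + w_px]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return Blob(pixels=pix, values=np.ones(len(pix)))


class TestEquivalentEllipse:
    @pytest.mark.parametrize("angle_deg", [0, 30, 75, -50])
    def test_filled_ellipse_recovery(self, angle_deg):
        ell = po.equivalent_ellipse(ellipse_blob(20, 5, math.radians(angle_deg)))
        assert ell.semi_major == pytest.approx(20, rel=0.02)
        assert ell.semi_minor == pytest.approx(5, rel=0.02)
        d = (ell.orientation - math.radians(angle_deg) + math.pi / 2) % math.pi - math.pi / 2
        assert abs(math.degrees(d)) < 1.0

    def test_disk_is_isotropic(self):
        ell = po.equivalent_ellipse(ellipse_blob(12, 12, 0.0))
        assert ell.semi_major == pytest.approx(ell.semi_minor, rel=0.01)
        assert ell.isotropic

    def test_rotation_equivariance(self):
        e0 = po.equivalent_ellipse(ellipse_blob(20, 5, math.radians(10)))
        e9 = po.equivalent_ellipse(ellipse_blob(20, 5, math.radians(100)))
        assert e9.semi_major == pytest.approx(e0.semi_major, rel=0.01)
        d = (e9.orientation - e0.orientation) % math.pi
        assert math.degrees(min(d, math.pi - d)) == pytest.approx(90, abs=1.0) or \
            math.degrees(d) == pytest.approx(90, abs=1.0)

    def test_tiny_blob_rejected(self):
        b = Blob(pixels=np.array([[0, 0], [0, 1]]), values=np.ones(2))
        with pytest.raises(ValueError):
            po.equivalent_ellipse(b)


class TestBSP:
    def test_symmetric_rod_splits_evenly(self):
        blob = rect_blob(100, 10)
        a, b = po.decompose_bsp(blob)
        assert abs(a.area - b.area) <= 10  # one pixel column at most

    def test_partition_is_exact(self, render_and_measure):
        blob, _ = render_and_measure(2.0, 2.0, 0.5, 0.3)
        a, b = po.decompose_bsp(blob, 0.035, (-11.0, -9.0))
        assert a.area + b.area == blob.area
        sa = {tuple(p) for p in a.pixels}
        sb = {tuple(p) for p in b.pixels}
        assert not sa & sb

    def test_rendered_head_half_is_heavier(self, render_and_measure, flow):
        blob, _ = render_and_measure(0.0, 0.0, 0.0, 0.0)  # heading +x
        a, b = po.decompose_bsp(blob, flow.pixel_size, flow.fov[:2])
        head, tail, _ = po.identify_head(a, b, None, flow.pixel_size, flow.fov[:2])
        assert head.area > tail.area
        ch = po.equivalent_ellipse(head, flow.pixel_size, flow.fov[:2]).center
        ct = po.equivalent_ellipse(tail, flow.pixel_size, flow.fov[:2]).center
        assert ch[0] > ct[0]  # head side lies along the heading

    def test_equal_halves_history_decides(self):
        blob = rect_blob(100, 10)
        a, b = po.decompose_bsp(blob)
        prev_head = po.equivalent_ellipse(a)
        prev = po.PoseSample(
            t=0, x_mm=0, y_mm=0, rho=1, theta=0, alpha=0, kappa=0,
            head=prev_head, tail=None,
        )
        head, _, flags = po.identify_head(a, b, prev)
        assert {tuple(p) for p in head.pixels} == {tuple(p) for p in a.pixels}
        assert "head_ambiguous" not in flags

    def test_equal_halves_no_history_flagged(self):
        blob = rect_blob(100, 10)
        a, b = po.decompose_bsp(blob)
        head, _, flags = po.identify_head(a, b, None)
        assert "head_ambiguous" in flags
        ch = po.equivalent_ellipse(head).center
        assert ch[0] <= po.equivalent_ellipse(blob).center[0]  # smaller-x tie-break


class TestAlphaConvention:
    def test_pointing_away_from_sink_is_zero(self, render_and_measure):
        theta = math.atan2(3.0, 5.0)
        _, p = render_and_measure(5.0, 3.0, theta, 0.0)  # head outward
        assert abs(math.degrees(p.alpha)) < 2.0

    def test_pointing_at_sink_is_pi(self, render_and_measure):
        theta = math.atan2(3.0, 5.0)
        _, p = render_and_measure(5.0, 3.0, theta + math.pi, 0.0)
        assert abs(math.degrees(abs(p.alpha))) > 178.0

    def test_30_degrees_off_radial(self, render_and_measure):
        theta = math.atan2(-4.0, 2.0)
        _, p = render_and_measure(2.0, -4.0, theta + math.radians(30), 0.0)
        assert math.degrees(p.alpha) == pytest.approx(30, abs=2.0)

    def test_receding_track_has_alpha_zero_and_rho_growing(self, flow, larva, pipe_cfg):
        """Counterflow-oriented motion: alpha ~ 0 while rho increases,
        matching the sign convention of the impulse term u cos(alpha)."""
        from rheopipe import segmentation as seg
        from rheopipe.posture import pose_from_blob

        rhos, alphas = [], []
        bg = np.zeros(flow.shape, dtype=np.float32)
        for i in range(5):
            r = 5.0 + 0.5 * i
            xy = np.array([r * math.cos(0.7), r * math.sin(0.7)])
            canvas = np.zeros(flow.shape, dtype=np.float32)
            sd.render_pose(canvas, xy, 0.7, 0.0, larva, flow)
            blob = seg.segment_frame(canvas, bg, pipe_cfg.segmentation, flow.pixel_size)[0]
            p = pose_from_blob(blob, flow)
            rhos.append(p.rho)
            alphas.append(p.alpha)
        assert np.all(np.diff(rhos) > 0)
        assert np.max(np.abs(np.degrees(alphas))) < 2.0


class TestSignedCurvature:
    def test_straight_rod_zero(self, render_and_measure):
        _, p = render_and_measure(-2.0, -3.0, 2.0, 0.0)
        assert p.kappa == 0.0

    @pytest.mark.parametrize("radius", [1.5, 2.0, 3.0])
    def test_arc_radius_recovered(self, render_and_measure, radius):
        _, p = render_and_measure(1.0, 2.0, 0.3, 1.0 / radius)
        assert abs(p.kappa) == pytest.approx(1.0 / radius, rel=0.10)

    def test_mirror_flips_sign(self, render_and_measure):
        _, p = render_and_measure(3.0, 1.0, 0.2, 0.4)
        _, pm = render_and_measure(3.0, -1.0, -0.2, -0.4)
        assert np.sign(pm.kappa) == -np.sign(p.kappa)
        assert abs(pm.kappa) == pytest.approx(abs(p.kappa), rel=0.02)

    def test_rotation_about_sink_equivariance(self, render_and_measure):
        rot = math.radians(40)
        _, p = render_and_measure(5.0, 1.0, 1.0, 0.3)
        r0 = math.hypot(5.0, 1.0)
        th0 = math.atan2(1.0, 5.0)
        _, q = render_and_measure(
            r0 * math.cos(th0 + rot), r0 * math.sin(th0 + rot), 1.0 + rot, 0.3
        )
        assert q.rho == pytest.approx(p.rho, abs=0.05)
        assert q.kappa == pytest.approx(p.kappa, rel=0.05)
        da = (q.alpha - p.alpha + math.pi) % (2 * math.pi) - math.pi
        assert abs(math.degrees(da)) < 1.0
        dth = (q.theta - p.theta - rot + math.pi) % (2 * math.pi) - math.pi
        assert abs(math.degrees(dth)) < 0.5

    def test_scale_consistency_of_kappa(self, larva, seg_params):
        """Halving the pixel size changes the measured curvature < 5%."""
        from rheopipe.config import FlowConfig
        from rheopipe import segmentation as seg
        from rheopipe.posture import pose_from_blob

        kappas = []
        for px in (0.035, 0.0175):
            cfg = FlowConfig(pixel_size=px, fov=(-6.0, -6.0, 12.0, 12.0), sink=(-5.0, -5.0))
            canvas = np.zeros(cfg.shape, dtype=np.float32)
            sd.render_pose(canvas, np.array([0.0, 0.0]), 0.8, 0.3, larva, cfg)
            bg = np.zeros(cfg.shape, dtype=np.float32)
            blob = seg.segment_frame(canvas, bg, seg_params, cfg.pixel_size)[0]
            kappas.append(pose_from_blob(blob, cfg).kappa)
        assert kappas[1] == pytest.approx(kappas[0], rel=0.05)
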