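import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from rheopipe.bouts import BoutKinematics, build_series
from rheopipe.config import FlowConfig
from rheopipe.posture import PoseSample
from rheopipe import stats as st
from rheopipe.tracking import Track


def bout(k, t_k, rho_k=8.0, a_on=0.0, a_off=0.0, u=20.0, v_f=1.0):
    return BoutKinematics(
        k=k, t_k=t_k, rho_k=rho_k, alpha_onset=a_on, alpha_offset=a_off,
        v_f=v_f, c=0.0, u=u, lam=0.04, n=5, tau_b=0.025,
        mean_abs_kappa=0.2, fit_rms=0.01,
    )


class TestCircularVariance:
    def test_equally_spaced_angles_give_one(self):
        a = np.linspace(0, 2 * math.pi, 8, endpoint=False)
        assert st.circular_variance(a) == pytest.approx(1.0, abs=1e-12)

    def test_identical_angles_give_zero(self):
        assert st.circular_variance(np.full(100, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_pair(self):
        # 1 - |(1 + i)/2| = 1 - sqrt(2)/2
        got = st.circular_variance([0.0, math.pi / 2])
        assert got == pytest.approx(1 - math.sqrt(2) / 2, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.circular_variance([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hst.lists(hst.floats(-math.pi, math.pi), min_size=1, max_size=30),
        hst.floats(-10, 10),
    )
    def test_bounded_and_rotation_invariant(self, angles, rot):
        v = st.circular_variance(angles)
        assert -1e-12 <= v <= 1 + 1e-12
        assert st.circular_variance(np.asarray(angles) + rot) == pytest.approx(v, abs=1e-9)


class TestLabelCss:
    def test_exploration_only_unlabeled(self):
        rng = np.random.default_rng(0)
        bouts = [
            bout(k, t_k=k * 1.0, a_on=rng.uniform(-math.pi, math.pi),
                 a_off=rng.uniform(-math.pi, math.pi))
            for k in range(10)
        ]
        # force impulses toward the sink so no counterflow run exists
        for b in bouts:
            b.alpha_onset = math.pi
        lab = st.label_css(build_series(bouts, 1))
        assert lab.onset is None

    def test_programmed_onset_found(self):
        bouts = [bout(k, k * 1.0, a_on=math.pi, a_off=2.0) for k in range(5)]
        bouts += [bout(5 + k, 5.0 + k, a_on=0.1, a_off=0.05) for k in range(4)]
        lab = st.label_css(build_series(bouts, 1))
        assert lab.onset == 5

    def test_run_length_one_takes_first_counterflow_bout(self):
        bouts = [bout(0, 0.0, a_on=math.pi, a_off=3.0), bout(1, 1.0, a_on=0.0, a_off=0.1)]
        lab = st.label_css(build_series(bouts, 1), run_length=1)
        assert lab.onset == 1

    def test_run_broken_by_misaligned_offset(self):
        bouts = [bout(k, k * 1.0, a_on=0.0, a_off=0.1) for k in range(7)]
        bouts[2].alpha_offset = 1.5  # > 45 degrees breaks the run
        lab = st.label_css(build_series(bouts, 1), run_length=3)
        assert lab.onset == 3


class TestKde:
    def test_single_point_is_gaussian(self):
        d = st.kde([0.0], bandwidth=1.0)
        i = np.argmin(np.abs(d.grid))
        assert d.density[i] == pytest.approx(1 / math.sqrt(2 * math.pi), rel=1e-4)

    def test_normalization(self):
        rng = np.random.default_rng(1)
        d = st.kde(rng.normal(3.0, 2.0, 200), bandwidth=0.5)
        assert d.integral() == pytest.approx(1.0, abs=1e-6)

    def test_two_distant_points_two_equal_modes(self):
        d = st.kde([-5.0, 5.0], bandwidth=1.0)
        i1 = np.argmin(np.abs(d.grid + 5))
        i2 = np.argmin(np.abs(d.grid - 5))
        assert d.density[i1] == pytest.approx(d.density[i2], rel=1e-6)
        assert d.density[i1] == pytest.approx(0.5 / math.sqrt(2 * math.pi), rel=1e-3)

    def test_permutation_invariance(self):
        x = np.array([1.0, 2.0, 4.0, -1.0])
        g = np.linspace(-10, 10, 101)
        a = st.kde(x, 0.7, grid=g)
        b = st.kde(x[::-1], 0.7, grid=g)
        assert np.allclose(a.density, b.density)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            st.kde([1.0, 2.0], bandwidth=0.0)


class TestCompareDistributions:
    def test_identical_samples_zero_distance(self):
        x = np.arange(10.0)
        d, p, stars = st.compare_distributions(x, x, "ks")
        assert d == 0.0 and stars == ""

    def test_disjoint_constant_samples_full_distance(self):
        d, _, _ = st.compare_distributions(np.zeros(5), np.ones(5), "ks")
        assert d == 1.0

    def test_ks_matches_bruteforce_cdf_gap(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            x = rng.normal(0, 1, rng.integers(2, 12))
            y = rng.normal(0.3, 1.2, rng.integers(2, 12))
            d, _, _ = st.compare_distributions(x, y, "ks")
            pts = np.concatenate([x, y])
            gap = max(
                abs((x <= v).mean() - (y <= v).mean()) for v in pts
            )
            assert d == pytest.approx(gap, abs=1e-12)

    def test_welch_detects_mean_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 200)
        y = rng.normal(2, 1, 200)
        t, p, stars = st.compare_distributions(x, y, "welch")
        assert p < 1e-6 and stars == "**"

    def test_degenerate_welch_rejected(self):
        with pytest.raises(ValueError):
            st.compare_distributions(np.zeros(5), np.zeros(5), "welch")


class TestRadialProfile:
    def test_perfect_holding_gives_zero_profile(self):
        bouts = [bout(k, k * 1.0, rho_k=8.0) for k in range(10)]
        s = build_series(bouts, 1)
        centers, mean, sem, counts, hist = st.radial_profile([s], np.array([7.0, 9.0]))
        assert mean[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_masked(self):
        s = build_series([bout(0, 0.0, rho_k=8.0), bout(1, 1.0, rho_k=8.5)], 1)
        centers, mean, sem, counts, hist = st.radial_profile([s], np.array([7.0, 9.0]))
        assert np.isnan(mean[0]) and counts[0] == 1

    def test_restoring_series_crosses_zero_at_operating_point(self):
        rng = np.random.default_rng(5)
        series = []
        for i in range(30):
            rhos = [rng.uniform(4.0, 12.0)]
            for _ in range(10):
                rhos.append(rhos[-1] + 0.3 * (8.0 - rhos[-1]))  # attracted to 8
            series.append(build_series([bout(k, k * 1.0, rho_k=r) for k, r in enumerate(rhos)], i))
        edges = np.arange(4.0, 12.5, 1.0)
        centers, mean, sem, counts, _ = st.radial_profile(series, edges)
        ok = ~np.isnan(mean)
        signs = np.sign(mean[ok])
        assert np.all(signs[centers[ok] < 7.5] > 0)  # below: pushed out
        assert np.all(signs[centers[ok] > 8.5] < 0)  # above: pulled in


class TestOnsetSummary:
    def _series_with_onset(self, lid, rho1, v1):
        bouts = [bout(0, 0.0, rho_k=rho1, a_on=0.0, a_off=0.1, v_f=v1)]
        bouts += [bout(1 + k, 1.0 + k, rho_k=rho1, a_on=0.0, a_off=0.1, v_f=v1) for k in range(3)]
        return build_series(bouts, lid)

    def test_group_means_and_flat_trigger(self):
        cfg = FlowConfig()
        rng = np.random.default_rng(6)
        series, groups = [], []
        for g, Q in enumerate([70, 220, 440]):
            for i in range(10):
                series.append(self._series_with_onset(g * 100 + i, 8.0 + rng.normal(0, 0.1), Q / 220.0))
                groups.append(Q)
        labels = [st.label_css(s) for s in series]
        per_group, ks, p = st.onset_summary(series, labels, groups, cfg,
                                            rng=np.random.default_rng(0))
        means = [v["mean_rho1"] for v in per_group.values()]
        assert max(means) - min(means) < 0.2  # flat across flow rates
        v1s = {g: v["mean_v1"] for g, v in per_group.items()}
        assert v1s[440] == pytest.approx(2 * v1s[220], rel=1e-9)
        assert p < 1e-3  # concentrated rho1 differs from uniform positions

    def test_null_sample_not_rejected(self):
        cfg = FlowConfig()
        rng = np.random.default_rng(7)
        x0, y0, w, h = cfg.fov
        pts = rng.uniform([x0, y0], [x0 + w, y0 + h], size=(40, 2))
        rhos = np.hypot(pts[:, 0], pts[:, 1])
        series = [self._series_with_onset(i, r, 1.0) for i, r in enumerate(rhos)]
        labels = [st.label_css(s) for s in series]
        _, ks, p = st.onset_summary(series, labels, [0] * len(series), cfg,
                                    rng=np.random.default_rng(1))
        assert p > 1e-3


class TestEgocentricDensity:
    def _poses(self, alphas, rho=6.0):
        return [
            PoseSample(t=0, x_mm=0, y_mm=0, rho=rho, theta=0.0, alpha=a, kappa=0.0)
            for a in alphas
        ]

    def test_facing_sink_mass_ahead(self):
        xe, ye, d = st.egocentric_density(self._poses([math.pi] * 50), FlowConfig())
        xc = (xe[:-1] + xe[1:]) / 2
        mass_x = d.sum(axis=1) * np.diff(xe)[0]
        assert xc[np.argmax(mass_x)] > 0

    def test_facing_away_mass_behind(self):
        xe, ye, d = st.egocentric_density(self._poses([0.0] * 50), FlowConfig())
        xc = (xe[:-1] + xe[1:]) / 2
        mass_x = d.sum(axis=1) * np.diff(xe)[0]
        assert xc[np.argmax(mass_x)] < 0

    def test_uniform_angles_make_a_ring(self):
        alphas = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        xe, ye, d = st.egocentric_density(self._poses(alphas, rho=6.0), FlowConfig())
        xc = (xe[:-1] + xe[1:]) / 2
        yc = (ye[:-1] + ye[1:]) / 2
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        r = np.hypot(xx, yy)
        occupied = d > 0
        assert abs(r[occupied].mean() - 6.0) < 0.5
        cell = (xe[1] - xe[0]) ** 2
        assert d.sum() * cell == pytest.approx(1.0, abs=1e-9)


class TestAlignedCircvar:
    def _track(self, lid, alphas, t0=0.0, fr=10.0):
        poses = [
            PoseSample(t=t0 + i / fr, x_mm=0, y_mm=0, rho=8.0, theta=0.0,
                       alpha=a, kappa=0.0, frame=i, larva_id=lid)
            for i, a in enumerate(alphas)
        ]
        return Track(lid, poses)

    def test_uniform_before_aligned_after(self):
        rng = np.random.default_rng(8)
        tracks, series = [], []
        for lid in range(30):
            onset_t = 5.0
            pre = rng.uniform(-math.pi, math.pi, 50)
            post = rng.normal(0, 0.1, 50)
            tracks.append(self._track(lid, np.concatenate([pre, post])))
            bouts = [bout(0, onset_t, a_on=0.0, a_off=0.05)]
            bouts += [bout(1 + k, onset_t + 1 + k, a_on=0.0, a_off=0.05) for k in range(3)]
            series.append(build_series(bouts, lid))
        labels = [st.label_css(s) for s in series]
        centers, var_c, counts = st.aligned_circvar(
            tracks, series, labels, bin_s=1.0, window_s=5.0, mode="frame"
        )
        pre_bins = var_c[(centers < 0) & ~np.isnan(var_c)]
        post_bins = var_c[(centers > 0) & ~np.isnan(var_c)]
        assert np.all(pre_bins > 0.7)
        assert np.all(post_bins < 0.1)

    def test_no_labels_rejected(self):
        tr = self._track(0, np.zeros(10))
        s = build_series([bout(0, 0.0, a_on=math.pi, a_off=3.0)], 0)
        labels = [st.label_css(s)]
        with pytest.raises(ValueError):
            st.aligned_circvar([tr], [s], labels)

    def test_shuffled_onsets_flatten_curve(self):
        rng = np.random.default_rng(9)
        tracks, series = [], []
        for lid in range(40):
            pre = rng.uniform(-math.pi, math.pi, 40)
            post = rng.normal(0, 0.1, 40)
            tracks.append(self._track(lid, np.concatenate([pre, post])))
            bouts = [bout(0, 4.0, a_on=0.0, a_off=0.05)]
            bouts += [bout(1 + k, 5.0 + k, a_on=0.0, a_off=0.05) for k in range(3)]
            series.append(build_series(bouts, lid))
        labels = [st.label_css(s) for s in series]
        centers, v_true, _ = st.aligned_circvar(tracks, series, labels, bin_s=1.0,
                                                window_s=4.0, mode="frame")
        # shuffle: shift each track's onset randomly
        for s, lab in zip(series, labels):
            s.bouts[lab.onset].t_k = float(rng.uniform(0.5, 9.5))
        centers, v_shuf, _ = st.aligned_circvar(tracks, series, labels, bin_s=1.0,
                                                window_s=4.0, mode="frame")
        drop_true = np.nanmean(v_true[centers < 0]) - np.nanmean(v_true[centers > 0])
        drop_shuf = np.nanmean(v_shuf[centers < 0]) - np.nanmean(v_shuf[centers > 0])
        assert drop_shuf < 0.6 * drop_true
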