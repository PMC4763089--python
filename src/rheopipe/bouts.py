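"""Swim-bout detection from curvature traces and per-bout kinematics.

Detection: the curvature derivative's sliding standard deviation (20 ms
window) is normalized by a quiet baseline — within each centered 400 ms
window, the mean of the sub-median values — and a bout is any run of the
normalized activity above 5 lasting more than 40 ms.  Tail beats are
excursions of the curvature (relative to its pre-bout baseline) beyond 0.1
per mm, one beat per pair of sign-alternating excursions.

Kinematics: within each bout the time of minimum radial position defines the
impulse start t_k; the 100 ms before t_k give the fluid drift by an affine
fit, and the up-to-300 ms after t_k are fitted by the Stokes-drag impulse
response

    rho(t_k + dt) = rho_k + lam * u * cos(alpha) * (1 - exp(-dt/lam)) - v_f * dt

with the impulse speed u >= 0 and the damping time lam in [4, 500] ms as the
only free parameters (v_f and alpha held fixed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BoutKinematics",
    "BoutSeries",
    "bout_activity",
    "detect_bouts",
    "count_tail_beats",
    "fit_bout_kinematics",
    "build_series",
    "extract_bouts",
]

LAMBDA_BOUNDS = (0.004, 0.500)  # s
LAMBDA_STARTS = (0.020, 0.040, 0.080)  # multi-start initial guesses, s


def _sliding_std(x: np.ndarray, win: int) -> np.ndarray:
    """Centered sliding standard deviation with edge windows shrunk."""
    n = x.size
    half = win // 2
    pad = np.pad(x, half, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(pad, win)[:n]
    return view.std(axis=1)


def bout_activity(kappa: np.ndarray, frame_rate: float) -> tuple[np.ndarray, bool]:
    """Normalized curvature activity trace; returns (activity, degenerate).

    kappa-dot by central differences (reflected ends), sigma over a 20 ms
    sliding window, divided by the per-sample quiet baseline: within a
    centered 400 ms window, the mean of the sigma values lying strictly
    below that window's median.  A constant trace has no baseline; the
    activity is then defined as zero and flagged.
    """
    kappa = np.asarray(kappa, dtype=float)
    if kappa.size < int(round(0.4 * frame_rate)):
        raise ValueError("trace must be at least 400 ms long")
    dt = 1.0 / frame_rate
    kdot = np.gradient(np.pad(kappa, 1, mode="reflect"))[1:-1] / dt
    win_s = max(3, int(round(0.020 * frame_rate)))
    sigma = _sliding_std(kdot, win_s)

    win_b = int(round(0.400 * frame_rate))
    if win_b % 2 == 0:
        win_b += 1
    half = win_b // 2
    pad = np.pad(sigma, half, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(pad, win_b)[: sigma.size]
    med = np.median(view, axis=1)
    below = view < med[:, None]
    cnt = below.sum(axis=1)
    tot = np.where(below, view, 0.0).sum(axis=1)
    baseline = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
    degenerate = bool(np.all(sigma <= 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        activity = np.where(baseline > 0, sigma / baseline, 0.0)
    # a dead-quiet baseline (kappa locked at a constant between bouts) makes
    # any curvature activity infinitely salient
    activity[(baseline <= 0) & (sigma > 0)] = np.inf
    return activity, degenerate


def detect_bouts(
    activity: np.ndarray,
    frame_rate: float,
    threshold: float = 5.0,
    min_duration: float = 0.040,
) -> list[tuple[int, int]]:
    """Maximal runs of activity > threshold lasting more than min_duration.

    Returns half-open sample intervals [start, stop), disjoint and
    time-ordered.
    """
    above = np.asarray(activity) > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    out = []
    for a, b in zip(starts, stops):
        if (b - a) / frame_rate > min_duration:
            out.append((int(a), int(b)))
    return out


def count_tail_beats(
    kappa: np.ndarray,
    interval: tuple[int, int],
    frame_rate: float,
    beat_threshold: float = 0.1,
) -> tuple[int, float, float]:
    """Tail-beat count, mean beat period and mean |relative curvature|.

    The relative curvature is kappa minus its pre-bout baseline (mean over
    the 100 ms before onset).  Beats are excursions of |relative kappa|
    above ``beat_threshold``; a full beat is a pair of sign-alternating
    excursions.  The beat period is twice the mean spacing of consecutive
    excursion peaks.  Returns (n, tau_b, mean_abs_kappa); n = 0 when no
    excursion crosses the threshold (tau_b is then nan).
    """
    kappa = np.asarray(kappa, dtype=float)
    a, b = interval
    pre = kappa[max(0, a - int(round(0.100 * frame_rate))) : a]
    baseline = float(pre.mean()) if pre.size else 0.0
    rel = kappa[a:b] - baseline
    mean_abs = float(np.abs(rel).mean()) if rel.size else 0.0

    above = np.abs(rel) > beat_threshold
    if not above.any():
        return 0, float("nan"), mean_abs
    # maximal runs of |rel| above threshold, each with a definite sign
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    peaks, signs = [], []
    for s0, s1 in zip(starts, stops):
        seg = rel[s0:s1]
        i = int(np.argmax(np.abs(seg)))
        peaks.append(s0 + i)
        signs.append(1.0 if seg[i] > 0 else -1.0)
    # merge same-sign neighbours (a beat's lobe split by noise)
    merged_peaks, merged_signs = [peaks[0]], [signs[0]]
    for p, s in zip(peaks[1:], signs[1:]):
        if s == merged_signs[-1]:
            continue
        merged_peaks.append(p)
        merged_signs.append(s)
    n_exc = len(merged_peaks)
    n = (n_exc + 1) // 2
    if n_exc > 1:
        tau_b = 2.0 * float(np.mean(np.diff(merged_peaks))) / frame_rate
    else:
        tau_b = float("nan")
    return n, tau_b, mean_abs


@dataclass
class BoutKinematics:
    """Fitted kinematics of one swim bout."""

    k: int
    t_k: float
    rho_k: float
    alpha_onset: float
    alpha_offset: float
    v_f: float  # fluid speed toward the sink (= -slope of pre-bout drift), mm/s
    c: float  # affine intercept at t_k, mm
    u: float  # impulse speed, mm/s
    lam: float  # damping time, s
    n: int
    tau_b: float
    mean_abs_kappa: float
    fit_rms: float
    interval: tuple[int, int] = (0, 0)
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class BoutSeries:
    """Bouts of one track plus inter-bout periods tau and distances delta."""

    larva_id: int
    bouts: list[BoutKinematics]

    @property
    def tau(self) -> np.ndarray:
        t = np.array([b.t_k for b in self.bouts])
        return np.diff(t)

    @property
    def delta(self) -> np.ndarray:
        r = np.array([b.rho_k for b in self.bouts])
        return np.diff(r)


def _impulse_model(dt: np.ndarray, u: float, lam: float, v_f: float, cos_a: float) -> np.ndarray:
    return lam * u * cos_a * (1.0 - np.exp(-dt / lam)) - v_f * dt


def fit_bout_kinematics(
    t: np.ndarray,
    rho: np.ndarray,
    interval: tuple[int, int],
    alpha_onset: float,
    frame_rate: float,
    next_bout_start: int | None = None,
    k: int = 0,
    alpha_offset: float = float("nan"),
    n_beats: int = 0,
    tau_b: float = float("nan"),
    mean_abs_kappa: float = float("nan"),
) -> BoutKinematics:
    """Fit the pre-bout drift and the post-bout impulse response of one bout.

    ``t`` and ``rho`` are the track's time and radial-position samples
    (regularly sampled), ``interval`` the detected bout in sample indices.
    t_k is the argmin of rho within the bout interval (computed on a
    5-sample median-filtered copy so a single noisy sample cannot shift it);
    the affine drift is fitted on the 100 ms before t_k, and rho_k is the
    affine value at t_k (the raw minimum sample carries a selection bias).
    u and lam are then fitted on (t_k, t_k + 300 ms] intersected with
    (t_k, next_bout_start) by bounded nonlinear least squares with
    multi-start on lam.
    """
    t = np.asarray(t, dtype=float)
    rho = np.asarray(rho, dtype=float)
    a, b = interval
    flags: tuple[str, ...] = ()

    from scipy.signal import medfilt

    seg = rho[a:b]
    if seg.size >= 5:
        seg_f = medfilt(seg, kernel_size=5)
        seg_f[:2], seg_f[-2:] = seg[:2], seg[-2:]
    else:
        seg_f = seg
    ik = a + int(np.argmin(seg_f))
    t_k = float(t[ik])

    n_pre = int(round(0.100 * frame_rate))
    i0 = max(0, ik - n_pre)
    tp = t[i0 : ik + 1] - t_k
    rp = rho[i0 : ik + 1]
    if tp.size >= 2:
        slope, c = np.polyfit(tp, rp, 1)
    else:
        slope, c = 0.0, float(rho[ik])
        flags += ("no_prefit",)
    v_f = -float(slope)  # positive = drift toward the sink
    rho_k = float(c)

    n_post = int(round(0.300 * frame_rate))
    stop = min(rho.size, ik + 1 + n_post)
    if next_bout_start is not None:
        stop = min(stop, next_bout_start)
    dts = t[ik + 1 : stop] - t_k
    robs = rho[ik + 1 : stop] - rho_k
    cos_a = math.cos(alpha_onset)

    u_hat, lam_hat, rms = 0.0, float("nan"), float("nan")
    if dts.size < 5:
        flags += ("unfit",)
    else:
        def resid(p):
            return _impulse_model(dts, p[0], p[1], v_f, cos_a) - robs

        best = None
        disp = robs[-1] + v_f * dts[-1]
        for lam0 in LAMBDA_STARTS:
            u0 = abs(disp) / lam0 if abs(cos_a) > 0.1 else 1.0
            u0 = float(np.clip(u0, 1e-3, 1e3))
            try:
                sol = least_squares(
                    resid,
                    x0=[u0, lam0],
                    bounds=([0.0, LAMBDA_BOUNDS[0]], [np.inf, LAMBDA_BOUNDS[1]]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success and best.cost > 1e-6:
            flags += ("fit_failed",)
        if best is not None:
            u_hat, lam_hat = float(best.x[0]), float(best.x[1])
            rms = float(np.sqrt(np.mean(best.fun**2)))

    return BoutKinematics(
        k=k,
        t_k=t_k,
        rho_k=rho_k,
        alpha_onset=float(alpha_onset),
        alpha_offset=float(alpha_offset),
        v_f=v_f,
        c=float(c),
        u=u_hat,
        lam=lam_hat,
        n=n_beats,
        tau_b=tau_b,
        mean_abs_kappa=mean_abs_kappa,
        fit_rms=rms,
        interval=(int(a), int(b)),
        flags=flags,
    )


def build_series(bouts: list[BoutKinematics], larva_id: int = -1) -> BoutSeries:
    """Assemble time-ordered bouts into a series with tau_k and delta_k."""
    bouts = sorted(bouts, key=lambda b: b.t_k)
    return BoutSeries(larva_id=larva_id, bouts=bouts)


def extract_bouts(
    t: np.ndarray,
    rho: np.ndarray,
    alpha: np.ndarray,
    kappa: np.ndarray,
    frame_rate: float,
    activity_threshold: float = 5.0,
    min_bout_duration: float = 0.040,
    beat_threshold: float = 0.1,
    larva_id: int = -1,
) -> BoutSeries:
    """Full per-track bout analysis: detect, count beats, fit kinematics.

    alpha_onset/offset are the body angles at the first and last sample of
    each detected bout interval.
    """
    activity, _ = bout_activity(kappa, frame_rate)
    intervals = detect_bouts(activity, frame_rate, activity_threshold, min_bout_duration)
    out = []
    for k, (a, b) in enumerate(intervals):
        nxt = intervals[k + 1][0] if k + 1 < len(intervals) else None
        n, tb, mak = count_tail_beats(kappa, (a, b), frame_rate, beat_threshold)
        bk = fit_bout_kinematics(
            t,
            rho,
            (a, b),
            alpha_onset=float(alpha[a]),
            frame_rate=frame_rate,
            next_bout_start=nxt,
            k=k,
            alpha_offset=float(alpha[min(b, alpha.size - 1) - 1]),
            n_beats=n,
            tau_b=tb,
            mean_abs_kappa=mak,
        )
        out.append(bk)
    return build_series(out, larva_id)
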