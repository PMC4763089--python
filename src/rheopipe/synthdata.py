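"""Ground-truthed synthetic rheotaxis sessions.

This module emulates the radial-suction assay end to end: larvae are point
bodies with a heading and an instantaneous body curvature, advected by a
depth-averaged point-sink flow (radial speed q/rho with q = Q_v / 2 pi h),
propelled by discrete swim bouts whose radial signature follows the
exponential impulse response

    rho(t > t_k) = rho_k + lam * u * cos(alpha) * (1 - exp(-(t-t_k)/lam)) - v_f (t-t_k)

and rendered as bright bent rods on a dark background at the nominal imaging
scale (250 Hz, 35 um/pixel).  Every stage of the analysis pipeline can be
tested against the returned ground truth.

Behavioral program (see :class:`rheopipe.config.BehaviorParams`): larvae
explore with randomly oriented bouts until they drift inside a trigger
radius; after a short reaction delay they switch to a counterflow swim
sequence (CSS) of bouts aimed against the flow whose pacing holds radial
position on average.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .config import BehaviorParams, FlowConfig, LarvaModel, NoiseParams

__all__ = [
    "GroundTruth",
    "flow_speed",
    "flow_velocity",
    "simulate_session",
    "render_pose",
    "render_frame",
    "render_frames",
    "iter_frames",
    "write_session",
]


# ---------------------------------------------------------------------------
# Flow field
# ---------------------------------------------------------------------------

def flow_speed(rho, config: FlowConfig):
    """Fluid speed q/rho (mm/s) at radial distance ``rho`` from the sink.

    The depth-averaged sink flow is purely radial and decays as 1/rho;
    ``rho`` must be strictly positive.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    out = config.q / rho
    return float(out) if out.ndim == 0 else out


def flow_velocity(pos: np.ndarray, config: FlowConfig) -> np.ndarray:
    """Flow velocity vector (mm/s) at arena position ``pos`` (mm)."""
    d = np.asarray(pos, dtype=float) - np.asarray(config.sink)
    rho = float(np.hypot(*d))
    if rho <= 0:
        return np.zeros(2)
    return -config.q / rho**2 * d


# ---------------------------------------------------------------------------
# Body geometry
# ---------------------------------------------------------------------------

_N_CENTERLINE = 257


def _continuum_head_axis(larva: LarvaModel, kappa: float, s_ref: float) -> float:
    """Head-axis angle of the continuum body at curvature ``kappa``.

    Mimics the posture stage on the ideal (un-pixelated) body: mass-weighted
    global principal axis, BSP split through the centroid, principal axis of
    the head half.  Heading is 0 and the tangent at ``s_ref`` anchors the arc.
    """
    n = 1024
    s = np.linspace(0.0, larva.L, n)
    w = larva.widths(s / larva.L)
    phi = -kappa * (s - s_ref)
    if abs(kappa) > 1e-9:
        c = np.array([0.0, -1.0]) / kappa
        pts = c - np.stack([np.sin(phi), -np.cos(phi)], axis=1) / kappa
    else:
        pts = np.stack([s - s_ref, np.zeros(n)], axis=1)
    nrm = np.stack([-np.sin(phi), np.cos(phi)], axis=1)  # strip normal

    def principal(sel):
        m = w[sel]
        p = pts[sel]
        nn = nrm[sel]
        c0 = (p * m[:, None]).sum(axis=0) / m.sum()
        d = p - c0
        cov = (d[:, :, None] * d[:, None, :] * m[:, None, None]).sum(axis=0)
        # across-width spread of each strip: variance w^2/3 along the normal
        cov += ((m * w[sel] ** 2 / 3.0)[:, None, None] * (nn[:, :, None] * nn[:, None, :])).sum(axis=0)
        cov /= m.sum()
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, 1]
        return c0, v

    c_all, v_all = principal(np.ones(n, dtype=bool))
    proj = (pts - c_all) @ v_all
    head_sel = proj >= 0 if proj[-1] >= 0 else proj <= 0
    c_h, v_h = principal(head_sel)
    if float(v_h @ (c_h - c_all)) < 0:
        v_h = -v_h
    return math.atan2(v_h[1], v_h[0])


@lru_cache(maxsize=32)
def _head_axis_arclength(larva: LarvaModel) -> float:
    """Arclength (mm, from tail tip) where the head-axis tangent is taken.

    Chosen so that, on the ideal continuum body at a representative
    curvature, the head-half principal axis (what the posture stage reports)
    coincides with the local tangent.  Solved by fixed-point iteration on
    s_ref using tangent(s) = heading - kappa (s - s_ref).
    """
    kappa_ref = 0.3
    # initial guess: midpoint of the front half by width mass
    s = np.linspace(0.0, 1.0, 513)
    w = larva.widths(s)
    cum = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
    cum /= cum[-1]
    s_split = float(np.interp(0.5, cum, s))
    s_ref = larva.L * (s_split + 1.0) / 2.0
    for _ in range(4):
        phi_m = _continuum_head_axis(larva, kappa_ref, s_ref)
        s_ref = float(np.clip(s_ref - phi_m / kappa_ref, 0.0, larva.L))
    return s_ref


def centerline(
    pose_xy: np.ndarray,
    heading: float,
    kappa: float,
    larva: LarvaModel,
    n: int = _N_CENTERLINE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centerline points (n, 2), half-widths (n,) and the reference point.

    The body is a circular arc of signed curvature ``kappa`` (positive when
    the center of curvature lies to the right of the heading); the tangent at
    the head-axis reference point equals ``heading`` and the width-weighted
    centroid sits at ``pose_xy``.  The returned reference point is the arena
    position where the tangent equals ``heading``.
    """
    if abs(kappa) * larva.L >= math.pi:
        raise ValueError("body closes on itself: |kappa| * L must be < pi")
    s = np.linspace(0.0, larva.L, n)
    w = larva.widths(s / larva.L)
    s_ref = _head_axis_arclength(larva)
    phi = heading - kappa * (s - s_ref)
    if abs(kappa) > 1e-9:
        # center of curvature relative to the reference point
        c = np.array([math.sin(heading), -math.cos(heading)]) / kappa
        pts = c - np.stack([np.sin(phi), -np.cos(phi)], axis=1) / kappa
    else:
        d = np.array([math.cos(heading), math.sin(heading)])
        pts = (s - s_ref)[:, None] * d
    centroid = (pts * w[:, None]).sum(axis=0) / w.sum()
    shift = np.asarray(pose_xy, dtype=float) - centroid
    return pts + shift, w, shift  # reference point was at the origin


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Programmed session: per-frame poses, bout schedule, phase labels.

    ``poses`` columns: frame, t, larva_id, x_mm, y_mm, heading_rad,
    kappa_per_mm, phase ('exploration' | 'css').
    ``bouts`` columns: larva_id, k, t_k_s, rho_k_mm, u_mm_s, lambda_s, n,
    tau_b_s, mean_abs_kappa_per_mm, target_heading_rad, phase, css_onset.
    """

    poses: pd.DataFrame
    bouts: pd.DataFrame
    config: FlowConfig
    larva: LarvaModel
    behavior: BehaviorParams
    seed: int
    n_frames: int = 0

    def larva_poses(self, larva_id: int) -> pd.DataFrame:
        return self.poses[self.poses["larva_id"] == larva_id].reset_index(drop=True)

    def rho(self, larva_id: int) -> np.ndarray:
        p = self.larva_poses(larva_id)
        sx, sy = self.config.sink
        return np.hypot(p["x_mm"] - sx, p["y_mm"] - sy).to_numpy()


def _wrap(a):
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


@dataclass
class _LarvaState:
    pos: np.ndarray
    heading: float
    rng_sched: np.random.Generator
    rng_kin: np.random.Generator
    next_bout_t: float = math.inf
    css_pending_t: float | None = None
    css_active: bool = False
    bout: dict | None = field(default=None)
    bouts: list = field(default_factory=list)
    frozen: bool = False
    last_bout_end: float = -math.inf
    hold_rho: float = 0.0
    rho_trigger: float = 0.0


def _draw_bout(state: _LarvaState, t: float, target_heading: float, beh: BehaviorParams):
    rng = state.rng_kin
    u = max(2.0, rng.normal(beh.u_mean, beh.u_std))
    lam = float(np.clip(rng.normal(beh.lam_mean, beh.lam_std), 0.015, 0.120))
    n = max(2, int(rng.poisson(beh.n_beats_mean)))
    tau_b = float(np.clip(rng.normal(beh.tau_b_mean, beh.tau_b_std), 0.012, 0.050))
    kap = max(0.05, rng.normal(beh.kappa_mean, beh.kappa_std))
    return {
        "t0": t,
        "dur": n * tau_b,
        "u": u,
        "lam": lam,
        "n": n,
        "tau_b": tau_b,
        "mean_abs_kappa": kap,
        "amp": kap * math.pi / 2.0,  # mean |A sin| = 2A/pi
        "h_from": state.heading,
        "h_to": target_heading,
        "sign": 1.0 if state.rng_kin.random() < 0.5 else -1.0,
    }


def simulate_session(
    config: FlowConfig,
    larva: LarvaModel,
    behavior: BehaviorParams | None = None,
    n_larvae: int = 2,
    duration: float = 10.0,
    seed: int = 0,
    init_positions: Sequence[tuple[float, float]] | None = None,
) -> GroundTruth:
    """Simulate a session and return its full ground truth.

    Randomness flows from ``seed`` through named substreams (initial
    placement, per-larva scheduling, per-larva kinematics), so two calls with
    identical arguments are bit-identical.

    ``init_positions`` (mm, arena frame) overrides the default uniform
    placement in the field of view; positions outside the FOV are rejected.
    """
    beh = behavior or BehaviorParams()
    ss = np.random.SeedSequence([seed, 0x5E551017])
    init_ss, sched_ss, kin_ss = ss.spawn(3)
    rng_init = np.random.default_rng(init_ss)
    sched_seeds = sched_ss.spawn(n_larvae)
    kin_seeds = kin_ss.spawn(n_larvae)

    x0, y0, w, h = config.fov
    sink = np.asarray(config.sink, dtype=float)
    if init_positions is not None:
        if len(init_positions) != n_larvae:
            raise ValueError("init_positions length must equal n_larvae")
        for p in init_positions:
            if not (x0 <= p[0] <= x0 + w and y0 <= p[1] <= y0 + h):
                raise ValueError(f"initial position {p} outside fov")
        starts = [np.asarray(p, dtype=float) for p in init_positions]
    else:
        starts = []
        for _ in range(n_larvae):
            while True:
                p = np.array([x0 + rng_init.random() * w, y0 + rng_init.random() * h])
                if np.hypot(*(p - sink)) > larva.L:
                    break
            starts.append(p)

    dt = 1.0 / config.frame_rate
    n_frames = int(round(duration * config.frame_rate))
    rate = beh.explore_rate
    states = []
    for i in range(n_larvae):
        st = _LarvaState(
            pos=starts[i].copy(),
            heading=float(rng_init.uniform(-math.pi, math.pi)),
            rng_sched=np.random.default_rng(sched_seeds[i]),
            rng_kin=np.random.default_rng(kin_seeds[i]),
        )
        if rate > 0:
            st.next_bout_t = st.rng_sched.exponential(1.0 / rate)
        states.append(st)

    rec_frame, rec_t, rec_id = [], [], []
    rec_x, rec_y, rec_h, rec_k, rec_phase = [], [], [], [], []

    for fi in range(n_frames):
        t = fi * dt
        for li, st in enumerate(states):
            rel = st.pos - sink
            rho = float(np.hypot(*rel))
            radial = math.atan2(rel[1], rel[0])

            # ---- event handling -------------------------------------------
            if st.bout is not None and t >= st.bout["t0"] + st.bout["dur"]:
                b = st.bout
                st.heading = b["h_to"]
                st.bout = None
                st.last_bout_end = t
                if st.css_active:
                    # next bout fires when the larva drifts back to its hold
                    # radius (checked below); jitter the per-cycle threshold
                    st.rho_trigger = st.hold_rho * float(
                        st.rng_sched.lognormal(0.0, beh.css_interval_jitter / 10.0)
                    )
                elif rate > 0:
                    st.next_bout_t = t + st.rng_sched.exponential(1.0 / rate)

            if (
                rate > 0
                and not st.css_active
                and st.css_pending_t is None
                and beh.trigger_radius_mm > 0
                and rho <= beh.trigger_radius_mm
            ):
                lo, hi = beh.reaction_delay_s
                st.css_pending_t = t + float(st.rng_sched.uniform(lo, hi))

            if st.bout is None and not st.frozen:
                start_css = st.css_pending_t is not None and t >= st.css_pending_t
                if st.css_active:
                    lo, hi = beh.css_interval_bounds_s
                    since = t - st.last_bout_end
                    start_css = since >= lo and (rho <= st.rho_trigger or since >= hi)
                if start_css:
                    # counterflow bout: aim at the outward radial direction
                    alpha_t = float(st.rng_kin.normal(0.0, beh.align_sigma_rad))
                    tgt = _wrap(radial + alpha_t)
                    st.bout = _draw_bout(st, t, float(tgt), beh)
                    st.bout["rho_start"] = rho
                    st.bout["css_onset"] = not st.css_active
                    if not st.css_active:
                        st.hold_rho = rho  # CSS operating point
                        st.rho_trigger = rho
                    st.css_active = True
                    st.css_pending_t = None
                    st.bouts.append(st.bout)
                elif st.css_pending_t is None and not st.css_active and t >= st.next_bout_t:
                    tgt = float(st.rng_kin.uniform(-math.pi, math.pi))
                    st.bout = _draw_bout(st, t, tgt, beh)
                    st.bout["rho_start"] = rho
                    st.bout["css_onset"] = False
                    st.bouts.append(st.bout)

            # ---- instantaneous pose ---------------------------------------
            if st.bout is not None:
                b = st.bout
                tb = t - b["t0"]
                frac = min(1.0, tb / b["tau_b"])
                dh = _wrap(b["h_to"] - b["h_from"])
                heading_now = _wrap(b["h_from"] + frac * dh)
                kappa_now = b["sign"] * b["amp"] * math.sin(
                    2 * math.pi * tb / b["tau_b"]
                )
            else:
                heading_now = st.heading
                kappa_now = 0.0
            st.heading = float(heading_now)

            phase = "css" if (st.css_active) else "exploration"
            rec_frame.append(fi)
            rec_t.append(t)
            rec_id.append(li)
            rec_x.append(st.pos[0])
            rec_y.append(st.pos[1])
            rec_h.append(st.heading)
            rec_k.append(kappa_now)
            rec_phase.append(phase)

            # ---- integrate to the next frame ------------------------------
            if st.frozen:
                continue
            vel = flow_velocity(st.pos, config)
            if st.bout is not None:
                b = st.bout
                sp = b["u"] * math.exp(-(t - b["t0"]) / b["lam"])
                vel = vel + sp * np.array(
                    [math.cos(st.heading), math.sin(st.heading)]
                )
            st.pos = st.pos + vel * dt
            new_rho = float(np.hypot(*(st.pos - sink)))
            if new_rho <= larva.L / 2:
                st.frozen = True  # sucked onto the needle
            elif (
                st.bout is None
                and beh.passive_reorientation
                and config.q > 0
            ):
                rel2 = st.pos - sink
                rad2 = math.atan2(rel2[1], rel2[0])
                alpha = _wrap(st.heading - rad2)
                dalpha = (
                    beh.reorientation_sign
                    * config.q
                    * larva.L
                    / new_rho**beh.reorientation_rho_exponent
                    * math.sin(alpha)
                )
                st.heading = float(_wrap(st.heading + dalpha * dt))

    poses = pd.DataFrame(
        {
            "frame": np.asarray(rec_frame, dtype=int),
            "t": rec_t,
            "larva_id": np.asarray(rec_id, dtype=int),
            "x_mm": rec_x,
            "y_mm": rec_y,
            "heading_rad": rec_h,
            "kappa_per_mm": rec_k,
            "phase": rec_phase,
        }
    )
    rows = []
    for li, st in enumerate(states):
        for k, b in enumerate(st.bouts):
            rows.append(
                {
                    "larva_id": li,
                    "k": k,
                    "t_k_s": b["t0"],
                    "rho_k_mm": b["rho_start"],
                    "u_mm_s": b["u"],
                    "lambda_s": b["lam"],
                    "n": b["n"],
                    "tau_b_s": b["tau_b"],
                    "mean_abs_kappa_per_mm": b["mean_abs_kappa"],
                    "target_heading_rad": b["h_to"],
                    "phase": "css" if b.get("css_onset") or _css_by_index(st, k) else "exploration",
                    "css_onset": bool(b.get("css_onset", False)),
                }
            )
    bouts = pd.DataFrame(
        rows,
        columns=[
            "larva_id", "k", "t_k_s", "rho_k_mm", "u_mm_s", "lambda_s", "n",
            "tau_b_s", "mean_abs_kappa_per_mm", "target_heading_rad", "phase",
            "css_onset",
        ],
    )
    return GroundTruth(poses, bouts, config, larva, beh, seed, n_frames=n_frames)


def _css_by_index(st: _LarvaState, k: int) -> bool:
    onset = next((i for i, b in enumerate(st.bouts) if b.get("css_onset")), None)
    return onset is not None and k >= onset


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_pose(
    canvas: np.ndarray,
    pose_xy: np.ndarray,
    heading: float,
    kappa: float,
    larva: LarvaModel,
    config: FlowConfig,
) -> None:
    """Paint one larva into ``canvas`` (float intensities, in place).

    The body is a flat-top stamp of the larva's width profile along a
    circular arc, with a one-pixel antialiased edge.  Raises if the arc
    closes on itself (|kappa| * L >= pi).
    """
    px = config.pixel_size
    s_ref = _head_axis_arclength(larva)
    L = larva.L
    # bounding box in pixels
    pts_all, w_all, p_ref = centerline(pose_xy, heading, kappa, larva, n=65)
    lo = config.mm_to_px(pts_all.min(axis=0) - w_all.max() - 2 * px)
    hi = config.mm_to_px(pts_all.max(axis=0) + w_all.max() + 2 * px)
    rows, cols = canvas.shape
    c0, r0 = int(max(0, math.floor(lo[0]))), int(max(0, math.floor(lo[1])))
    c1, r1 = int(min(cols, math.ceil(hi[0]) + 1)), int(min(rows, math.ceil(hi[1]) + 1))
    if c1 <= c0 or r1 <= r0:
        return
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    # pixel centers in mm
    pmm = config.px_to_mm(np.stack([cc + 0.5, rr + 0.5], axis=-1))

    # arc frame: recover the arclength of the nearest centerline point
    anchor = p_ref
    if abs(kappa) > 1e-9:
        C = anchor + np.array([math.sin(heading), -math.cos(heading)]) / kappa
        v = pmm - C
        r = np.hypot(v[..., 0], v[..., 1])
        psi = np.arctan2(v[..., 1], v[..., 0])
        phi_p = psi - math.copysign(math.pi / 2.0, kappa)
        s_p = s_ref - _wrap(phi_p - heading) / kappa
        d_line = np.abs(r - 1.0 / abs(kappa))
    else:
        dvec = np.array([math.cos(heading), math.sin(heading)])
        nvec = np.array([-math.sin(heading), math.cos(heading)])
        rel_a = pmm - anchor
        s_p = s_ref + rel_a @ dvec
        d_line = np.abs(rel_a @ nvec)

    s_cl = np.clip(s_p, 0.0, L)
    inside = (s_p >= 0.0) & (s_p <= L)
    w_at = larva.widths(s_cl / L)
    # distance to the nearest end cap for points beyond the ends
    tail_pt, head_pt = pts_all[0], pts_all[-1]
    d_tail = np.hypot(pmm[..., 0] - tail_pt[0], pmm[..., 1] - tail_pt[1])
    d_head = np.hypot(pmm[..., 0] - head_pt[0], pmm[..., 1] - head_pt[1])
    d_cap = np.where(s_p < 0.0, d_tail, d_head)
    d = np.where(inside, d_line, d_cap)

    stamp = (np.clip((w_at - d) / px + 0.5, 0.0, 1.0) * larva.intensity).astype(
        canvas.dtype
    )
    region = canvas[r0:r1, c0:c1]
    np.maximum(region, stamp, out=region)


_NOISE_PAD = 256


def _finalize_frame(canvas, noise, rng, bank=None):
    canvas += noise.background_level
    if rng is not None and noise.intensity_sigma > 0:
        if bank is None:
            canvas += noise.intensity_sigma * rng.standard_normal(
                canvas.shape, dtype=np.float32
            )
        else:
            r, c = canvas.shape
            dy, dx = rng.integers(0, _NOISE_PAD, size=2)
            canvas += noise.intensity_sigma * bank[dy : dy + r, dx : dx + c]
    canvas += 0.5  # round-half-up via truncation
    np.clip(canvas, 0, 65535, out=canvas)
    return canvas.astype(np.uint16)


def render_frame(
    truth: GroundTruth,
    frame_index: int,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a single frame of a session (uint16, bright on dark)."""
    noise = noise or NoiseParams()
    cfg = truth.config
    canvas = np.zeros(cfg.shape, dtype=np.float32)
    sub = truth.poses[truth.poses["frame"] == frame_index]
    for xy, hh, kk in zip(
        sub[["x_mm", "y_mm"]].to_numpy(),
        sub["heading_rad"].to_numpy(),
        sub["kappa_per_mm"].to_numpy(),
    ):
        render_pose(canvas, xy, float(hh), float(kk), truth.larva, cfg)
    return _finalize_frame(canvas, noise, rng)


def iter_frames(
    truth: GroundTruth,
    noise: NoiseParams | None = None,
    seed: int | None = 0,
) -> Iterator[np.ndarray]:
    """Stream rendered frames (memory-light alternative to render_frames)."""
    noise = noise or NoiseParams()
    rng = None if seed is None else np.random.default_rng(
        np.random.SeedSequence([int(seed), 0x0A015E])
    )
    cfg = truth.config
    xy = truth.poses[["x_mm", "y_mm"]].to_numpy()
    hh = truth.poses["heading_rad"].to_numpy()
    kk = truth.poses["kappa_per_mm"].to_numpy()
    indices = truth.poses.groupby("frame").indices
    bank = None
    if rng is not None and noise.intensity_sigma > 0:
        # unit-variance Gaussian bank; frames take random crops (cheap per
        # frame, per-pixel marginals identical to fresh draws)
        r, c = cfg.shape
        bank = rng.standard_normal((r + _NOISE_PAD, c + _NOISE_PAD), dtype=np.float32)
    for fi in range(truth.n_frames):
        canvas = np.zeros(cfg.shape, dtype=np.float32)
        for i in indices.get(fi, ()):  # frames may be empty
            render_pose(canvas, xy[i], float(hh[i]), float(kk[i]), truth.larva, cfg)
        yield _finalize_frame(canvas, noise, rng, bank)


def render_frames(
    truth: GroundTruth,
    noise: NoiseParams | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Render the whole session as a (n_frames, rows, cols) uint16 stack."""
    return np.stack(list(iter_frames(truth, noise, seed)))


def mean_background(truth: GroundTruth, noise: NoiseParams | None = None) -> np.ndarray:
    """The session's expected run-average image (background + larva ghosts).

    Equals the pixel-wise mean of the rendered frames up to the O(sigma/
    sqrt(n_frames)) residual of the zero-mean noise; a single noiseless
    accumulation pass instead of a second rendering pass.
    """
    noise = noise or NoiseParams()
    cfg = truth.config
    acc = np.zeros(cfg.shape, dtype=np.float64)
    xy = truth.poses[["x_mm", "y_mm"]].to_numpy()
    hh = truth.poses["heading_rad"].to_numpy()
    kk = truth.poses["kappa_per_mm"].to_numpy()
    indices = truth.poses.groupby("frame").indices
    canvas = np.zeros(cfg.shape, dtype=np.float32)
    for fi in range(truth.n_frames):
        canvas[:] = 0.0
        for i in indices.get(fi, ()):
            render_pose(canvas, xy[i], float(hh[i]), float(kk[i]), truth.larva, cfg)
        acc += canvas
    return acc / max(truth.n_frames, 1) + noise.background_level


def write_session(
    truth: GroundTruth,
    out_dir: str | Path,
    noise: NoiseParams | None = None,
    seed: int | None = 0,
    write_video: bool = True,
) -> Path:
    """Write frames.tif (multi-page 16-bit), timestamps.csv, poses.csv, bouts.csv."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if write_video:
        with tifffile.TiffWriter(out / "frames.tif", bigtiff=True) as tw:
            for frame in iter_frames(truth, noise, seed):
                tw.write(frame, contiguous=False)
    dt = 1.0 / truth.config.frame_rate
    pd.DataFrame(
        {"frame": np.arange(truth.n_frames), "t_seconds": np.arange(truth.n_frames) * dt}
    ).to_csv(out / "timestamps.csv", index=False)
    truth.poses.to_csv(out / "poses.csv", index=False)
    truth.bouts.to_csv(out / "bouts.csv", index=False)
    return out
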