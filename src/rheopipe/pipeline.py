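"""Pipeline orchestration: simulate -> segment -> posture -> track -> bouts
-> stats with one flat configuration, CSV outputs and a run manifest.

Each stage writes its table(s) into the run directory and appends a manifest
record (stage, config hash, seed, output file, content hash), so a rerun
with the same configuration and seed is bit-identical for every
deterministic stage.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import bouts as bt
from . import segmentation as seg
from . import stats as st
from . import synthdata as sd
from . import tracking as trk
from .config import PipelineConfig, config_hash
from .posture import PoseSample, pose_from_blob

__all__ = [
    "run",
    "analyze_frames",
    "tracks_from_poses",
    "poses_table",
    "bouts_table",
    "DEFAULT_BANDWIDTHS",
]

STAGES = ("simulate", "segment", "posture", "track", "bouts", "stats")

# Gaussian KDE bandwidths for the six bout/inter-bout quantities
# (tail-beat count, beat period in ms, |curvature| in 1/mm, impulse speed in
# mm/s, inter-bout period in s, inter-bout distance in mm).
DEFAULT_BANDWIDTHS = {
    "n": 0.75,
    "tau_b_ms": 1.0,
    "abs_kappa": 0.01,
    "u": 2.0,
    "tau": 0.075,
    "delta": 0.25,
}


# ---------------------------------------------------------------------------
# In-memory stage functions
# ---------------------------------------------------------------------------

def session_background(truth, cfg: PipelineConfig) -> np.ndarray:
    """Run background per the configured estimator, from rendered frames."""
    sp = cfg.segmentation
    if sp.background_method == "percentile":
        n = truth.n_frames
        idx = set(np.unique(np.linspace(0, n - 1, min(96, n)).astype(int)).tolist())
        sub = [f for fi, f in enumerate(sd.iter_frames(truth, cfg.noise, seed=cfg.seed)) if fi in idx]
        return seg.percentile_background(sub, sp.background_percentile)
    return sd.mean_background(truth, cfg.noise)


def analyze_frames(
    frames: Iterable[np.ndarray],
    cfg: PipelineConfig,
    background: np.ndarray | None = None,
) -> list[list[PoseSample]]:
    """Segment every frame and compute poses (two passes when the background
    must be built from the stream itself)."""
    if background is None:
        frames = list(frames)
        background = seg.build_background(frames)
    flow = cfg.flow
    dt = 1.0 / flow.frame_rate
    out: list[list[PoseSample]] = []
    for fi, frame in enumerate(frames):
        blobs = seg.segment_frame(frame, background, cfg.segmentation, flow.pixel_size)
        poses = []
        for b in blobs:
            try:
                poses.append(pose_from_blob(b, flow, t=fi * dt, frame=fi))
            except ValueError:
                continue  # degenerate blob; drop the detection
        out.append(poses)
    return out


def tracks_from_poses(per_frame: list[list[PoseSample]], cfg: PipelineConfig) -> list[trk.Track]:
    tracks = trk.link(per_frame, max_disp=cfg.max_disp_mm, memory=cfg.memory_frames)
    return trk.filter_tracks(tracks, cfg.min_duration_s, cfg.contact_exclusion_mm)


def series_from_tracks(tracks: list[trk.Track], cfg: PipelineConfig) -> list[bt.BoutSeries]:
    out = []
    for tr in tracks:
        t = tr.times
        rho = np.array([p.rho for p in tr.poses])
        alpha = np.array([p.alpha for p in tr.poses])
        kappa = np.array([p.kappa for p in tr.poses])
        if t.size < int(0.4 * cfg.flow.frame_rate) + 2:
            continue
        out.append(
            bt.extract_bouts(
                t,
                rho,
                alpha,
                kappa,
                cfg.flow.frame_rate,
                activity_threshold=cfg.activity_threshold,
                min_bout_duration=cfg.min_bout_duration_s,
                beat_threshold=cfg.beat_threshold,
                larva_id=tr.larva_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def poses_table(per_frame: list[list[PoseSample]]) -> pd.DataFrame:
    rows = []
    for poses in per_frame:
        for p in poses:
            rows.append(
                {
                    "frame": p.frame,
                    "larva_id": p.larva_id,
                    "t_s": p.t,
                    "x_mm": p.x_mm,
                    "y_mm": p.y_mm,
                    "rho_mm": p.rho,
                    "theta_rad": p.theta,
                    "alpha_rad": p.alpha,
                    "kappa_per_mm": p.kappa,
                    "flags": ";".join(p.flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "larva_id", "t_s", "x_mm", "y_mm", "rho_mm", "theta_rad",
            "alpha_rad", "kappa_per_mm", "flags",
        ],
    )


def tracks_table(tracks: list[trk.Track]) -> pd.DataFrame:
    per_frame: dict[int, list[PoseSample]] = {}
    for tr in tracks:
        for p in tr.poses:
            per_frame.setdefault(p.frame, []).append(p)
    frames = [per_frame.get(i, []) for i in range(max(per_frame, default=-1) + 1)]
    return poses_table(frames)


def bouts_table(series_list: list[bt.BoutSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for b in s.bouts:
            rows.append(
                {
                    "larva_id": s.larva_id,
                    "k": b.k,
                    "t_k_s": b.t_k,
                    "rho_k_mm": b.rho_k,
                    "alpha_onset_rad": b.alpha_onset,
                    "alpha_offset_rad": b.alpha_offset,
                    "v_f_mm_s": b.v_f,
                    "u_mm_s": b.u,
                    "lambda_s": b.lam,
                    "n": b.n,
                    "tau_b_s": b.tau_b,
                    "mean_abs_kappa_per_mm": b.mean_abs_kappa,
                    "fit_rms_mm": b.fit_rms,
                    "flags": ";".join(b.flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "larva_id", "k", "t_k_s", "rho_k_mm", "alpha_onset_rad",
            "alpha_offset_rad", "v_f_mm_s", "u_mm_s", "lambda_s", "n",
            "tau_b_s", "mean_abs_kappa_per_mm", "fit_rms_mm", "flags",
        ],
    )


def series_table(series_list: list[bt.BoutSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        tau, delta = s.tau, s.delta
        for k in range(tau.size):
            rows.append(
                {"larva_id": s.larva_id, "k": k, "tau_s": tau[k], "delta_mm": delta[k]}
            )
    return pd.DataFrame(rows, columns=["larva_id", "k", "tau_s", "delta_mm"])


def tracks_from_table(df: pd.DataFrame) -> list[trk.Track]:
    """Rebuild Track objects (positions/angles only) from a tracks.csv table."""
    tracks = []
    for lid, sub in df.groupby("larva_id"):
        sub = sub.sort_values("frame")
        poses = [
            PoseSample(
                t=float(r.t_s),
                x_mm=float(r.x_mm),
                y_mm=float(r.y_mm),
                rho=float(r.rho_mm),
                theta=float(r.theta_rad),
                alpha=float(r.alpha_rad),
                kappa=float(r.kappa_per_mm),
                frame=int(r.frame),
                larva_id=int(lid),
            )
            for r in sub.itertuples()
        ]
        tracks.append(trk.Track(int(lid), poses))
    return tracks


# ---------------------------------------------------------------------------
# Run directory orchestration
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path, manifest: list, stage: str, cfg_hash: str, seed: int):
    df.to_csv(path, index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    manifest.append(
        {"stage": stage, "file": path.name, "sha256": digest, "config": cfg_hash, "seed": seed}
    )


def run(
    cfg: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    write_video: bool = False,
) -> Path:
    """Run the requested stages in order, writing tables and a manifest.

    The synthetic stage feeds later stages in memory (frames are re-rendered
    deterministically rather than stored, unless ``write_video`` is set).
    Raises if a requested stage's input stage was neither requested nor
    previously written to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(s for s in STAGES if s in stages)
    if not stages:
        raise ValueError("no recognized stages requested")
    cfg_hash = config_hash(cfg)
    manifest: list[dict] = []

    truth = None
    per_frame = None
    tracks = None
    series_list = None

    if "simulate" in stages:
        truth = sd.simulate_session(
            cfg.flow,
            cfg.larva,
            cfg.behavior,
            n_larvae=cfg.n_larvae,
            duration=cfg.duration_s,
            seed=cfg.seed,
        )
        sd.write_session(truth, out, cfg.noise, seed=cfg.seed, write_video=write_video)
        for name in ("poses.csv", "bouts.csv"):
            p = out / name
            digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            manifest.append(
                {"stage": "simulate", "file": name, "sha256": digest, "config": cfg_hash, "seed": cfg.seed}
            )

    if "segment" in stages or "posture" in stages:
        if truth is None:
            raise RuntimeError("segment/posture stages need the simulate stage (or external frames)")
        bg = session_background(truth, cfg)
        per_frame = analyze_frames(sd.iter_frames(truth, cfg.noise, seed=cfg.seed), cfg, background=bg)
        if "segment" in stages:
            rows = []
            for fi, poses in enumerate(per_frame):
                for bi, p in enumerate(poses):
                    rows.append(
                        {"frame": fi, "blob_id": bi, "area_px": p.blob_area,
                         "cx_mm": p.x_mm, "cy_mm": p.y_mm}
                    )
            _write(pd.DataFrame(rows, columns=["frame", "blob_id", "area_px", "cx_mm", "cy_mm"]),
                   out / "blobs.csv", manifest, "segment", cfg_hash, cfg.seed)
        if "posture" in stages:
            _write(poses_table(per_frame), out / "measured_poses.csv", manifest, "posture", cfg_hash, cfg.seed)

    if "track" in stages:
        if per_frame is None:
            mp = out / "measured_poses.csv"
            if not mp.exists():
                raise RuntimeError("track stage needs the posture stage output (measured_poses.csv)")
            df = pd.read_csv(mp, keep_default_na=False)
            nf = int(df["frame"].max()) + 1 if len(df) else 0
            per_frame = [[] for _ in range(nf)]
            for r in df.itertuples():
                per_frame[int(r.frame)].append(
                    PoseSample(
                        t=float(r.t_s), x_mm=float(r.x_mm), y_mm=float(r.y_mm),
                        rho=float(r.rho_mm), theta=float(r.theta_rad),
                        alpha=float(r.alpha_rad), kappa=float(r.kappa_per_mm),
                        frame=int(r.frame),
                    )
                )
        tracks = tracks_from_poses(per_frame, cfg)
        _write(tracks_table(tracks), out / "tracks.csv", manifest, "track", cfg_hash, cfg.seed)

    if "bouts" in stages:
        if tracks is None:
            tp = out / "tracks.csv"
            if not tp.exists():
                raise RuntimeError("bouts stage needs the track stage output (tracks.csv)")
            tracks = tracks_from_table(pd.read_csv(tp, keep_default_na=False))
        series_list = series_from_tracks(tracks, cfg)
        _write(bouts_table(series_list), out / "measured_bouts.csv", manifest, "bouts", cfg_hash, cfg.seed)
        _write(series_table(series_list), out / "series.csv", manifest, "bouts", cfg_hash, cfg.seed)

    if "stats" in stages:
        if series_list is None or tracks is None:
            raise RuntimeError("stats stage needs tracks and bouts in the same run")
        labels = [st.label_css(s, cfg.css_run_length, cfg.css_alpha_max_rad) for s in series_list]
        stats_rows = []
        try:
            centers, var_c, counts = st.aligned_circvar(tracks, series_list, labels)
            for c, v, n in zip(centers, var_c, counts):
                stats_rows.append({"t_from_onset_s": c, "circvar": v, "n": n})
        except ValueError:
            pass
        _write(pd.DataFrame(stats_rows, columns=["t_from_onset_s", "circvar", "n"]),
               out / "aligned_circvar.csv", manifest, "stats", cfg_hash, cfg.seed)
        groups = [0 for _ in series_list]  # single condition per run
        per_group, ks_stat, ks_p = st.onset_summary(
            series_list, labels, groups, cfg.flow,
            rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11])),
        )
        rows = [
            {"group": g, **vals, "ks_stat_vs_uniform": ks_stat, "ks_p_vs_uniform": ks_p}
            for g, vals in per_group.items()
        ]
        _write(pd.DataFrame(rows), out / "onset_summary.csv", manifest, "stats", cfg_hash, cfg.seed)

    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
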