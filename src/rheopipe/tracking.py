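"""Frame-to-frame linking of poses into identity-preserving tracks.

Crocker–Grier-style linking: per frame pair the assignment between open
tracks and new detections minimizes the total squared displacement, subject
to a hard gate ``max_disp`` on each displacement (3.5 mm between consecutive
images by default).  A track that misses detections stays claimable for up
to ``memory`` frames (100 time steps, 400 ms at 250 Hz) before it is closed;
unclaimed detections seed new tracks.  The assignment is solved exactly
(Hungarian algorithm), not greedily.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .posture import PoseSample

__all__ = ["Track", "link", "filter_tracks"]


@dataclass
class Track:
    """Time-ordered poses of one larva; gaps are left absent, not interpolated."""

    larva_id: int
    poses: list[PoseSample] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.poses], dtype=int)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.poses])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[p.x_mm, p.y_mm] for p in self.poses])

    @property
    def duration(self) -> float:
        return float(self.poses[-1].t - self.poses[0].t) if len(self.poses) > 1 else 0.0

    def gap_lengths(self) -> np.ndarray:
        f = self.frames
        return np.diff(f) - 1 if f.size > 1 else np.array([], dtype=int)


def link(
    frames: list[list[PoseSample]],
    max_disp: float = 3.5,
    memory: int = 100,
) -> list[Track]:
    """Link per-frame pose lists into tracks.

    ``frames[i]`` holds the poses detected in frame ``i`` (empty lists are
    fine).  Assignment costs are squared displacements from each open
    track's last seen position; displacements above ``max_disp`` (mm) are
    forbidden.  Dormant tracks may reclaim a detection for up to ``memory``
    missed frames.  Track ids are assigned in order of creation; ties in
    cost resolve toward the smallest id (stable Hungarian solution).
    """
    open_tracks: list[Track] = []
    last_pos: list[np.ndarray] = []
    last_frame: list[int] = []
    done: list[Track] = []
    next_id = 0
    big = 1e12

    for fi, dets in enumerate(frames):
        # retire tracks beyond memory
        keep = []
        for i, tr in enumerate(open_tracks):
            if fi - last_frame[i] - 1 > memory:
                done.append(tr)
            else:
                keep.append(i)
        open_tracks = [open_tracks[i] for i in keep]
        last_pos = [last_pos[i] for i in keep]
        last_frame = [last_frame[i] for i in keep]

        # sort detections deterministically (by position) so the track set
        # does not depend on detection order within a frame
        dets = sorted(dets, key=lambda p: (p.x_mm, p.y_mm))
        if not dets:
            continue
        det_pos = np.array([[p.x_mm, p.y_mm] for p in dets])
        assigned = np.full(len(dets), -1, dtype=int)
        if open_tracks:
            tp = np.array(last_pos)
            d2 = ((tp[:, None, :] - det_pos[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_disp**2, d2, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    assigned[c] = r
        for ci, det in enumerate(dets):
            ti = assigned[ci]
            if ti >= 0:
                tr = open_tracks[ti]
                det.larva_id = tr.larva_id
                tr.poses.append(det)
                last_pos[ti] = det_pos[ci]
                last_frame[ti] = fi
            else:
                tr = Track(larva_id=next_id, poses=[det])
                det.larva_id = next_id
                next_id += 1
                open_tracks.append(tr)
                last_pos.append(det_pos[ci])
                last_frame.append(fi)

    done.extend(open_tracks)
    done.sort(key=lambda t: t.larva_id)
    return done


def filter_tracks(
    tracks: list[Track],
    min_duration: float = 0.0,
    contact_exclusion: float = 0.0,
) -> list[Track]:
    """Automatic curation replacing manual trajectory triage.

    Tracks shorter than ``min_duration`` seconds are dropped; when two
    tracks' poses come nearer than ``contact_exclusion`` mm in the same
    frame, both are truncated at the approach frame (merged or touching
    larvae cannot be attributed reliably).
    """
    if contact_exclusion > 0 and len(tracks) > 1:
        cut: dict[int, int] = {}
        by_frame: dict[int, list[tuple[int, np.ndarray]]] = {}
        for idx, tr in enumerate(tracks):
            for p in tr.poses:
                by_frame.setdefault(p.frame, []).append((idx, np.array([p.x_mm, p.y_mm])))
        for f, items in by_frame.items():
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    ia, pa = items[i]
                    ib, pb = items[j]
                    if ia != ib and np.linalg.norm(pa - pb) < contact_exclusion:
                        cut[ia] = min(cut.get(ia, f), f)
                        cut[ib] = min(cut.get(ib, f), f)
        trimmed = []
        for idx, tr in enumerate(tracks):
            if idx in cut:
                poses = [p for p in tr.poses if p.frame < cut[idx]]
                trimmed.append(Track(tr.larva_id, poses))
            else:
                trimmed.append(tr)
        tracks = trimmed
    out = []
    for tr in tracks:
        if len(tr.poses) >= 2 and tr.duration >= min_duration:
            out.append(tr)
        elif min_duration <= 0 and tr.poses:
            out.append(tr)
    return out
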