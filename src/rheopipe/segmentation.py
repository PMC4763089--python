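"""Larva detection: background subtraction, smoothing, thresholding, size filter.

Each frame is compared against the run's average image; the difference is
smoothed with a small Gaussian (box and sigma given in micrometres and
converted through the pixel size), thresholded (Otsu by default) and split
into 4-connected components.  Components smaller than ``min_area`` pixels
(default 500, roughly half a larva at the nominal 35 um/pixel scale) are
discarded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .config import SegmentationParams

__all__ = ["Blob", "build_background", "segment_frame", "smooth_difference"]


@dataclass
class Blob:
    """One connected component: pixel coordinates, intensities, geometry.

    ``pixels`` is an (n, 2) integer array of (row, col) indices; ``values``
    the smoothed difference-image intensities at those pixels.  ``centroid``
    is the intensity-weighted centroid in (col, row) pixel units (pixel
    centers, i.e. +0.5 offsets applied) — convert to mm with the frame's
    pixel size.  ``touches_border`` flags components clipped by the frame
    edge.
    """

    pixels: np.ndarray
    values: np.ndarray
    touches_border: bool = False

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def centroid(self) -> np.ndarray:
        w = self.values
        rc = (self.pixels * w[:, None]).sum(axis=0) / w.sum()
        return np.array([rc[1] + 0.5, rc[0] + 0.5])  # (col, row) pixel centers

    def centroid_mm(self, pixel_size: float, origin=(0.0, 0.0)) -> np.ndarray:
        return self.centroid * pixel_size + np.asarray(origin, dtype=float)


def build_background(frames) -> np.ndarray:
    """Pixel-wise mean over a sequence of frames (the run's average image)."""
    it = iter(frames)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("cannot build a background from an empty sequence")
    acc = np.asarray(first, dtype=np.float64).copy()
    n = 1
    for f in it:
        f = np.asarray(f, dtype=np.float64)
        if f.shape != acc.shape:
            raise ValueError("frames must all have the same shape")
        acc += f
        n += 1
    if n < 2:
        raise ValueError("need at least 2 frames to build a background")
    return acc / n


def percentile_background(frames, q: float = 10.0, max_frames: int = 96) -> np.ndarray:
    """Pixel-wise low percentile over (a subsample of) the frames.

    For bright larvae on a dark background a low percentile recovers the
    empty arena even under pixels occupied most of the run, where the mean
    (and even the median) retain larva ghosts.  The additive-noise offset it
    introduces is uniform and absorbed by the detection threshold.
    """
    frames = list(frames) if not isinstance(frames, (list, np.ndarray)) else frames
    n = len(frames)
    if n == 0:
        raise ValueError("cannot build a background from an empty sequence")
    idx = np.unique(np.linspace(0, n - 1, min(max_frames, n)).astype(int))
    stack = np.stack([np.asarray(frames[i], dtype=np.float32) for i in idx])
    return np.quantile(stack, q / 100.0, axis=0).astype(np.float32)


def _blur_radius_px(params: SegmentationParams, pixel_size_mm: float) -> tuple[int, float]:
    """Gaussian box half-width (px, box rounded up to odd) and sigma (px)."""
    box_px = params.blur_box_um / 1000.0 / pixel_size_mm
    box_odd = int(math.ceil(box_px))
    if box_odd % 2 == 0:
        box_odd += 1
    sigma_px = params.blur_sigma_um / 1000.0 / pixel_size_mm
    return (box_odd - 1) // 2, sigma_px


def smooth_difference(
    frame: np.ndarray,
    background: np.ndarray,
    params: SegmentationParams,
    pixel_size_mm: float,
) -> np.ndarray:
    """Background-subtracted, Gaussian-smoothed intensity image."""
    frame = np.asarray(frame, dtype=np.float32)
    background = np.asarray(background, dtype=np.float32)
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    diff = frame - background
    radius, sigma = _blur_radius_px(params, pixel_size_mm)
    return ndi.gaussian_filter(diff, sigma=sigma, radius=radius, mode="nearest")


def segment_frame(
    frame: np.ndarray,
    background: np.ndarray,
    params: SegmentationParams,
    pixel_size_mm: float,
) -> list[Blob]:
    """Detect larva blobs in one frame; sorted by area, largest first."""
    sm = smooth_difference(frame, background, params, pixel_size_mm)
    if params.threshold == "auto":
        sample = sm[::3, ::3]  # Otsu is insensitive to this decimation
        sample = sample[np.isfinite(sample)]
        if sample.size == 0 or np.ptp(sample) < 1e-9:
            return []
        thr = float(threshold_otsu(sample))
        if thr <= 0:
            return []
    else:
        thr = float(params.threshold)
    mask = sm > thr
    if not mask.any():
        return []
    # An automatic threshold on a larva-free frame falls inside the noise and
    # selects a large fraction of the image; no plausible set of larvae does.
    if params.threshold == "auto" and mask.mean() > 0.05:
        return []
    lab = cc_label(mask, connectivity=1)
    blobs: list[Blob] = []
    rows, cols = mask.shape
    objects = ndi.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = lab[sl] == i
        area = int(sub.sum())
        if area < params.min_area:
            continue
        rr, cc = np.nonzero(sub)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        touches = bool(
            rr.min() == 0 or cc.min() == 0 or rr.max() == rows - 1 or cc.max() == cols - 1
        )
        blobs.append(
            Blob(
                pixels=np.stack([rr, cc], axis=1),
                values=np.clip(sm[rr, cc], 1e-9, None),
                touches_border=touches,
            )
        )
    blobs.sort(key=lambda b: -b.area)
    return blobs
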