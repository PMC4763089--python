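"""Population-level statistics of rheotaxic behavior.

Circular variance of body angles, automated counterflow-swim-sequence (CSS)
labeling, onset-aligned circular-variance curves, fixed-bandwidth Gaussian
kernel density estimates, two-sample distribution tests (Kolmogorov-Smirnov,
Welch), radial position-holding profiles, CSS-onset summaries and the
egocentric density of the suction point.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .bouts import BoutSeries
from .config import FlowConfig
from .tracking import Track

__all__ = [
    "circular_variance",
    "CSSLabel",
    "label_css",
    "aligned_circvar",
    "DensityEstimate",
    "kde",
    "compare_distributions",
    "radial_profile",
    "onset_summary",
    "egocentric_density",
]


def circular_variance(angles) -> float:
    """1 - |mean resultant vector| of a set of angles (radians).

    0 when all angles coincide, 1 when the resultant cancels (e.g. equally
    spaced angles, or a uniform distribution at large N).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("circular variance of an empty angle set")
    return float(1.0 - np.abs(np.exp(1j * a).mean()))


@dataclass
class CSSLabel:
    """CSS onset of one bout series (``onset`` is a bout index or None)."""

    larva_id: int
    onset: int | None
    run_length: int
    alpha_max: float


def label_css(
    series: BoutSeries,
    run_length: int = 3,
    alpha_max: float = math.radians(45.0),
) -> CSSLabel:
    """Automatic CSS onset: the first bout opening a run of ``run_length``
    consecutive bouts that are aligned (|alpha_offset| <= alpha_max) and
    propel the larva away from the sink (u cos(alpha_onset) > 0)."""
    good = [
        abs(b.alpha_offset) <= alpha_max and b.u * math.cos(b.alpha_onset) > 0
        for b in series.bouts
    ]
    onset = None
    streak = 0
    for i, g in enumerate(good):
        streak = streak + 1 if g else 0
        if streak >= run_length:
            onset = i - run_length + 1
            break
    return CSSLabel(series.larva_id, onset, run_length, alpha_max)


def aligned_circvar(
    tracks: list[Track],
    series_list: list[BoutSeries],
    labels: list[CSSLabel],
    bin_s: float = 0.5,
    window_s: float = 10.0,
    n_min: int = 3,
    mode: str = "bout",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circular variance of alpha versus time from CSS onset.

    Pools angles from all labeled tracks into bins of ``bin_s`` seconds
    spanning +-``window_s`` around each track's onset time.  ``mode`` is
    'bout' (bout-onset angles, the printed definition) or 'frame'
    (per-frame angles, a frame-resolved variant of the same curve).
    Returns (bin_centers, var_c, counts); bins with fewer than ``n_min``
    samples are masked with NaN.
    """
    onsets = {}
    for s, lab in zip(series_list, labels):
        if lab.onset is not None and lab.onset < len(s.bouts):
            onsets[s.larva_id] = s.bouts[lab.onset].t_k
    if not onsets:
        raise ValueError("no labeled CSS onsets")
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    pooled: list[list[float]] = [[] for _ in centers]
    if mode == "bout":
        for s in series_list:
            if s.larva_id not in onsets:
                continue
            t0 = onsets[s.larva_id]
            for b in s.bouts:
                i = np.searchsorted(edges, b.t_k - t0, side="right") - 1
                if 0 <= i < centers.size:
                    pooled[i].append(b.alpha_onset)
    elif mode == "frame":
        for tr in tracks:
            if tr.larva_id not in onsets:
                continue
            t0 = onsets[tr.larva_id]
            for p in tr.poses:
                i = np.searchsorted(edges, p.t - t0, side="right") - 1
                if 0 <= i < centers.size:
                    pooled[i].append(p.alpha)
    else:
        raise ValueError("mode must be 'bout' or 'frame'")
    var_c = np.full(centers.size, np.nan)
    counts = np.array([len(p) for p in pooled])
    for i, p in enumerate(pooled):
        if len(p) >= n_min:
            var_c[i] = circular_variance(p)
    return centers, var_c, counts


@dataclass
class DensityEstimate:
    """Gaussian-kernel density on a regular grid (trapezoidal integral 1)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde(samples, bandwidth: float, grid: np.ndarray | None = None) -> DensityEstimate:
    """Fixed-bandwidth Gaussian kernel density estimate.

    The grid auto-extends 6 bandwidths beyond the sample range with a step
    fine enough for the trapezoidal integral to be 1 within 1e-6.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 1:
        raise ValueError("kde needs at least one sample")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if grid is None:
        lo = x.min() - 6.0 * bandwidth
        hi = x.max() + 6.0 * bandwidth
        n = int(min(2**16, max(4096, math.ceil((hi - lo) / (0.004 * bandwidth)))))
        grid = np.linspace(lo, hi, n)
    g = np.asarray(grid, dtype=float)
    # evaluate in chunks to bound memory at large n
    dens = np.zeros_like(g)
    step = max(1, int(2e7 / max(x.size, 1)))
    for i in range(0, g.size, step):
        d = (g[i : i + step, None] - x[None, :]) / bandwidth
        dens[i : i + step] = np.exp(-0.5 * d**2).sum(axis=1)
    dens /= x.size * bandwidth * math.sqrt(2 * math.pi)
    return DensityEstimate(grid=g, density=dens, bandwidth=float(bandwidth))


def compare_distributions(x, y, method: str = "ks") -> tuple[float, float, str]:
    """Two-sample test: 'ks' (Kolmogorov-Smirnov D, asymptotic p) or 'welch'
    (unequal-variance t).  Returns (statistic, p, stars) with stars '*' for
    p < 1e-3 and '**' for p < 1e-6."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    if method == "ks":
        res = sps.ks_2samp(x, y, method="asymp")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "ks_exact":
        res = sps.ks_2samp(x, y, method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "welch":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("Welch test undefined for two zero-variance samples")
        res = sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("method must be 'ks', 'ks_exact' or 'welch'")
    stars = "**" if p < 1e-6 else ("*" if p < 1e-3 else "")
    return stat, p, stars


def radial_profile(
    series_list: list[BoutSeries],
    rho_edges: np.ndarray,
    n_min: int = 3,
):
    """Mean inter-bout distance delta_k binned by bout radial position rho_k.

    Returns (bin_centers, mean_delta, sem_delta, counts, rho_histogram).
    delta_k is paired with the radius of bout k (where the inter-bout step
    starts); bins with fewer than ``n_min`` pairs, or a single pair (SE
    undefined), are masked with NaN.
    """
    rho_edges = np.asarray(rho_edges, dtype=float)
    rhos, deltas = [], []
    for s in series_list:
        r = np.array([b.rho_k for b in s.bouts])
        d = s.delta
        if d.size:
            rhos.append(r[:-1])
            deltas.append(d)
    if not rhos:
        raise ValueError("no inter-bout pairs")
    rho = np.concatenate(rhos)
    delta = np.concatenate(deltas)
    centers = (rho_edges[:-1] + rho_edges[1:]) / 2
    mean = np.full(centers.size, np.nan)
    sem = np.full(centers.size, np.nan)
    counts = np.zeros(centers.size, dtype=int)
    idx = np.digitize(rho, rho_edges) - 1
    for i in range(centers.size):
        sel = idx == i
        counts[i] = int(sel.sum())
        if counts[i] >= max(n_min, 2):
            mean[i] = float(delta[sel].mean())
            sem[i] = float(delta[sel].std(ddof=1) / math.sqrt(counts[i]))
    hist, _ = np.histogram(rho, rho_edges)
    return centers, mean, sem, counts, hist


def onset_summary(
    series_list: list[BoutSeries],
    labels: list[CSSLabel],
    groups,
    config: FlowConfig,
    n_null: int = 2000,
    rng: np.random.Generator | None = None,
):
    """Radial position rho_1 and fluid speed v_1 at the first CSS bout,
    averaged per group (e.g. per flow rate or per age).

    ``groups`` assigns a hashable group key to each series.  v_1 is the
    fitted pre-bout fluid speed of the onset bout.  Also runs a KS test of
    the pooled rho_1 sample against radii of uniformly random positions in
    the field of view (seeded through ``rng``).

    Returns (per_group, ks_stat, ks_p) where per_group maps
    group -> dict(mean_rho1, sem_rho1, mean_v1, sem_v1, n).
    """
    rng = rng or np.random.default_rng(0)
    rho1: dict[object, list[float]] = {}
    v1: dict[object, list[float]] = {}
    for s, lab, g in zip(series_list, labels, groups):
        if lab.onset is None or lab.onset >= len(s.bouts):
            continue
        b = s.bouts[lab.onset]
        rho1.setdefault(g, []).append(b.rho_k)
        v1.setdefault(g, []).append(b.v_f)
    per_group = {}
    for g in rho1:
        r = np.asarray(rho1[g])
        v = np.asarray(v1[g])
        per_group[g] = {
            "mean_rho1": float(r.mean()),
            "sem_rho1": float(r.std(ddof=1) / math.sqrt(r.size)) if r.size > 1 else float("nan"),
            "mean_v1": float(v.mean()),
            "sem_v1": float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan"),
            "n": int(r.size),
        }
    pooled = np.concatenate([np.asarray(v) for v in rho1.values()]) if rho1 else np.array([])
    if pooled.size >= 2:
        x0, y0, w, h = config.fov
        pts = rng.uniform([x0, y0], [x0 + w, y0 + h], size=(n_null, 2))
        null_rho = np.hypot(pts[:, 0] - config.sink[0], pts[:, 1] - config.sink[1])
        ks_stat, ks_p, _ = compare_distributions(pooled, null_rho, "ks")
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    return per_group, ks_stat, ks_p


def egocentric_density(
    poses,
    config: FlowConfig,
    extent_mm: float = 15.0,
    n_bins: int = 60,
):
    """2D probability density of the suction point in the larva's frame.

    Each pose puts the sink at polar coordinates (rho, pi - alpha) in the
    head-forward frame (+x ahead of the larva, +y to its left).  Returns
    (x_edges, y_edges, density) with the density normalized to integrate
    to 1 over the histogram support.
    """
    rho = np.asarray([p.rho for p in poses], dtype=float)
    alpha = np.asarray([p.alpha for p in poses], dtype=float)
    ang = math.pi - alpha
    x = rho * np.cos(ang)
    y = rho * np.sin(ang)
    edges = np.linspace(-extent_mm, extent_mm, n_bins + 1)
    hist, xe, ye = np.histogram2d(x, y, bins=(edges, edges))
    cell = (edges[1] - edges[0]) ** 2
    total = hist.sum()
    dens = hist / (total * cell) if total > 0 else hist
    return xe, ye, dens
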