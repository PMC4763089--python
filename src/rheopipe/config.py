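"""Configuration dataclasses shared across the pipeline.

All lengths are in millimetres, times in seconds, angles in radians unless a
field name says otherwise.  See docs/UNITS.md.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FlowConfig",
    "LarvaModel",
    "SegmentationParams",
    "BehaviorParams",
    "NoiseParams",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


@dataclass(frozen=True)
class FlowConfig:
    """Assay geometry and suction flow.

    The suction needle is modelled as a point sink in a shallow layer of
    depth ``h``: the depth-averaged flow is purely radial with speed
    ``q / rho`` where ``q = Q_v / (2 pi h)`` is the surfacic flow rate.

    Parameters
    ----------
    Q_v : float
        Volumetric suction rate, mm^3/s (0.22 mL/s == 220 mm^3/s).
    h : float
        Water depth over the platform, mm.
    sink : (float, float)
        Suction-point coordinates in the arena frame, mm.
    fov : (float, float, float, float)
        Field of view as (x0, y0, width, height), mm.
    frame_rate : float
        Acquisition rate, Hz.
    pixel_size : float
        Camera sampling, mm per pixel.
    """

    Q_v: float = 220.0
    h: float = 4.0
    sink: tuple[float, float] = (0.0, 0.0)
    fov: tuple[float, float, float, float] = (-11.0, -9.0, 22.0, 18.0)
    frame_rate: float = 250.0
    pixel_size: float = 0.035

    def __post_init__(self) -> None:
        if self.Q_v < 0:
            raise ValueError("Q_v must be >= 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        x0, y0, w, hh = self.fov
        sx, sy = self.sink
        if not (x0 <= sx <= x0 + w and y0 <= sy <= y0 + hh):
            raise ValueError("sink must lie inside or on the boundary of fov")

    @property
    def q(self) -> float:
        """Surfacic flow rate q = Q_v / (2 pi h), mm^2/s."""
        return self.Q_v / (2.0 * math.pi * self.h)

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (rows, cols) implied by fov and pixel_size."""
        _, _, w, hh = self.fov
        return (int(round(hh / self.pixel_size)), int(round(w / self.pixel_size)))

    def mm_to_px(self, xy: np.ndarray) -> np.ndarray:
        """Arena mm coordinates -> (col, row) pixel coordinates."""
        x0, y0, _, _ = self.fov
        xy = np.asarray(xy, dtype=float)
        return (xy - np.array([x0, y0])) / self.pixel_size

    def px_to_mm(self, colrow: np.ndarray) -> np.ndarray:
        x0, y0, _, _ = self.fov
        return np.asarray(colrow, dtype=float) * self.pixel_size + np.array([x0, y0])


def _default_width_profile() -> tuple[float, ...]:
    # Half-width (mm) sampled uniformly along the body from tail tip (s=0) to
    # head tip (s=L): a tapering tail and a wider, rounded head lobe.
    s = np.linspace(0.0, 1.0, 33)
    tail = 0.09 + 0.09 * s  # linear taper
    head = 0.23 * np.sqrt(np.clip(1.0 - ((s - 0.80) / 0.22) ** 2, 0.0, None))
    w = np.maximum(tail * (s < 0.62), head)
    w = np.maximum(w, 0.08)
    return tuple(np.round(w, 4))


@dataclass(frozen=True)
class LarvaModel:
    """Geometric/photometric model of one larva.

    ``width_profile`` holds the body half-width sampled uniformly in
    arclength from tail tip to head tip; the head lobe (the front
    ``head_fraction`` of the body) is wider than the tail, which is what lets
    the posture stage tell head from tail by mass.
    """

    L: float = 4.0
    head_fraction: float = 0.4
    width_profile: tuple[float, ...] = field(default_factory=_default_width_profile)
    intensity: float = 220.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if not 0 < self.head_fraction < 1:
            raise ValueError("head_fraction must be in (0, 1)")
        if np.any(np.asarray(self.width_profile) <= 0):
            raise ValueError("width_profile must be strictly positive")

    def widths(self, s: np.ndarray) -> np.ndarray:
        """Half-width at arclength fraction ``s`` in [0, 1] (tail -> head)."""
        prof = np.asarray(self.width_profile)
        grid = np.linspace(0.0, 1.0, prof.size)
        return np.interp(np.asarray(s, dtype=float), grid, prof)


@dataclass(frozen=True)
class SegmentationParams:
    """Detection parameters (background-subtracted, smoothed, thresholded).

    ``blur_box_um``/``blur_sigma_um`` are given in micrometres and converted
    to pixels through the frame's pixel size (box rounded up to an odd pixel
    count).  ``threshold='auto'`` uses Otsu's method on the smoothed
    difference image; a float fixes the threshold in intensity units.
    ``min_area`` drops connected components smaller than that many pixels
    (default 500, about half a larva at the nominal scale).
    """

    blur_box_um: float = 175.0
    blur_sigma_um: float = 50.0
    threshold: float | str = "auto"
    min_area: int = 500
    # run-background estimator used by the pipeline: "mean" is the run's
    # average image; "percentile" (default, bright-on-dark) is robust to
    # larvae that hover in place for most of a run
    background_method: str = "percentile"
    background_percentile: float = 10.0

    def __post_init__(self) -> None:
        if self.min_area <= 0:
            raise ValueError("min_area must be > 0")
        if self.blur_sigma_um <= 0:
            raise ValueError("blur sigma must be > 0")


@dataclass(frozen=True)
class BehaviorParams:
    """Programmed behavior of the synthetic larvae.

    Exploration: bouts at exponentially distributed intervals
    (``explore_interval_s`` mean) with uniformly random new headings.
    A counterflow swim sequence (CSS) starts at the first bout scheduled
    ``reaction_delay_s`` after the larva first drifts inside
    ``trigger_radius_mm``; CSS bouts aim at the outward radial direction
    (alpha = 0) with Gaussian scatter ``align_sigma_rad`` and their timing is
    chosen to hold radial position on average (the inter-bout advection
    cancels the previous bout's radial gain, times a lognormal jitter).

    Impulse parameters are drawn per bout: speed ``u`` (mm/s), damping time
    ``lam`` (s), ``n`` tail beats of period ``tau_b`` (s) and mean absolute
    curvature ``kappa`` (1/mm).  Between bouts larvae are advected by the
    sink flow and reoriented passively (stabilizing Jeffery-type torque,
    see rheopipe.passive).
    """

    explore_interval_s: float = 1.0
    trigger_radius_mm: float = 8.0
    reaction_delay_s: tuple[float, float] = (0.1, 0.3)
    align_sigma_rad: float = 0.175
    u_mean: float = 20.0
    u_std: float = 4.0
    lam_mean: float = 0.040
    lam_std: float = 0.008
    n_beats_mean: float = 5.0
    tau_b_mean: float = 0.025
    tau_b_std: float = 0.003
    kappa_mean: float = 0.20
    kappa_std: float = 0.04
    css_interval_bounds_s: tuple[float, float] = (0.1, 2.5)
    css_interval_jitter: float = 0.15
    passive_reorientation: bool = True
    reorientation_sign: float = -1.0
    reorientation_rho_exponent: int = 3
    bout_rate_hz: float | None = None  # overrides 1/explore_interval_s if set

    @property
    def explore_rate(self) -> float:
        if self.bout_rate_hz is not None:
            return self.bout_rate_hz
        return 1.0 / self.explore_interval_s


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model for synthetic data.

    ``intensity_sigma`` is additive Gaussian pixel noise (same arbitrary
    units as LarvaModel.intensity); ``rho_jitter_mm`` and ``kappa_sigma`` are
    the pixel-scale jitters applied to ground-truth traces when bypassing the
    rendering stage.
    """

    intensity_sigma: float = 6.0
    background_level: float = 12.0
    rho_jitter_mm: float = 0.035
    kappa_sigma: float = 0.010


@dataclass(frozen=True)
class PipelineConfig:
    """One flat configuration object for the whole pipeline."""

    flow: FlowConfig = field(default_factory=FlowConfig)
    larva: LarvaModel = field(default_factory=LarvaModel)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    # tracking
    max_disp_mm: float = 3.5
    memory_frames: int = 100
    min_duration_s: float = 0.0
    contact_exclusion_mm: float = 2.0
    # bout detection / fitting
    activity_threshold: float = 5.0
    min_bout_duration_s: float = 0.040
    beat_threshold: float = 0.1
    # CSS labeling
    css_run_length: int = 3
    css_alpha_max_rad: float = math.radians(45.0)
    # session
    n_larvae: int = 2
    duration_s: float = 10.0
    seed: int = 0


def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_dict(v) for v in obj]
    return obj


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of a configuration (for run manifests)."""
    blob = json.dumps(_as_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _build(f.type, v)
        kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


_SUBCONFIGS = {
    "flow": FlowConfig,
    "larva": LarvaModel,
    "segmentation": SegmentationParams,
    "behavior": BehaviorParams,
    "noise": NoiseParams,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a flat JSON or TOML file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    kwargs = {}
    for key, val in data.items():
        if key in _SUBCONFIGS:
            kwargs[key] = _build(_SUBCONFIGS[key], val)
        else:
            kwargs[key] = tuple(val) if isinstance(val, list) else val
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_as_dict(cfg), indent=2))
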