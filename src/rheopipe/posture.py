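"""Posture from image moments: equivalent ellipses, head/tail split, body
angle alpha and signed curvature kappa.

The body angle alpha is measured from the OUTWARD radial direction at the
larva (the direction pointing away from the suction point) to the resolved
axis of the head ellipse, wrapped to (-pi, pi].  alpha = 0 therefore means
perfect counterflow orientation, consistent with the impulse model where a
bout of speed u increases rho by lam * u * cos(alpha).

Curvature: the body is split into head and tail halves by the plane through
the global centroid perpendicular to the global major axis (a level-1 binary
space partition).  The two halves' equivalent-ellipse minor axes intersect at
the center of curvature C; kappa = 1/R with R the mean distance from C to all
body pixels, signed positive when C lies to the right of the head direction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import FlowConfig
from .segmentation import Blob

__all__ = [
    "EquivalentEllipse",
    "PoseSample",
    "equivalent_ellipse",
    "decompose_bsp",
    "identify_head",
    "signed_curvature",
    "pose_from_blob",
]

EPS_ANGLE_DEG = 0.5  # minor axes closer than this are treated as parallel
KAPPA_CAP = 2.0  # |kappa| ceiling, 1/mm


@dataclass
class EquivalentEllipse:
    """Ellipse with the same intensity-weighted moments as a blob.

    ``orientation`` is the major-axis angle; after direction resolution it is
    a true direction in (-pi, pi], otherwise an axis in [-pi/2, pi/2).
    """

    center: np.ndarray  # (x, y) mm
    semi_major: float
    semi_minor: float
    orientation: float
    isotropic: bool = False

    @property
    def direction(self) -> np.ndarray:
        return np.array([math.cos(self.orientation), math.sin(self.orientation)])

    def resolve_toward(self, target: np.ndarray) -> "EquivalentEllipse":
        """Flip the axis so it points from the ellipse toward ``target``."""
        d = self.direction
        v = np.asarray(target, dtype=float) - self.center
        if float(d @ v) < 0:
            o = self.orientation + math.pi
            o = (o + math.pi) % (2 * math.pi) - math.pi
            return EquivalentEllipse(self.center, self.semi_major, self.semi_minor, o, self.isotropic)
        return self


@dataclass
class PoseSample:
    """One larva in one frame, in assay coordinates."""

    t: float
    x_mm: float
    y_mm: float
    rho: float
    theta: float
    alpha: float
    kappa: float
    head: EquivalentEllipse | None = None
    tail: EquivalentEllipse | None = None
    frame: int = -1
    larva_id: int = -1
    blob_area: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


def _blob_xy_mm(blob: Blob, pixel_size: float, origin) -> np.ndarray:
    # pixel centers: (col + .5, row + .5)
    xy = np.stack([blob.pixels[:, 1] + 0.5, blob.pixels[:, 0] + 0.5], axis=1)
    return xy * pixel_size + np.asarray(origin, dtype=float)


def equivalent_ellipse(blob: Blob, pixel_size: float = 1.0, origin=(0.0, 0.0)) -> EquivalentEllipse:
    """Intensity-weighted equivalent ellipse of a blob.

    The ellipse shares the blob's centroid and second central moments; a
    uniformly filled ellipse of semi-axes (a, b) has second moments
    (a^2/4, b^2/4), so axes are 2*sqrt(eigenvalues).  A per-pixel variance of
    1/12 px^2 (flat sampling within a pixel) is subtracted before scaling.
    """
    if blob.area < 5:
        raise ValueError("blob too small for a meaningful ellipse (area < 5)")
    xy = _blob_xy_mm(blob, pixel_size, origin)
    w = np.asarray(blob.values, dtype=float)
    w = w / w.sum()
    c = w @ xy
    d = xy - c
    mxx = float(w @ (d[:, 0] ** 2)) - pixel_size**2 / 12.0
    myy = float(w @ (d[:, 1] ** 2)) - pixel_size**2 / 12.0
    mxy = float(w @ (d[:, 0] * d[:, 1]))
    mxx = max(mxx, 1e-12)
    myy = max(myy, 1e-12)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam2 <= 0:
        raise ValueError("degenerate blob: zero variance along an axis")
    major = evecs[:, 1]
    orientation = math.atan2(major[1], major[0])
    if orientation >= math.pi / 2:
        orientation -= math.pi
    elif orientation < -math.pi / 2:
        orientation += math.pi
    iso = (lam1 - lam2) / lam1 < 1e-3
    return EquivalentEllipse(
        center=c,
        semi_major=2.0 * math.sqrt(lam1),
        semi_minor=2.0 * math.sqrt(lam2),
        orientation=orientation,
        isotropic=iso,
    )


def decompose_bsp(
    blob: Blob, pixel_size: float = 1.0, origin=(0.0, 0.0)
) -> tuple[Blob, Blob]:
    """Split a blob by the plane through the centroid perpendicular to the
    global major axis (level-1 BSP).  Returns (half_A, half_B) where half_A
    holds the pixels with non-negative projection on the major axis."""
    ell = equivalent_ellipse(blob, pixel_size, origin)
    xy = _blob_xy_mm(blob, pixel_size, origin)
    proj = (xy - ell.center) @ ell.direction
    sel = proj >= 0.0
    if not sel.any() or sel.all():
        raise ValueError("BSP split produced an empty half")
    half_a = Blob(blob.pixels[sel], blob.values[sel], blob.touches_border)
    half_b = Blob(blob.pixels[~sel], blob.values[~sel], blob.touches_border)
    return half_a, half_b


def identify_head(
    half_a: Blob,
    half_b: Blob,
    previous_pose: PoseSample | None = None,
    pixel_size: float = 1.0,
    origin=(0.0, 0.0),
) -> tuple[Blob, Blob, tuple[str, ...]]:
    """Decide which half is the head.

    Without history the heavier (larger-area) half wins — the head lobe is
    wider than the tail.  With a previous pose, continuity wins: the half
    whose centroid is nearer the previous head-ellipse center.  Exact area
    ties without history fall back to the smaller x-centroid and are flagged.
    """
    flags: tuple[str, ...] = ()
    if previous_pose is not None:
        ca = _blob_xy_mm(half_a, pixel_size, origin).mean(axis=0)
        cb = _blob_xy_mm(half_b, pixel_size, origin).mean(axis=0)
        prev = previous_pose.head.center
        da, db = np.linalg.norm(ca - prev), np.linalg.norm(cb - prev)
        if da != db:
            head, tail = (half_a, half_b) if da < db else (half_b, half_a)
        else:  # tie-break toward area
            head, tail = (half_a, half_b) if half_a.area >= half_b.area else (half_b, half_a)
    elif half_a.area != half_b.area:
        head, tail = (half_a, half_b) if half_a.area > half_b.area else (half_b, half_a)
    else:
        ca = _blob_xy_mm(half_a, pixel_size, origin).mean(axis=0)
        cb = _blob_xy_mm(half_b, pixel_size, origin).mean(axis=0)
        head, tail = (half_a, half_b) if ca[0] <= cb[0] else (half_b, half_a)
        flags = ("head_ambiguous",)
    return head, tail, flags


def signed_curvature(
    head: EquivalentEllipse,
    tail: EquivalentEllipse,
    blob: Blob,
    pixel_size: float = 1.0,
    origin=(0.0, 0.0),
    eps_angle_deg: float = EPS_ANGLE_DEG,
    kappa_cap: float = KAPPA_CAP,
) -> float:
    """Signed body curvature (1/mm) from the two halves' minor axes.

    The minor-axis lines intersect at the center of curvature C; the radius
    R is the mean distance from C to all body pixels and kappa = +-1/R,
    positive when C lies to the right of the resolved head direction.
    Near-parallel minor axes (within ``eps_angle_deg``) give kappa = 0.
    """
    dh = head.direction
    dt = tail.direction
    # minor axes are perpendicular to the major axes
    n1 = np.array([-dh[1], dh[0]])
    n2 = np.array([-dt[1], dt[0]])
    cross = n1[0] * n2[1] - n1[1] * n2[0]
    if abs(cross) < math.sin(math.radians(eps_angle_deg)):
        return 0.0
    # head.center + s*n1 == tail.center + u*n2
    rhs = tail.center - head.center
    s = (rhs[0] * n2[1] - rhs[1] * n2[0]) / cross
    C = head.center + s * n1
    xy = _blob_xy_mm(blob, pixel_size, origin)
    R = float(np.mean(np.hypot(xy[:, 0] - C[0], xy[:, 1] - C[1])))
    if R <= 0:
        return 0.0
    w_c = C - (head.center + tail.center) / 2.0
    z = dh[0] * w_c[1] - dh[1] * w_c[0]
    kappa = (1.0 if z < 0 else -1.0) / R
    return float(np.clip(kappa, -kappa_cap, kappa_cap))


def pose_from_blob(
    blob: Blob,
    config: FlowConfig,
    previous_pose: PoseSample | None = None,
    t: float = 0.0,
    frame: int = -1,
    larva_id: int = -1,
) -> PoseSample:
    """Full pose (rho, theta, alpha, kappa) of one blob in assay coordinates."""
    px = config.pixel_size
    origin = config.fov[:2]
    centroid = blob.centroid_mm(px, origin)
    sink = np.asarray(config.sink, dtype=float)
    rel = centroid - sink
    rho = float(np.hypot(*rel))
    if rho <= 0:
        raise ValueError("blob centroid coincides with the sink")
    theta = math.atan2(rel[1], rel[0])

    half_a, half_b = decompose_bsp(blob, px, origin)
    head_blob, tail_blob, flags = identify_head(half_a, half_b, previous_pose, px, origin)
    head = equivalent_ellipse(head_blob, px, origin)
    tail = equivalent_ellipse(tail_blob, px, origin)
    # resolve the head axis to point away from the split plane, i.e. from the
    # whole-body centroid through the head half's centroid
    global_c = blob.centroid_mm(px, origin)
    head = head.resolve_toward(global_c + 2.0 * (head.center - global_c))
    alpha = (head.orientation - theta + math.pi) % (2 * math.pi) - math.pi
    # map -pi to +pi so alpha lies in (-pi, pi]
    if alpha <= -math.pi:
        alpha += 2 * math.pi
    kappa = signed_curvature(head, tail, blob, px, origin)
    if blob.touches_border:
        flags = flags + ("border",)
    return PoseSample(
        t=t,
        x_mm=float(centroid[0]),
        y_mm=float(centroid[1]),
        rho=rho,
        theta=theta,
        alpha=float(alpha),
        kappa=kappa,
        head=head,
        tail=tail,
        frame=frame,
        larva_id=larva_id,
        blob_area=blob.area,
        flags=flags,
    )
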