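"""Geometric analyses of recombinase configurations.

Covers the consensus rotation mapping (anchor nanofocus to the origin,
goal nanofocus onto the positive vertical axis, all channels
co-transformed), intra-configuration center distances, the minimal
distance from a nanofocus to the synaptonemal-complex axes, the
inside/outside call relative to a synapsed lateral-element pair, and
the acute angle between a D2R1 dumbbell and the local axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import AxisPolyline
from .nanofoci import DMC1, RAD51, Configuration, Nanofocus
from .render import DensityImage, render_density

__all__ = [
    "RotatedRoi",
    "AxisDistanceRecord",
    "rotate_to_consensus",
    "accumulate_consensus",
    "internal_distances",
    "distance_to_axis",
    "lateral_position",
    "d2r1_axis_angle",
    "total_least_squares_direction",
]

AXIS_DISTANCE_CUTOFF_NM = 500.0


def _role_center(config: Configuration, channel: str, role: str) -> np.ndarray:
    for nf in config.of_channel(channel):
        if nf.role == role or (role == "any" and nf.role in ("single", "close")):
            return np.asarray(nf.center_of_mass, float)
    raise ValueError(f"configuration {config.label} has no {channel} nanofocus with role {role!r}")


def anchor_goal_centers(
    config: Configuration, anchor: str, goal: str
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve role descriptors like ``"close DMC1"`` / ``"far DMC1"`` /
    ``"RAD51"`` to nanofocus centers of mass."""

    def resolve(desc: str) -> np.ndarray:
        parts = desc.split()
        role, channel = (parts if len(parts) == 2 else ("any", parts[0]))
        return _role_center(config, channel, role)

    return resolve(anchor), resolve(goal)


@dataclass
class RotatedRoi:
    """A ROI's localizations after the consensus rigid transform."""

    roi_id: str
    localizations: dict[str, np.ndarray]  # channel -> (n, 2) nm
    anchor: str
    goal: str
    far_center: np.ndarray | None = None  # transformed far-nanofocus center
    far_localizations: np.ndarray | None = None


def rigid_transform(anchor_xy: np.ndarray, goal_xy: np.ndarray):
    """Return f(points): translation of anchor to origin followed by the
    rotation placing goal on the positive vertical half-axis."""
    anchor_xy = np.asarray(anchor_xy, float)
    v = np.asarray(goal_xy, float) - anchor_xy
    d = np.hypot(*v)
    if d == 0:
        raise ValueError("anchor and goal coincide")
    # rotate v onto (0, +d): angle from v to the +y axis
    theta = np.arctan2(v[0], v[1])  # rotation by +theta maps v -> (0, d)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])

    def apply(points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - anchor_xy) @ R.T

    return apply


def rotate_to_consensus(
    config: Configuration,
    localizations: dict[str, np.ndarray],
    anchor: str,
    goal: str,
) -> RotatedRoi:
    """Apply the consensus rigid transform to all channels of one ROI.

    ``anchor``/``goal`` are role descriptors (e.g. ``"close DMC1"``,
    ``"RAD51"``). No reflection or scaling occurs, so all pairwise
    distances are preserved; the anchor center of mass maps to the
    origin and the goal center to (0, +d).
    """
    if anchor == goal:
        raise ValueError("anchor and goal must differ")
    a, g = anchor_goal_centers(config, anchor, goal)
    f = rigid_transform(a, g)
    moved = {ch: f(pts) for ch, pts in localizations.items()}
    far = [nf for nf in config.nanofoci if nf.role == "far"]
    far_center = f(np.asarray(far[0].center_of_mass))[None, :][0] if far else None
    return RotatedRoi(config.roi_id, moved, anchor, goal, far_center)


def accumulate_consensus(
    rotated: list[RotatedRoi],
    precisions: float | dict[str, float] = 15.0,
    extent: tuple[float, float, float, float] = (-500.0, 500.0, -500.0, 500.0),
    pixel_size: float = 5.0,
) -> tuple[dict[str, DensityImage], np.ndarray, DensityImage | None]:
    """Pool rotated ROIs into consensus images.

    Returns per-channel summed density images on a common grid, the
    far-nanofocus center dots (one per contributing ROI, independent of
    localization counts), and the pooled far-localization density (None
    when no ROI carries far localizations).
    """
    if not rotated:
        raise ValueError("no rotated ROIs to accumulate")
    channels = sorted({ch for r in rotated for ch in r.localizations})
    images: dict[str, DensityImage] = {}
    for ch in channels:
        pts = [r.localizations[ch] for r in rotated if ch in r.localizations]
        allpts = np.vstack(pts) if pts else np.zeros((0, 2))
        sigma = precisions[ch] if isinstance(precisions, dict) else precisions
        images[ch] = render_density(
            allpts, pixel_size=pixel_size, bandwidth_mode="fixed",
            fixed_sigma=sigma, extent=extent,
        )
    dots = np.array([r.far_center for r in rotated if r.far_center is not None]).reshape(-1, 2)
    far_pts = [r.far_localizations for r in rotated if r.far_localizations is not None]
    far_img = None
    if far_pts:
        sigma = (
            np.mean(list(precisions.values())) if isinstance(precisions, dict) else precisions
        )
        far_img = render_density(
            np.vstack(far_pts), pixel_size=pixel_size, bandwidth_mode="fixed",
            fixed_sigma=float(sigma), extent=extent,
        )
    return images, dots, far_img


# ---------------------------------------------------------------------------
# distances


_PAIRS = {
    "D1R1": [("D-R", ("DMC1", "single"), ("RAD51", "single"))],
    "D2R1": [
        ("Dc-R", ("DMC1", "close"), ("RAD51", "single")),
        ("Df-R", ("DMC1", "far"), ("RAD51", "single")),
        ("Dc-Df", ("DMC1", "close"), ("DMC1", "far")),
    ],
    "D1R2": [
        ("Rc-D", ("RAD51", "close"), ("DMC1", "single")),
        ("Rf-D", ("RAD51", "far"), ("DMC1", "single")),
        ("Rc-Rf", ("RAD51", "close"), ("RAD51", "far")),
    ],
}


def internal_distances(config: Configuration) -> list[tuple[str, float]]:
    """Center-of-mass distances between the configuration's defined pairs
    (D1R1: D-R; D2R1: Dc-R, Df-R, Dc-Df; D1R2: Rc-D, Rf-D, Rc-Rf)."""
    if len(config.nanofoci) < 2:
        raise ValueError("configuration has fewer than 2 nanofoci")
    if config.label not in _PAIRS:
        raise ValueError(f"no defined pair set for configuration {config.label}")
    out = []
    for name, (ch_a, role_a), (ch_b, role_b) in _PAIRS[config.label]:
        a = _role_center(config, ch_a, role_a)
        b = _role_center(config, ch_b, role_b)
        out.append((name, float(np.hypot(*(a - b)))))
    return out


@dataclass
class AxisDistanceRecord:
    roi_id: str
    channel: str
    role: str
    distance: float
    fragment_id: str
    synapsis: str
    excluded: bool
    position: str = "not_applicable"  # inside/outside set separately


def distance_to_axis(
    nf: Nanofocus,
    axes: list[AxisPolyline],
    cutoff: float = AXIS_DISTANCE_CUTOFF_NM,
) -> AxisDistanceRecord:
    """Minimal center-of-mass distance to any axis fragment.

    Distances beyond ``cutoff`` (default 500 nm) are flagged ``excluded``
    and left out of downstream statistics; the nearest fragment's
    synapsis status is recorded.
    """
    if not axes:
        raise ValueError("no axis polylines supplied")
    p = np.asarray(nf.center_of_mass, float)
    dists = [ax.distance_to(p) for ax in axes]
    best = int(np.argmin(dists))
    d = float(dists[best])
    frag = axes[best]
    return AxisDistanceRecord(
        roi_id=nf.roi_id,
        channel=nf.channel,
        role=nf.role,
        distance=d,
        fragment_id=frag.fragment_id,
        synapsis="synapsed" if frag.synapsed else "unsynapsed",
        excluded=d > cutoff,
    )


def lateral_position(
    nf: Nanofocus, lateral_pair: tuple[AxisPolyline, AxisPolyline]
) -> str:
    """Inside/outside call relative to a synapsed lateral-element pair.

    With u1, u2 the unit vectors from the center of mass to its nearest
    points on each lateral, the nanofocus is *inside* iff u1 . u2 <= 0
    (opposite directions; a point lying exactly on a lateral counts as
    inside). Raises on an unsynapsed input.
    """
    a, b = lateral_pair
    if not (a.synapsed and b.synapsed):
        raise ValueError("lateral_position requires a synapsed lateral pair")
    p = np.asarray(nf.center_of_mass, float)
    us = []
    for ax in (a, b):
        foot = ax.point_at(ax.project(p))
        v = foot - p
        n = np.hypot(*v)
        if n == 0:
            return "inside"
        us.append(v / n)
    return "inside" if float(np.dot(us[0], us[1])) <= 0 else "outside"


# ---------------------------------------------------------------------------
# D2R1 dumbbell angle


def total_least_squares_direction(points: np.ndarray) -> np.ndarray:
    """Unit direction of the orthogonal (total) least-squares line."""
    pts = np.asarray(points, float)
    if len(pts) < 2:
        raise ValueError("need >= 2 points for a line fit")
    d = pts - pts.mean(axis=0)
    if not np.any(np.abs(d) > 1e-12):
        raise ValueError("degenerate (coincident) points")
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return vt[0]


def d2r1_axis_angle(config: Configuration, axis_points: np.ndarray) -> float:
    """Acute angle (degrees, folded into [0, 90]) between the total
    least-squares line through the three D2R1 nanofocus centers and the
    total least-squares line through the nearby axis coordinates."""
    if config.label != "D2R1":
        raise ValueError("angle analysis is defined for D2R1 configurations")
    centers = np.array([nf.center_of_mass for nf in config.nanofoci])
    u = total_least_squares_direction(centers)
    v = total_least_squares_direction(np.asarray(axis_points, float))
    cosang = abs(float(np.dot(u, v)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
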