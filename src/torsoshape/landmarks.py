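"""Torso segment boundaries and anterior/posterior surface landmarks.

The torso segment runs from the buttock (gluteal/hip-girth) landmark to the
xiphoid process; the xiphoid height is placed at 60% of the buttock-to-neck
distance.  At that height a thin horizontal band of points is cut from the
cloud and the posterior (L1) and anterior (L2) surface landmarks are found as
the extreme points along the anterior-posterior direction, robustified as the
centroid of the 5 most extreme points.

Facing convention: the participant faces -x, so the anterior landmark is the
minimal-x extreme and the posterior the maximal-x extreme.  To keep detection
equivariant under yaw of the subject, the band's anterior direction is first
estimated from the third-moment (skewness) structure of the outline (human
cross-sections are anteriorly fuller) and the band is de-rotated before the
x-extrema rule is applied.  Perfectly symmetric bands carry no skewness; for
those the raw x-extrema rule is used unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

XIPHOID_BAND_HALF_WIDTH_MM = 1.0   # the 2 mm extraction band
ORIENTATION_SLAB_FRACTION = 0.12   # of buttock-to-neck distance, each side
N_EXTREME_POINTS = 5
_SKEWNESS_THRESHOLD = 0.04         # below this the outline is treated as symmetric


@dataclass(frozen=True)
class LandmarkSet:
    """Segment boundary heights plus the L1/L2 surface landmarks (mm)."""

    buttock_height: float
    neck_height: float
    xiphoid_height: float
    L1: np.ndarray   # posterior
    L2: np.ndarray   # anterior

    def __post_init__(self) -> None:
        if not self.buttock_height < self.xiphoid_height < self.neck_height:
            raise ValueError("landmark heights must satisfy "
                             "buttock < xiphoid < neck")


def xiphoid_height(buttock_height: float, neck_height: float,
                   fraction: float = 0.60) -> float:
    """Xiphoid height from the buttock/neck landmarks.

    Placed at ``fraction`` (default 60%) of the buttock-to-neck distance.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if neck_height <= buttock_height:
        raise ValueError("neck landmark must lie above the buttock landmark")
    return buttock_height + fraction * (neck_height - buttock_height)


def extract_band(cloud: np.ndarray, z_center: float,
                 half_width: float = XIPHOID_BAND_HALF_WIDTH_MM) -> np.ndarray:
    """All points with |z - z_center| <= half_width (closed interval)."""
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != 3 or len(cloud) == 0:
        raise ValueError("cloud must be a non-empty (N, 3) array")
    band = cloud[np.abs(cloud[:, 2] - z_center) <= half_width]
    if len(band) == 0:
        raise ValueError(f"no surface at height {z_center:.1f} mm")
    return band


def _skewness_direction(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Radial-asymmetry direction of a planar band.

    Computes the first circular moment of the radius deviations about the
    band centroid, v = mean((r_i - r_mean) * unit(p_i - c)), and returns
    ``(v / |v|, |v| / rms(r - r_mean))``.  For torso cross-sections the
    direction points toward the anteriorly fuller side; for symmetric
    outlines the normalised magnitude is ~0.  Weighting by radius
    deviation (rather than third moments of the coordinates) keeps the
    statistic insensitive to uneven angular sampling density.
    """
    d = xy - xy.mean(axis=0)
    r = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
    u = d / r[:, None]
    w = r - r.mean()
    v = (w[:, None] * u).mean(axis=0)
    rms = float(np.sqrt(np.mean(w * w)))
    norm = float(np.linalg.norm(v))
    if norm == 0.0 or rms == 0.0:
        return np.array([1.0, 0.0]), 0.0
    return v / norm, norm / rms


def _voronoi_centroid(xy: np.ndarray) -> np.ndarray:
    """Centroid with angular-gap (Voronoi) weights about the plain mean.

    Scanner bands can contain partial extra arcs (points that drift across
    the band boundary under z-noise); weighting each point by its angular
    gap removes the sampling-density bias those arcs induce in the plain
    centroid.  Requires angularly deduplicated input.
    """
    c0 = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - c0[1], xy[:, 0] - c0[0])
    order = np.argsort(ang, kind="stable")
    a_sorted = ang[order]
    gaps_fwd = np.diff(np.concatenate([a_sorted,
                                       [a_sorted[0] + 2.0 * np.pi]]))
    gaps_bwd = np.roll(gaps_fwd, 1)
    wts = np.empty(len(xy))
    wts[order] = 0.5 * (gaps_fwd + gaps_bwd)
    wts /= wts.sum()
    return (wts[:, None] * xy).sum(axis=0)


def _pole_estimate(w: np.ndarray, side: float, n_extreme: int,
                   method: str) -> np.ndarray:
    """Locate the outline's extreme point along +/-x in de-rotated coords.

    ``method="mean"`` is the centroid of the ``n_extreme`` most extreme
    points (ties included, so mirror-symmetric outlines stay symmetric);
    ``method="parabola"`` fits a local quadratic x(y) over an adaptive
    extreme window and returns its vertex, which suppresses the tangential
    scatter that a plain extreme-point centroid inherits from noise.
    """
    x = side * w[:, 0]
    y = w[:, 1]
    extent = float(np.ptp(x))
    tol = 1e-6 * max(1.0, extent)
    if method == "mean" or len(w) < 25:
        xs = np.sort(x)
        sel = x >= xs[-min(n_extreme, len(x))] - tol
        return np.array([side * x[sel].mean(), y[sel].mean()])
    if method == "polar":
        # outline crossing of the +/-x axis: local quadratic fit of the
        # radius over a +/-0.25 rad window.  Extremum-based poles are
        # ill-conditioned on the nearly flat posterior aspect (curvature
        # radius of metres), while the axis crossing stays put.
        theta = np.arctan2(y, x)
        r = np.hypot(x, y)
        sel = np.abs(theta) <= 0.25
        if sel.sum() >= 6:
            A = np.column_stack([np.ones(int(sel.sum())), theta[sel],
                                 theta[sel] ** 2])
            coef, *_ = np.linalg.lstsq(A, r[sel], rcond=None)
            return np.array([side * coef[0], 0.0])
        # fall through to the parabola fit when the sector is occluded
    elif method != "parabola":
        raise ValueError("method must be 'polar', 'parabola' or 'mean'")
    # fixed-fraction extreme window: a count quantile is robust to a noisy
    # single maximum, unlike a threshold anchored on it
    k = max(8, int(round(0.15 * len(x))))
    xs = np.sort(x)
    sel = x >= xs[-min(k, len(x))] - tol
    ys, xsel = y[sel], x[sel]
    A = np.column_stack([np.ones(int(sel.sum())), ys, ys * ys])
    (a, b, c), *_ = np.linalg.lstsq(A, xsel, rcond=None)
    y0 = -b / (2.0 * c) if c < 0 else float(ys.mean())
    y0 = float(np.clip(y0, ys.min(), ys.max()))
    return np.array([side * (a + b * y0 + c * y0 * y0), y0])


def detect_ap_landmarks(band: np.ndarray, nominal_z: float | None = None,
                        n_extreme: int = N_EXTREME_POINTS,
                        orient: str = "auto",
                        method: str = "polar",
                        orientation_points: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (L1) and anterior (L2) landmarks of a planar band.

    L1 is the maximal-x and L2 the minimal-x extreme of the outline.  With
    ``orient="auto"`` the band is first de-rotated so its skewness-estimated
    anterior direction points along -x, which makes detection equivariant
    under yaw; ``orient="none"`` applies the raw x-extrema rule.  The
    anterior direction can be estimated from a larger point set than the
    band itself (``orientation_points``, e.g. a thick slab around the
    xiphoid) — one thin band carries too few points for a reliable
    asymmetry estimate on noisy scans.  The pole position is computed as
    the outline's crossing of the AP axis (``method="polar"``, default), a
    local parabola-vertex fit (``"parabola"``), or the centroid of the
    ``n_extreme`` most extreme points (``"mean"``); ``n_extreme=1`` with
    ``method="mean"`` gives the raw extreme point.
    """
    band = np.asarray(band, dtype=float)
    if band.ndim != 2 or band.shape[1] not in (2, 3):
        raise ValueError("band must be (N, 2) or (N, 3)")
    if len(band) < 10:
        raise ValueError("band must contain at least 10 points")
    xy = band[:, :2]
    if nominal_z is None:
        nominal_z = float(band[:, 2].mean()) if band.shape[1] == 3 else 0.0

    centroid = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0])
    ang = np.sort(ang)
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2.0 * np.pi]]))
    if gaps.max() > 2.0 * np.pi / 3.0:
        raise ValueError("band leaves more than 120 degrees of arc "
                         "uncovered; not a closed torso section")

    rot = np.eye(2)
    if orient == "auto":
        opts = xy if orientation_points is None \
            else np.asarray(orientation_points, dtype=float)[:, :2]
        direction, gamma = _skewness_direction(opts)
        if gamma >= _SKEWNESS_THRESHOLD:
            # rotate the anterior direction onto -x
            ca, sa = -direction[0], -direction[1]
            rot = np.array([[ca, sa], [-sa, ca]])
    elif orient != "none":
        raise ValueError("orient must be 'auto' or 'none'")

    # collapse angularly coincident points (a band may catch two raster
    # rings on the same angular grid) so the extreme-point window always
    # spans n_extreme distinct outline positions
    angles = np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0])
    order_a = np.argsort(angles, kind="stable")
    a_sorted = angles[order_a]
    xy_sorted = xy[order_a]
    starts = np.flatnonzero(
        np.concatenate([[True], np.diff(a_sorted) >= 1e-6]))
    ends = np.append(starts[1:], len(a_sorted))
    xy_u = np.array([xy_sorted[s:e].mean(axis=0)
                     for s, e in zip(starts, ends)])

    centroid = _voronoi_centroid(xy_u)
    w = (xy_u - centroid) @ rot.T
    if np.ptp(w[:, 0]) <= 0.0:
        raise ValueError("degenerate band: zero extent along the x-axis")
    L1_w = _pole_estimate(w, +1.0, n_extreme, method)
    L2_w = _pole_estimate(w, -1.0, n_extreme, method)
    L1_xy = centroid + L1_w @ rot
    L2_xy = centroid + L2_w @ rot
    L1 = np.array([L1_xy[0], L1_xy[1], nominal_z])
    L2 = np.array([L2_xy[0], L2_xy[1], nominal_z])
    return L1, L2


def detect_landmarks(cloud: np.ndarray, buttock_height: float,
                     neck_height: float, fraction: float = 0.60,
                     half_width: float = XIPHOID_BAND_HALF_WIDTH_MM,
                     orient: str = "auto") -> LandmarkSet:
    """Full landmark set for one cloud given the segment boundary heights."""
    zx = xiphoid_height(buttock_height, neck_height, fraction)
    band = extract_band(cloud, zx, half_width)
    # anterior direction estimated from a thick slab: one 2 mm band has too
    # few points for a stable asymmetry estimate on noisy scans.  The slab
    # depth is body-relative so it commutes with uniform scaling.
    half_depth = ORIENTATION_SLAB_FRACTION * (neck_height - buttock_height)
    slab = cloud[np.abs(cloud[:, 2] - zx) <= half_depth]
    L1, L2 = detect_ap_landmarks(band, nominal_z=zx, orient=orient,
                                 orientation_points=slab)
    return LandmarkSet(buttock_height=buttock_height, neck_height=neck_height,
                       xiphoid_height=zx, L1=L1, L2=L2)
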