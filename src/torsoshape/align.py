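"""Anatomical frame, torso cropping, slice extraction and size removal.

Each torso is expressed in its own anatomical coordinate system built from
the L1 (posterior) / L2 (anterior) landmarks: the origin is the midpoint of
L1L2, X is the unit vector L1->L2, the vertical axis Z is obtained from X and
an auxiliary in-plane vector w (X rotated by 15 degrees about the global
vertical), and Y = X x Z.  The segment between the buttock and xiphoid
heights is cropped and 25 thin (2 mm) horizontal bands are extracted at
uniform intervals; the points of each band are flattened to the band-centre
height, giving 25 planar outline profiles.  Scale is removed by a single
joint scale factor that sets the pooled centroid size of all 25 profiles
(each profile centred at its own centroid) to a common reference.

Centroid size, the standard geometric-morphometrics size measure, is

    CS(X) = sqrt( sum_i sum_j (X_ij - C_j)^2 )

the square root of the summed squared deviations of the configuration's
points from their centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

N_SLICES_DEFAULT = 25
BAND_HEIGHT_MM_DEFAULT = 2.0
MIN_POINTS_PER_SLICE = 10
FRAME_AUX_ROTATION_DEG = 15.0


@dataclass(frozen=True)
class AnatomicalFrame:
    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.X, self.Y, self.Z):
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError("frame axes must be unit vectors")
        if max(abs(self.X @ self.Y), abs(self.X @ self.Z),
               abs(self.Y @ self.Z)) > 1e-9:
            raise ValueError("frame axes must be mutually orthogonal")

    @property
    def basis(self) -> np.ndarray:
        """Rows are the X, Y, Z axes; maps global offsets to frame coords."""
        return np.vstack([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class SliceProfile:
    """One flattened outline: points ordered CCW by angle about the slice
    centroid, starting at the +x axis."""

    slice_index: int
    z_level: float
    points: np.ndarray   # (K, 2)

    def __post_init__(self) -> None:
        if len(self.points) < MIN_POINTS_PER_SLICE:
            raise ValueError("slice profile needs >= 10 points")


@dataclass(frozen=True)
class TorsoSlices:
    profiles: tuple[SliceProfile, ...]
    joint_centroid_size: float
    scale_factor_applied: float = 1.0

    def __post_init__(self) -> None:
        if len(self.profiles) != N_SLICES_DEFAULT:
            raise ValueError(f"expected {N_SLICES_DEFAULT} profiles, "
                             f"got {len(self.profiles)}")


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return (v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c))


def build_frame(L1: np.ndarray, L2: np.ndarray,
                global_up: np.ndarray = np.array([0.0, 0.0, 1.0])
                ) -> AnatomicalFrame:
    """Anatomical frame from the posterior/anterior landmarks.

    origin = midpoint of L1L2; X = unit L1->L2; w = X rotated +15 degrees
    about the global vertical; Z = unit X x w (flipped to point upward);
    Y = X x Z.
    """
    L1 = np.asarray(L1, dtype=float)
    L2 = np.asarray(L2, dtype=float)
    up = np.asarray(global_up, dtype=float)
    up = up / np.linalg.norm(up)
    d = L2 - L1
    if np.linalg.norm(d) <= 1.0:
        raise ValueError("landmarks closer than 1 mm; cannot build frame")
    X = d / np.linalg.norm(d)
    if 1.0 - abs(X @ up) < 1e-9:
        raise ValueError("landmark axis parallel to the vertical")
    w = _rotate_about(X, up, math.radians(FRAME_AUX_ROTATION_DEG))
    Z = np.cross(X, w)
    Z = Z / np.linalg.norm(Z)
    if Z @ up < 0:
        Z = -Z
    Y = np.cross(X, Z)
    Y = Y / np.linalg.norm(Y)
    # re-orthogonalise X against Z to absorb rounding in near-degenerate input
    Xo = X - (X @ Z) * Z
    Xo = Xo / np.linalg.norm(Xo)
    return AnatomicalFrame(origin=0.5 * (L1 + L2), X=Xo, Y=Y, Z=Z)


def transform_to_frame(cloud: np.ndarray, frame: AnatomicalFrame) -> np.ndarray:
    """Express the cloud in the anatomical frame (rigid map)."""
    cloud = np.asarray(cloud, dtype=float)
    return (cloud - frame.origin) @ frame.basis.T


def crop_torso(cloud: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Keep points with z in the closed interval [lower, upper]."""
    if lower >= upper:
        raise ValueError("crop bounds must satisfy lower < upper")
    cloud = np.asarray(cloud, dtype=float)
    kept = cloud[(cloud[:, 2] >= lower) & (cloud[:, 2] <= upper)]
    if len(kept) == 0:
        raise ValueError("crop produced an empty cloud")
    return kept


def _order_outline(points_xy: np.ndarray) -> np.ndarray:
    """Order points CCW by angle about their centroid, starting at +x."""
    c = points_xy.mean(axis=0)
    ang = np.mod(np.arctan2(points_xy[:, 1] - c[1], points_xy[:, 0] - c[0]),
                 2.0 * np.pi)
    return points_xy[np.argsort(ang, kind="stable")]


def extract_slices(cloud: np.ndarray, lower: float | None = None,
                   upper: float | None = None,
                   n_slices: int = N_SLICES_DEFAULT,
                   band_height: float = BAND_HEIGHT_MM_DEFAULT) -> TorsoSlices:
    """Extract ``n_slices`` flattened outline profiles from a frame-aligned,
    cropped cloud.

    Band centres are placed at uniform intervals spanning the segment
    inclusive of half-band margins, so every band lies fully inside the
    crop.  Each band's points take the band-centre z (flattening).  A band
    with fewer than 10 points (e.g. excessive occlusion) raises.
    """
    cloud = np.asarray(cloud, dtype=float)
    if lower is None:
        lower = float(cloud[:, 2].min())
    if upper is None:
        upper = float(cloud[:, 2].max())
    if upper - lower < n_slices * band_height:
        raise ValueError("torso segment shorter than n_slices x band_height")
    centres = np.linspace(lower + band_height / 2.0,
                          upper - band_height / 2.0, n_slices)
    half = band_height / 2.0
    profiles = []
    for k, c in enumerate(centres):
        sel = np.abs(cloud[:, 2] - c) <= half
        pts = cloud[sel, :2]
        if len(pts) < MIN_POINTS_PER_SLICE:
            raise ValueError(f"band {k} at z={c:.1f} has only {len(pts)} "
                             "points (occlusion too severe)")
        profiles.append(SliceProfile(slice_index=k, z_level=float(c),
                                     points=_order_outline(pts)))
    return TorsoSlices(profiles=tuple(profiles),
                       joint_centroid_size=joint_centroid_size(profiles))


def centroid_size(points: np.ndarray) -> float:
    """Centroid size of a planar or 3D configuration (printed formula)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("centroid size needs >= 2 points")
    dev = points - points.mean(axis=0)
    return float(np.sqrt(np.sum(dev * dev)))


def joint_centroid_size(profiles) -> float:
    """Pooled centroid size over all slices, each centred at its own
    centroid (x, y deviations only; profiles are already flattened)."""
    total = 0.0
    for p in profiles:
        dev = p.points - p.points.mean(axis=0)
        total += float(np.sum(dev * dev))
    return math.sqrt(total)


def scale_slices(slices: TorsoSlices, reference: float = 1.0,
                 cs_source: str = "raw") -> TorsoSlices:
    """Scale all profiles by one factor so the joint centroid size equals
    ``reference``; z levels are rescaled by the same factor.

    ``cs_source`` chooses the configuration the joint centroid size is
    measured on: ``"raw"`` pools the band points as extracted, while
    ``"resampled"`` pools each outline resampled at 70 uniform angles.
    Centroid size is a statistic of a fixed-size landmark configuration;
    raw scanner bands have density-dependent point counts, which makes the
    raw-point variant depend (as sqrt of count) on sampling density rather
    than purely on scale.  The resampled variant gives every participant the
    same configuration size and removes scale exactly, and is what the
    pipeline uses.
    """
    if cs_source == "raw":
        cs = joint_centroid_size(slices.profiles)
    elif cs_source == "resampled":
        from .descriptors import joint_centroid_size_resampled

        cs = joint_centroid_size_resampled(slices)
    else:
        raise ValueError("cs_source must be 'raw' or 'resampled'")
    if cs <= 0.0:
        raise ValueError("degenerate configuration: zero joint centroid size")
    factor = reference / cs
    profiles = tuple(
        replace(p, points=p.points * factor, z_level=p.z_level * factor)
        for p in slices.profiles)
    return TorsoSlices(profiles=profiles,
                       joint_centroid_size=joint_centroid_size(profiles),
                       scale_factor_applied=slices.scale_factor_applied * factor)
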