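"""Synthetic torso-cohort generator.

Produces scanner-like 3D point clouds of the human torso with a known latent
shape structure, so that every downstream stage of the morphometric pipeline
(landmarking, frame alignment, slice extraction, spectral descriptors, shape
PCA, PLS regression) can be validated against ground truth.

The surface of one torso is a star-shaped radius function about a vertical
axis,

    r(theta, z) = [B(z) + taper * G_T * g3(u)] * (1 - ECC * cos 2*theta)
                  - [ASYM * B(z) + ap * G_A * g1(u) + bulge * G_B * g2(u)] * cos theta

with ``u`` the normalised height within the torso segment (0 at the buttock
landmark, 1 at the xiphoid process), ``B(z)`` a smooth base-radius profile
(hip fullness, waist narrowing, chest re-expansion) inflated by the
``roundness`` latent, and fixed axial envelopes ``g1..g3``.  ``theta`` is
measured from the +x axis; the participant faces -x, so anterior fullness
corresponds to the ``-cos theta`` terms.  A fixed cos 2*theta ellipticity
(torsos are wider than they are deep) and a fixed population-level anterior
fullness are part of the base anatomy; the five latents modulate it:

* ``ap_weighting`` — anterior-posterior mass shift, mid-torso envelope;
* ``taper``        — upper-vs-lower girth gradient; its per-sex mean offset is
                     the sole sex effect (males wider above, females below);
* ``roundness``    — global girth inflation (essentially size);
* ``lean``         — lateral shear of the whole segment, applied after the
                     surface is built and generated independently of all
                     measures (the analogue of postural lean);
* ``bulge``        — localised low-anterior protrusion.

Clouds are sampled as horizontal rings whose vertical pitch (~1.5 mm) is
finer than the 2 mm extraction bands, so any band is populated; two bands
may be occluded over a contiguous angular arc, isotropic point noise is
added, and the cloud is finally moved by a nuisance rigid pose plus uniform
scale.
Ground-truth body measures are evaluated on the analytic noise-free surface
and re-expressed in the posed (scaled) units.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LATENT_NAMES = ("ap_weighting", "taper", "roundness", "lean", "bulge")

# Fixed anatomy of the surface model (millimetres where dimensional).
ECCENTRICITY = 0.15        # cos(2 theta) width-over-depth coefficient
ANTERIOR_FULLNESS = 0.10   # fixed anterior cos(theta) share of the base radius
AP_GAIN_MM = 9.0           # mm of radius per unit ap_weighting at envelope peak
TAPER_GAIN_MM = 7.0        # mm of radius per unit taper at the segment ends
BULGE_GAIN_MM = 7.0        # mm of radius per unit bulge at envelope peak
LEAN_GAIN = 0.035          # lateral shear slope per unit lean (~2 deg)
NECK_HEIGHT_FRAC = 0.845   # neck landmark height as fraction of stature
BUTTOCK_HEIGHT_FRAC = 0.493
XIPHOID_FRACTION = 0.60    # xiphoid at 60% of the buttock-to-neck distance
LANDMARK_NOISE_SD_MM = 8.0
GEN_MARGIN_MM = 30.0       # generated surface extends past the torso segment
DITHER_PERIODS = 11        # angular periods of the sawtooth z-dither
TISSUE_DENSITY_KG_M3 = 1050.0
TORSO_MASS_SHARE = 0.38    # torso volume -> whole-body weight proxy


@dataclass(frozen=True)
class LatentShape:
    """One participant's scores on the five generative shape modes."""

    ap_weighting: float
    taper: float
    roundness: float
    lean: float
    bulge: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"latent shape values must be finite, got {vals}")
        if self.roundness <= -1.0:
            raise ValueError("roundness <= -1 collapses the surface")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in LATENT_NAMES], dtype=float)


@dataclass(frozen=True)
class PoseTransform:
    """Nuisance rigid pose + uniform scale applied to a generated cloud."""

    rotation_deg: float = 0.0   # about the global vertical axis
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        a = math.radians(self.rotation_deg)
        c, s = math.cos(a), math.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return self.scale * points @ rot.T + np.asarray(self.translation_mm)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Latent parameter vectors are ordered as ``LATENT_NAMES``; sex offsets are
    added as ``offset * sex`` with males = +1 and females = -1.  Physique
    means/SDs are (male, female) pairs; stature follows the cohort summary of
    the source population (M 176.1 +/- 7.3 cm, F 164.0 +/- 7.0 cm).
    """

    n: int = 200
    latent_means: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0)
    latent_sds: tuple[float, ...] = (0.45, 0.55, 0.085, 1.0, 0.50)
    latent_sex_offsets: tuple[float, ...] = (0.0, 1.0, 0.0, 0.0, 0.0)
    measure_noise_sd_cm: float = 0.3
    point_noise_sd_mm: float = 1.0
    gap_fraction: float = 0.08
    points_per_slice: int = 110
    n_gen_slices: int = 280
    seed: int = 0
    height_mean_mm: tuple[float, float] = (1761.0, 1640.0)
    height_sd_mm: tuple[float, float] = (73.0, 70.0)
    base_radius_mean_mm: tuple[float, float] = (150.0, 144.0)
    base_radius_sd_mm: tuple[float, float] = (11.0, 12.0)
    pose_rotation_max_deg: float = 15.0
    pose_translation_max_mm: float = 50.0
    pose_scale_range: tuple[float, float] = (0.97, 1.03)

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size n must be >= 2")
        if len(self.latent_means) != 5 or len(self.latent_sds) != 5 \
                or len(self.latent_sex_offsets) != 5:
            raise ValueError("latent parameter vectors must have length 5")
        if any(sd < 0 for sd in self.latent_sds):
            raise ValueError("latent SDs must be >= 0")
        if self.measure_noise_sd_cm < 0 or self.point_noise_sd_mm < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.gap_fraction <= 0.25:
            raise ValueError("gap_fraction must lie in [0, 0.25]")
        if self.points_per_slice < 10 or self.n_gen_slices < 10:
            raise ValueError("need >= 10 generator slices and points per slice")

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TorsoGeometry:
    """Analytic description of one noise-free torso surface (pre-pose, mm)."""

    height_mm: float
    base_radius_mm: float
    buttock_height_mm: float
    neck_height_mm: float
    latents: LatentShape
    sex: int

    @property
    def xiphoid_height_mm(self) -> float:
        return self.buttock_height_mm + XIPHOID_FRACTION * (
            self.neck_height_mm - self.buttock_height_mm)

    @property
    def z_span(self) -> tuple[float, float]:
        return (self.buttock_height_mm - GEN_MARGIN_MM,
                self.xiphoid_height_mm + GEN_MARGIN_MM)

    def torso_u(self, z: np.ndarray) -> np.ndarray:
        return (np.asarray(z, dtype=float) - self.buttock_height_mm) / (
            self.xiphoid_height_mm - self.buttock_height_mm)

    def radius(self, theta, z):
        """Surface radius r(theta, z) about the torso axis, in mm."""
        r, _ = self.radius_and_derivative(theta, z)
        return r

    def radius_and_derivative(self, theta, z):
        """Radius and its analytic d/d(theta), for arc-length quadrature."""
        theta = np.asarray(theta, dtype=float)
        u = self.torso_u(z)
        lat = self.latents
        base = self.base_radius_mm * _base_profile(u) * (1.0 + lat.roundness)
        iso = base + lat.taper * TAPER_GAIN_MM * _g3(u)
        ap = (ANTERIOR_FULLNESS * base
              + lat.ap_weighting * AP_GAIN_MM * _g1(u)
              + lat.bulge * BULGE_GAIN_MM * _g2(u))
        r = iso * (1.0 - ECCENTRICITY * np.cos(2.0 * theta)) - ap * np.cos(theta)
        dr = iso * 2.0 * ECCENTRICITY * np.sin(2.0 * theta) + ap * np.sin(theta)
        return r, dr

    def lean_offset_y(self, z) -> np.ndarray:
        """Lateral shear displacement (mm) at height z; pivot at the xiphoid."""
        z = np.asarray(z, dtype=float)
        return self.latents.lean * LEAN_GAIN * (z - self.xiphoid_height_mm)


def _base_profile(u) -> np.ndarray:
    """Unitless base-radius profile along the segment: hips 1.04, waist 0.92."""
    u = np.asarray(u, dtype=float)
    return 1.04 - 0.12 * np.exp(-((u - 0.68) ** 2) / (2.0 * 0.18 ** 2))


def _g1(u) -> np.ndarray:
    """Anterior-posterior weighting envelope: broad mid-torso bump."""
    u = np.asarray(u, dtype=float)
    return np.exp(-((u - 0.45) ** 2) / (2.0 * 0.16 ** 2))


def _g2(u) -> np.ndarray:
    """Low-anterior bulge envelope: narrow bump above the hip."""
    u = np.asarray(u, dtype=float)
    return np.exp(-((u - 0.22) ** 2) / (2.0 * 0.10 ** 2))


def _g3(u) -> np.ndarray:
    """Taper envelope: -1 at the buttock end, +1 at the xiphoid end."""
    return np.clip(2.0 * np.asarray(u, dtype=float) - 1.0, -1.3, 1.3)


@dataclass(frozen=True)
class SyntheticSample:
    """One synthetic participant: cloud, ground truth and nuisance pose."""

    cloud: np.ndarray                 # (N, 3) mm, posed
    latents: LatentShape
    sex: int                          # -1 female, +1 male
    true_measures: dict[str, float]   # noise-free analytic measures (posed units)
    observed_measures: dict[str, float]  # with measurement noise added
    buttock_height: float             # mm, posed units
    neck_height: float                # mm, posed units
    applied_pose: PoseTransform
    geometry: TorsoGeometry           # pre-pose analytic surface


# --- measure definitions -----------------------------------------------------

_GIRTH_U = [0.0, 0.08, 0.16, 0.24, 0.32, 0.40, 0.50, 0.60, 0.68, 0.78, 0.90, 1.02]
_GIRTH_NAMES = [
    "hip_girth", "upper_hip_girth", "lower_abdomen_girth", "abdomen_girth",
    "navel_girth", "upper_abdomen_girth", "mid_torso_girth",
    "lower_waist_girth", "waist_girth", "lower_chest_girth", "chest_girth",
    "upper_chest_girth",
]
_WIDTH_U = [0.0, 0.15, 0.30, 0.45, 0.60, 0.75, 0.90, 1.02]
_WIDTH_NAMES = [
    "hip_width", "abdomen_width", "navel_width", "mid_torso_width",
    "waist_width", "lower_chest_width", "chest_width", "upper_chest_width",
]
_DEPTH_NAMES = [n.replace("_width", "_depth") for n in _WIDTH_NAMES]
_LENGTH_NAMES = [
    "torso_length", "neck_to_xiphoid_length", "neck_to_buttock_length",
    "hip_to_waist_length", "waist_to_xiphoid_length", "lower_torso_length",
]
MEASURE_NAMES = _GIRTH_NAMES + _WIDTH_NAMES + _DEPTH_NAMES + _LENGTH_NAMES
assert len(MEASURE_NAMES) == 34

_THETA_GRID = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)


def closed_outline_perimeter(radius_fn, n: int = 4096) -> float:
    """Arc length of a smooth closed polar curve r(theta).

    Uses a spectral derivative, so the quadrature converges exponentially
    for smooth outlines (circles, ellipses, torso sections).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.asarray(radius_fn(theta), dtype=float)
    c = np.fft.rfft(r)
    dr = np.fft.irfft(1j * np.arange(len(c)) * c, n)
    return float(np.sqrt(r * r + dr * dr).mean() * 2.0 * np.pi)


def _section_perimeter(geom: TorsoGeometry, z) -> np.ndarray:
    """Arc length of the cross-section outline(s) at height(s) z (mm)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))[:, None]
    r, dr = geom.radius_and_derivative(_THETA_GRID[None, :], z)
    return np.sqrt(r * r + dr * dr).mean(axis=1) * 2.0 * np.pi


def _section_extents(geom: TorsoGeometry, z) -> tuple[np.ndarray, np.ndarray]:
    """(depth, width) = x- and y-extents of section outlines at heights z."""
    z = np.atleast_1d(np.asarray(z, dtype=float))[:, None]
    r = geom.radius(_THETA_GRID[None, :], z)
    x = r * np.cos(_THETA_GRID[None, :])
    y = r * np.sin(_THETA_GRID[None, :])
    return x.max(axis=1) - x.min(axis=1), y.max(axis=1) - y.min(axis=1)


def _torso_volume_mm3(geom: TorsoGeometry) -> float:
    z = np.linspace(geom.buttock_height_mm, geom.xiphoid_height_mm, 101)
    r = geom.radius(_THETA_GRID[None, :], z[:, None])
    areas = 0.5 * np.mean(r * r, axis=1) * 2.0 * np.pi
    return float(np.trapezoid(areas, z))


def compute_true_measures(sample_or_geom, scale: float = None) -> dict[str, float]:
    """Analytic body measures from the noise-free surface.

    Girths are cross-section perimeters at named heights, widths/depths are
    y/x extents, lengths are landmark-height differences.  Values are in cm
    (weight in kg) and, for a :class:`SyntheticSample`, re-expressed in the
    posed (uniformly scaled) units.  Raises ``ValueError`` if a requested
    measure height falls outside the generated surface span.
    """
    if isinstance(sample_or_geom, SyntheticSample):
        geom = sample_or_geom.geometry
        k = sample_or_geom.applied_pose.scale if scale is None else scale
    else:
        geom = sample_or_geom
        k = 1.0 if scale is None else scale

    zb, zx = geom.buttock_height_mm, geom.xiphoid_height_mm
    seg = zx - zb
    lo, hi = geom.z_span
    out: dict[str, float] = {}
    girth_z = zb + np.asarray(_GIRTH_U) * seg
    width_z = zb + np.asarray(_WIDTH_U) * seg
    for z, names in ((girth_z, _GIRTH_NAMES), (width_z, _WIDTH_NAMES)):
        if z.min() < lo or z.max() > hi:
            bad = names[int(np.argmax((z < lo) | (z > hi)))]
            raise ValueError(f"measure height for {bad} outside torso range")
    for name, g in zip(_GIRTH_NAMES, _section_perimeter(geom, girth_z)):
        out[name] = float(g) * k / 10.0
    depths, widths = _section_extents(geom, width_z)
    for wname, dname, w, d in zip(_WIDTH_NAMES, _DEPTH_NAMES, widths, depths):
        out[wname] = float(w) * k / 10.0
        out[dname] = float(d) * k / 10.0
    neck = geom.neck_height_mm
    out["torso_length"] = seg * k / 10.0
    out["neck_to_xiphoid_length"] = (neck - zx) * k / 10.0
    out["neck_to_buttock_length"] = (neck - zb) * k / 10.0
    out["hip_to_waist_length"] = 0.68 * seg * k / 10.0
    out["waist_to_xiphoid_length"] = 0.32 * seg * k / 10.0
    out["lower_torso_length"] = 0.30 * seg * k / 10.0
    out["height"] = geom.height_mm * k / 10.0
    vol_m3 = _torso_volume_mm3(geom) * (k ** 3) * 1e-9
    out["weight"] = vol_m3 * TISSUE_DENSITY_KG_M3 / TORSO_MASS_SHARE
    assert all(v > 0 for v in out.values())
    return out


# --- cloud generation --------------------------------------------------------

def generate_torso_cloud(latents: LatentShape, sex: int, spec: CohortSpec,
                         seed: int, measures_only: bool = False
                         ) -> SyntheticSample:
    """Generate one posed, noisy torso point cloud with full ground truth.

    The same ``(latents, sex, spec, seed)`` always yields a bit-identical
    sample.  Physique (stature, base radius, landmark-height noise), pose,
    occlusion and point noise are drawn from ``seed``; the latent shape is
    taken as given.  With ``measures_only=True`` the point sampling is
    skipped (``cloud`` comes back empty) but physique, pose and all measures
    are identical to the full sample for the same seed.
    """
    spec.validate()
    if sex not in (-1, 1):
        raise ValueError("sex code must be -1 (female) or +1 (male)")
    rng = np.random.default_rng(seed)
    si = 0 if sex == 1 else 1

    height = spec.height_mean_mm[si] + spec.height_sd_mm[si] * rng.standard_normal()
    r0 = spec.base_radius_mean_mm[si] + spec.base_radius_sd_mm[si] * rng.standard_normal()
    r0 = max(r0, 80.0)
    buttock = BUTTOCK_HEIGHT_FRAC * height + LANDMARK_NOISE_SD_MM * rng.standard_normal()
    neck = NECK_HEIGHT_FRAC * height + LANDMARK_NOISE_SD_MM * rng.standard_normal()
    geom = TorsoGeometry(height_mm=height, base_radius_mm=r0,
                         buttock_height_mm=buttock, neck_height_mm=neck,
                         latents=latents, sex=sex)
    pose = PoseTransform(
        rotation_deg=rng.uniform(-spec.pose_rotation_max_deg,
                                 spec.pose_rotation_max_deg),
        translation_mm=tuple(rng.uniform(-spec.pose_translation_max_mm,
                                         spec.pose_translation_max_mm, size=3)),
        scale=rng.uniform(*spec.pose_scale_range),
    )
    k, tz = pose.scale, pose.translation_mm[2]
    true_meas = compute_true_measures(geom, scale=k)
    mnoise = spec.measure_noise_sd_cm * rng.standard_normal(len(MEASURE_NAMES))
    observed = dict(true_meas)
    for j, name in enumerate(MEASURE_NAMES):
        observed[name] = max(true_meas[name] + mnoise[j], 1e-3)

    if measures_only:
        cloud = np.empty((0, 3))
    else:
        lo, hi = geom.z_span
        nr, m = spec.n_gen_slices, spec.points_per_slice
        spacing = (hi - lo) / nr
        z_rings = lo + (np.arange(nr) + 0.5) * spacing
        # all rings share one angular grid: when a 2 mm band catches two
        # rings their points coincide in theta and the resampler averages
        # them, which keeps band content stable under small scale changes
        i = np.arange(m)
        theta = np.broadcast_to((2.0 * np.pi / m) * (i[None, :] + 0.5),
                                (nr, m))
        z = np.broadcast_to(z_rings[:, None], theta.shape)

        r = geom.radius(theta, z)
        x = r * np.cos(theta)
        y = r * np.sin(theta) + geom.lean_offset_y(z)

        # occlusion: contiguous angular arc deleted on two random bands
        keep = np.ones((nr, m), dtype=bool)
        occluded = rng.choice(nr, size=2, replace=False)
        starts = rng.uniform(0.0, 2.0 * np.pi, size=2)
        if spec.gap_fraction > 0.0:
            for b, s in zip(occluded, starts):
                frac = np.mod(theta[b] - s, 2.0 * np.pi)
                keep[b] &= frac >= spec.gap_fraction * 2.0 * np.pi

        pts = np.column_stack([x[keep], y[keep], z[keep]])
        if spec.point_noise_sd_mm > 0.0:
            pts = pts + spec.point_noise_sd_mm * rng.standard_normal(pts.shape)
        cloud = pose.apply(pts)

    return SyntheticSample(
        cloud=cloud, latents=latents, sex=sex, true_measures=true_meas,
        observed_measures=observed,
        buttock_height=k * buttock + tz, neck_height=k * neck + tz,
        applied_pose=pose, geometry=geom,
    )


def generate_cohort(spec: CohortSpec,
                    measures_only: bool = False) -> list[SyntheticSample]:
    """Draw a cohort of samples; sexes alternate (balanced to within 1).

    Latents are Normal with the configured means, SDs and additive
    ``offset * sex`` shifts; ``lean`` is drawn independently of physique and
    of every measure.  Same spec (incl. seed) reproduces the cohort exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.latent_means)
    sds = np.asarray(spec.latent_sds)
    offsets = np.asarray(spec.latent_sex_offsets)
    draws = means + sds * rng.standard_normal((spec.n, 5))
    seeds = rng.integers(0, 2 ** 31 - 1, size=spec.n)
    samples = []
    for idx in range(spec.n):
        sex = 1 if idx % 2 == 0 else -1
        vals = draws[idx] + offsets * sex
        vals[2] = max(vals[2], -0.6)  # keep the surface well away from collapse
        latents = LatentShape(*vals)
        samples.append(generate_torso_cloud(latents, sex, spec,
                                            int(seeds[idx]),
                                            measures_only=measures_only))
    return samples


def cohort_truth_table(samples: list[SyntheticSample]) -> pd.DataFrame:
    """Flat ground-truth table: one row per participant."""
    rows = []
    for idx, s in enumerate(samples):
        row = {"participant": idx, "sex": s.sex}
        for n in LATENT_NAMES:
            row[n] = getattr(s.latents, n)
        row.update({
            "buttock_height_mm": s.buttock_height,
            "neck_height_mm": s.neck_height,
            "pose_rotation_deg": s.applied_pose.rotation_deg,
            "pose_scale": s.applied_pose.scale,
        })
        row["height_cm"] = s.observed_measures["height"]
        row["weight_kg"] = s.observed_measures["weight"]
        for n in MEASURE_NAMES:
            row[n] = s.observed_measures[n]
        rows.append(row)
    return pd.DataFrame(rows)
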