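"""Spectral outline descriptors and the torso shape PCA.

Each scaled slice outline is converted to a polar radius function r(theta)
about the torso's frame axis, smoothed with a periodic cubic smoothing
spline, and resampled at 70 uniform angles.  A real FFT of the 70 radii
yields 35 non-DC harmonics; the harmonic "coefficient" used downstream is
the amplitude 2|c_m|/70, which is invariant to the outline's start angle
(phases are discarded).  The DC term — the residual per-slice mean radius —
is size rather than shape and is excluded; global size was already removed
by the joint centroid-size scaling.  Harmonics above 10 are treated as noise
and dropped, so a torso is described by 25 slices x 10 harmonics = 250
values.  A principal component analysis over these feature vectors, with
components below 1% explained variance omitted, gives the shape PC model.

The radial parameterisation is taken about the slice stack's common axis
(x = y = 0 in the anatomical frame) rather than each slice's own centroid:
a per-slice-centroid parameterisation is blind to per-slice translations and
would erase postural lean from the descriptor entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splrep

from .align import SliceProfile, TorsoSlices

N_ANGLES_DEFAULT = 70
N_HARMONICS_FULL = N_ANGLES_DEFAULT // 2          # 35
N_HARMONICS_KEPT = 10
N_SLICES = 25
FEATURE_LENGTH = N_SLICES * N_HARMONICS_KEPT      # 250
PCA_MIN_RATIO_DEFAULT = 0.01
MAX_ANGULAR_GAP_RAD = np.pi / 2.0


@dataclass(frozen=True)
class RadialProfile:
    slice_index: int
    radii: np.ndarray          # length n_angles, at theta_k = 2 pi k / n
    smoothing: float           # spline smoothing parameter actually used

    def __post_init__(self) -> None:
        r = np.asarray(self.radii)
        if not (np.all(np.isfinite(r)) and np.all(r > 0)):
            raise ValueError("radii must be finite and positive")


@dataclass(frozen=True)
class SliceSpectrum:
    amplitudes_full: np.ndarray    # harmonics 1..35
    amplitudes_kept: np.ndarray    # first 10

    def __post_init__(self) -> None:
        if len(self.amplitudes_full) != N_HARMONICS_FULL:
            raise ValueError("full spectrum must have 35 harmonics")


@dataclass(frozen=True)
class ShapePCModel:
    """Centred PCA over feature vectors with the >= 1% retention rule."""

    mean: np.ndarray                 # (250,)
    loadings: np.ndarray             # (retained, 250), orthonormal rows
    explained_ratio: np.ndarray      # retained ratios, non-increasing
    all_ratios: np.ndarray           # full spectrum of ratios
    scores: np.ndarray               # (participants, retained)

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[0]

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(features) - self.mean) @ self.loadings.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self.mean + np.atleast_2d(scores) @ self.loadings


def _difference_noise_variance(y: np.ndarray) -> float:
    """Noise-variance estimate from second differences of an ordered signal."""
    if len(y) < 3:
        return 0.0
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]
    return float(np.sum(d2 * d2) / (6.0 * len(d2)))


def resample_outline(profile: SliceProfile, n_angles: int = N_ANGLES_DEFAULT,
                     smoothing: float | None = None,
                     center: tuple[float, float] = (0.0, 0.0)
                     ) -> RadialProfile:
    """Fit a periodic cubic smoothing spline to r(theta) and resample it at
    ``n_angles`` uniform angles.

    ``center`` is the polar origin (default: the frame axis).  ``smoothing``
    is FITPACK's residual budget ``s``; by default it is set to
    n * sigma_hat^2 with sigma_hat estimated from second differences of the
    ordered radii.  Angular gaps larger than 90 degrees raise; radii that
    are multi-valued at a common angle are reduced to their median.
    """
    pts = profile.points - np.asarray(center, dtype=float)
    theta = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
    r = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(theta, kind="stable")
    theta, r = theta[order], r[order]

    # collapse angularly coincident samples (e.g. two raster rings flattened
    # into one band) to their median radius at the group-mean angle
    _COINCIDENT_RAD = 1e-3
    if np.any(np.diff(theta) < _COINCIDENT_RAD):
        starts = np.flatnonzero(
            np.concatenate([[True], np.diff(theta) >= _COINCIDENT_RAD]))
        ends = np.append(starts[1:], len(theta))
        counts = ends - starts
        merged_t = np.add.reduceat(theta, starts) / counts
        if counts.max() <= 2:
            # pairs: mean and median coincide
            merged_r = np.add.reduceat(r, starts) / counts
            hi = np.maximum.reduceat(r, starts)
            lo = np.minimum.reduceat(r, starts)
            spread = float((hi - lo).max())
        else:
            merged_r = np.array([np.median(r[s:e])
                                 for s, e in zip(starts, ends)])
            spread = max(float(r[s:e].max() - r[s:e].min())
                         for s, e in zip(starts, ends))
        if spread > 0.05 * float(np.median(r)):
            warnings.warn("outline multi-valued in theta (not star-shaped); "
                          "keeping median radius")
        theta, r = merged_t, merged_r

    gaps = np.diff(np.concatenate([theta, [theta[0] + 2.0 * np.pi]]))
    if gaps.max() > MAX_ANGULAR_GAP_RAD:
        raise ValueError("angular gap exceeds 90 degrees; outline too "
                         "occluded for spline interpolation")

    if smoothing is None:
        smoothing = len(r) * _difference_noise_variance(r)
    # periodic spline: FITPACK needs the first point repeated one period on
    theta_ext = np.concatenate([theta, [theta[0] + 2.0 * np.pi]])
    r_ext = np.concatenate([r, [r[0]]])
    with warnings.catch_warnings():
        # tiny residual budgets on noise-free outlines trip FITPACK's
        # "s too small" advisory; the interpolating fit it returns is fine
        warnings.filterwarnings("ignore", message=".*impossible result.*")
        tck = splrep(theta_ext, r_ext, k=3, s=smoothing, per=1)
    grid = 2.0 * np.pi * np.arange(n_angles) / n_angles
    radii = np.asarray(splev(np.mod(grid - theta[0], 2.0 * np.pi) + theta[0],
                             tck))
    return RadialProfile(slice_index=profile.slice_index, radii=radii,
                         smoothing=float(smoothing))


def harmonic_amplitudes(radial: RadialProfile,
                        keep: int = N_HARMONICS_KEPT) -> SliceSpectrum:
    """Harmonic amplitudes 2|c_m|/N for m = 1..N/2; the DC term is dropped."""
    r = np.asarray(radial.radii, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite radii")
    n = len(r)
    c = np.fft.rfft(r)
    amps = 2.0 * np.abs(c[1:n // 2 + 1]) / n
    return SliceSpectrum(amplitudes_full=amps, amplitudes_kept=amps[:keep])


def assemble_feature_vector(spectra) -> np.ndarray:
    """Concatenate 25 kept spectra (slice 0 -> 24) into the 250-vector."""
    spectra = list(spectra)
    if len(spectra) != N_SLICES:
        raise ValueError(f"expected {N_SLICES} slice spectra, got {len(spectra)}")
    vec = np.concatenate([s.amplitudes_kept for s in spectra])
    if len(vec) != FEATURE_LENGTH:
        raise ValueError("kept spectra do not assemble to length 250")
    return vec


def resampled_outline_points(radial: RadialProfile,
                             center: tuple[float, float] = (0.0, 0.0)
                             ) -> np.ndarray:
    """The (n_angles, 2) outline point configuration implied by a radial
    profile, in the slice plane."""
    grid = 2.0 * np.pi * np.arange(len(radial.radii)) / len(radial.radii)
    return np.column_stack([
        center[0] + radial.radii * np.cos(grid),
        center[1] + radial.radii * np.sin(grid)])


def joint_centroid_size_resampled(slices: TorsoSlices,
                                  n_angles: int = N_ANGLES_DEFAULT) -> float:
    """Joint centroid size of the pooled fixed-count (25 x n_angles)
    resampled outline configuration, each slice centred at its own
    centroid."""
    total = 0.0
    for p in slices.profiles:
        pts = resampled_outline_points(resample_outline(p, n_angles=n_angles))
        dev = pts - pts.mean(axis=0)
        total += float(np.sum(dev * dev))
    return float(np.sqrt(total))


def feature_vector_from_slices(slices: TorsoSlices,
                               n_angles: int = N_ANGLES_DEFAULT,
                               keep: int = N_HARMONICS_KEPT,
                               smoothing: float | None = None) -> np.ndarray:
    """Convenience: scaled slices -> resample -> FFT -> 250-vector."""
    spectra = []
    for p in slices.profiles:
        radial = resample_outline(p, n_angles=n_angles, smoothing=smoothing)
        spectra.append(harmonic_amplitudes(radial, keep=keep))
    return assemble_feature_vector(spectra)


def fit_shape_pca(features: np.ndarray,
                  min_ratio: float = PCA_MIN_RATIO_DEFAULT) -> ShapePCModel:
    """Centred PCA retaining the leading PCs with explained-variance ratio
    >= ``min_ratio`` (default 1%)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a (participants >= 10) x features matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc * Xc))
    if total_var <= 0.0:
        raise ValueError("zero total variance: all feature vectors identical")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ratios = (s * s) / np.sum(s * s)
    retained = int(np.searchsorted(-ratios, -min_ratio, side="right"))
    retained = max(retained, 1)
    loadings = vt[:retained]
    # deterministic sign convention: largest-magnitude loading entry positive
    for i in range(retained):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = Xc @ loadings.T
    return ShapePCModel(mean=mean, loadings=loadings,
                        explained_ratio=ratios[:retained],
                        all_ratios=ratios, scores=scores)


def reconstruct_outlines(model: ShapePCModel, scores: np.ndarray,
                         n_angles: int = N_ANGLES_DEFAULT,
                         reference_radius: float = 1.0) -> list[np.ndarray]:
    """Outlines r(theta) implied by a point in shape-PC space.

    The inverse map runs mean + scores . loadings -> 250 amplitudes, then a
    truncated cosine synthesis per slice with the DC term set to a common
    reference radius.  Phases were discarded in the descriptor, so each
    harmonic is reconstructed with zero phase; the result is a canonical
    representative of the shape class.  Returns 25 radius arrays.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) != model.n_retained:
        raise ValueError("score vector length must equal retained PC count")
    feats = model.inverse_transform(scores).ravel()
    grid = 2.0 * np.pi * np.arange(n_angles) / n_angles
    outlines = []
    for s in range(N_SLICES):
        amps = feats[s * N_HARMONICS_KEPT:(s + 1) * N_HARMONICS_KEPT]
        r = np.full(n_angles, float(reference_radius))
        for m, a in enumerate(amps, start=1):
            r = r + a * np.cos(m * grid)
        outlines.append(r)
    return outlines
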