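"""Spectral descriptors: spline resampling, harmonic amplitudes, shape PCA."""

import numpy as np
import pytest

from torsoshape import descriptors
from torsoshape.align import SliceProfile, _order_outline
from torsoshape.descriptors import (FEATURE_LENGTH, N_HARMONICS_FULL,
                                    RadialProfile, SliceSpectrum,
                                    assemble_feature_vector, fit_shape_pca,
                                    harmonic_amplitudes, reconstruct_outlines,
                                    resample_outline)


def profile_from_radius(radius_fn, n=200, start=0.0):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + start
    r = radius_fn(th)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return SliceProfile(slice_index=0, z_level=0.0, points=_order_outline(pts))


def radial(values):
    return RadialProfile(slice_index=0, radii=np.asarray(values, float),
                         smoothing=0.0)


class TestResampleOutline:
    def test_circle_resampled_exactly(self):
        prof = profile_from_radius(lambda th: np.full_like(th, 5.0))
        out = resample_outline(prof)
        assert len(out.radii) == 70
        assert np.allclose(out.radii, 5.0, atol=1e-6)

    def test_circle_with_30_degree_gap_interpolated(self):
        th = np.linspace(np.radians(30.0), 2.0 * np.pi, 180, endpoint=False)
        pts = np.column_stack([5.0 * np.cos(th), 5.0 * np.sin(th)])
        prof = SliceProfile(slice_index=0, z_level=0.0,
                            points=_order_outline(pts))
        out = resample_outline(prof)
        assert np.all(np.abs(out.radii - 5.0) < 0.05)

    def test_custom_angle_count(self):
        prof = profile_from_radius(lambda th: np.full_like(th, 5.0))
        assert len(resample_outline(prof, n_angles=32).radii) == 32

    def test_large_gap_raises(self):
        th = np.linspace(np.radians(100.0), 2.0 * np.pi, 120, endpoint=False)
        pts = np.column_stack([5.0 * np.cos(th), 5.0 * np.sin(th)])
        prof = SliceProfile(slice_index=0, z_level=0.0,
                            points=_order_outline(pts))
        with pytest.raises(ValueError, match="gap"):
            resample_outline(prof)

    def test_smoothing_suppresses_noise(self):
        rng = np.random.default_rng(3)
        prof = profile_from_radius(
            lambda th: 140.0 + 3.0 * np.cos(2 * th) + rng.normal(0, 1.0, len(th)))
        out = resample_outline(prof)
        ref = 140.0 + 3.0 * np.cos(2 * np.pi * 2 * np.arange(70) / 70)
        assert np.std(out.radii - ref) < 1.0  # below the raw noise level


class TestHarmonicAmplitudes:
    def test_constant_radius_all_zero(self):
        spec = harmonic_amplitudes(radial(np.full(70, 7.0)))
        assert np.allclose(spec.amplitudes_full, 0.0, atol=1e-12)
        assert np.allclose(spec.amplitudes_kept, 0.0, atol=1e-12)

    def test_pure_cosine_closed_form(self):
        th = 2.0 * np.pi * np.arange(70) / 70
        spec = harmonic_amplitudes(radial(5.0 + np.cos(2.0 * th)))
        assert spec.amplitudes_full[1] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(spec.amplitudes_full, 1)
        assert np.all(others < 1e-9)

    def test_full_35_kept_10(self):
        spec = harmonic_amplitudes(radial(np.linspace(5.0, 6.0, 70)))
        assert len(spec.amplitudes_full) == N_HARMONICS_FULL == 35
        assert len(spec.amplitudes_kept) == 10
        assert np.array_equal(spec.amplitudes_kept, spec.amplitudes_full[:10])

    def test_start_angle_invariance(self):
        rng = np.random.default_rng(0)
        r = 100.0 + rng.normal(0, 2.0, 70)
        a = harmonic_amplitudes(radial(r)).amplitudes_full
        b = harmonic_amplitudes(radial(np.roll(r, 17))).amplitudes_full
        assert np.allclose(a, b, atol=1e-9)

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(1)
        th = 2.0 * np.pi * np.arange(70) / 70
        r = np.full(70, 50.0)
        for m in range(1, 35):  # band-limited below the Nyquist harmonic
            r = r + rng.normal() * np.cos(m * th) + rng.normal() * np.sin(m * th)
        amps = harmonic_amplitudes(radial(r)).amplitudes_full
        energy = 2.0 / 70 * np.sum((r - r.mean()) ** 2)
        assert np.sum(amps ** 2) == pytest.approx(energy, rel=1e-9)

    def test_nonfinite_radii_rejected(self):
        with pytest.raises(ValueError):
            RadialProfile(slice_index=0, radii=np.full(70, np.nan),
                          smoothing=0.0)


class TestAssembleFeatureVector:
    def _spectra(self, k=25):
        th = 2.0 * np.pi * np.arange(70) / 70
        return [harmonic_amplitudes(radial(10.0 + np.cos(th)))
                for _ in range(k)]

    def test_length_250(self):
        assert len(assemble_feature_vector(self._spectra())) == FEATURE_LENGTH

    def test_wrong_slice_count_raises(self):
        with pytest.raises(ValueError):
            assemble_feature_vector(self._spectra(24))

    def test_zero_spectra_give_zero_vector(self):
        zero = [harmonic_amplitudes(radial(np.full(70, 3.0)))
                for _ in range(25)]
        assert np.allclose(assemble_feature_vector(zero), 0.0, atol=1e-12)


class TestShapePCA:
    def _single_mode_data(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        loading = rng.normal(size=250)
        loading /= np.linalg.norm(loading)
        latent = rng.normal(size=n)
        X = 5.0 + np.outer(latent, loading) + rng.normal(0, 1e-4, (n, 250))
        return X, latent

    def test_single_mode_recovered(self):
        X, latent = self._single_mode_data()
        model = fit_shape_pca(X)
        assert model.n_retained == 1
        corr = np.corrcoef(model.scores[:, 0], latent)[0, 1]
        assert abs(corr) >= 0.99

    def test_ratios_non_increasing_and_retained_above_threshold(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 250)) * np.linspace(3, 0.01, 250)
        model = fit_shape_pca(X)
        assert np.all(np.diff(model.all_ratios) <= 1e-12)
        assert np.all(model.explained_ratio >= 0.01)
        assert model.all_ratios[model.n_retained] < 0.01

    def test_identical_rows_raise(self):
        with pytest.raises(ValueError, match="variance"):
            fit_shape_pca(np.ones((20, 250)))

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 250)) * np.linspace(2, 0.5, 250)
        model = fit_shape_pca(X, min_ratio=0.001)
        G = model.loadings @ model.loadings.T
        assert np.allclose(G, np.eye(model.n_retained), atol=1e-9)


class TestReconstruction:
    def test_zero_scores_give_mean_outlines(self):
        X, _ = TestShapePCA()._single_mode_data()
        model = fit_shape_pca(X)
        outlines = reconstruct_outlines(model, np.zeros(model.n_retained),
                                        reference_radius=10.0)
        assert len(outlines) == 25
        feats = model.inverse_transform(np.zeros(model.n_retained)).ravel()
        grid = 2.0 * np.pi * np.arange(70) / 70
        expected = 10.0 + sum(feats[m - 1] * np.cos(m * grid)
                              for m in range(1, 11))
        assert np.allclose(outlines[0], expected, atol=1e-12)

    def test_full_rank_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 250))
        model = fit_shape_pca(X, min_ratio=0.0)
        back = model.inverse_transform(model.transform(X))
        assert np.allclose(back, X, atol=1e-9)

    def test_truncation_error_bounded_by_discarded_variance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 250)) * np.linspace(3, 0.01, 250)
        model = fit_shape_pca(X)
        back = model.inverse_transform(model.transform(X))
        err = np.sum((X - back) ** 2)
        total = np.sum((X - X.mean(axis=0)) ** 2)
        discarded = 1.0 - model.explained_ratio.sum()
        assert err <= discarded * total * (1.0 + 1e-9)

    def test_score_length_mismatch_raises(self):
        X, _ = TestShapePCA()._single_mode_data()
        model = fit_shape_pca(X)
        with pytest.raises(ValueError):
            reconstruct_outlines(model, np.zeros(model.n_retained + 1))
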