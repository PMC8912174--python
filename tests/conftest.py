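import numpy as np
import pytest

from torsoshape import pipeline, synth


@pytest.fixture(scope="session")
def small_cohort():
    """Thirty full synthetic participants (clouds + ground truth)."""
    spec = synth.CohortSpec(n=30, seed=42)
    return spec, synth.generate_cohort(spec)


@pytest.fixture(scope="session")
def measures_cohort():
    """Two thousand participants, analytic measures only (no clouds)."""
    spec = synth.CohortSpec(n=2000, seed=314)
    samples = synth.generate_cohort(spec, measures_only=True)
    return spec, synth.cohort_truth_table(samples)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, un-posed, gap-free study conditions."""
    return synth.CohortSpec(
        n=4, seed=3, point_noise_sd_mm=0.0, gap_fraction=0.0,
        measure_noise_sd_cm=0.0, pose_rotation_max_deg=0.0,
        pose_translation_max_mm=0.0, pose_scale_range=(1.0, 1.0))


@pytest.fixture()
def default_config():
    return pipeline.PipelineConfig(cohort=synth.CohortSpec(n=30, seed=42))


def ring_cloud(radius=150.0, z_levels=(0.0, 2.0, 4.0), n=72):
    """Plain stacked-ring cylinder cloud for brute-force oracles."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + 0.013
    rings = [np.column_stack([radius * np.cos(th), radius * np.sin(th),
                              np.full(n, z)]) for z in z_levels]
    return np.vstack(rings)
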