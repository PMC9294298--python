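import numpy as np
import pytest

from capfreq import (
    BANDS,
    SimulationConfig,
    simulate_cohort,
    zscore_rois,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort for unit-level checks."""
    return SimulationConfig(
        n_roi=60,
        n_states=6,
        n_frames=120,
        n_subjects_per_group=6,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort (20+20 subjects, 235 frames, 408 ROIs)."""
    return simulate_cohort(SimulationConfig(master_seed=11))


@pytest.fixture(scope="session")
def default_cohort_zscored(default_cohort):
    ts_set, meta, truth = default_cohort
    return {s: zscore_rois(ts) for s, ts in ts_set.items()}, meta, truth


@pytest.fixture(scope="session")
def separable_frames():
    """Frames drawn exactly from 6 orthogonal templates, no noise."""
    rng = np.random.default_rng(3)
    K, R = 6, 48
    templates = np.zeros((K, R))
    for k in range(K):
        templates[k, k * 8 : (k + 1) * 8] = 1.0 + 0.2 * rng.standard_normal(8)
        templates[k] -= templates[k].mean()
    labels = np.repeat(np.arange(1, K + 1), 20)
    # per-frame constant offset: breaks the zero within-state SD without
    # touching frame-template correlations (constants cancel in Pearson r)
    jitter = 1e-3 * rng.standard_normal((labels.size, 1)) * np.ones((1, R))
    return templates, labels, templates[labels - 1] + jitter
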