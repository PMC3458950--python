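import warnings

import numpy as np
import pytest

import normcoh as nc


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on test order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small fast cohort (6 per group, T = 120) for smoke-level tests."""
    spec = nc.CohortSpec(n_per_group=6, T=120, seed=11)
    manifest, series = nc.generate_cohort(spec)
    return spec, manifest, series


@pytest.fixture(scope="session")
def contrast_cohort_features():
    """Coherence features of the canonical single-band contrast cohort.

    Session-scoped because feature extraction fits 42 VAR models; several
    anomaly/relevance tests reuse the same matrices.
    """
    spec = nc.single_band_contrast(seed=0)
    manifest, series = nc.generate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features, orders, _ = nc.pipeline.extract_features(
            manifest, nc.PipelineConfig(), series
        )
    X = features.iloc[:, 1:].to_numpy()
    groups = manifest["group"].to_numpy()
    return X[groups == "case"], X[groups == "control"]
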