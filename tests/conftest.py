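import numpy as np
import pytest

import mmrisk


def small_spec(**overrides) -> mmrisk.CohortSpec:
    base = dict(
        n_patients=48,
        n_lab_features=8,
        n_series_variables=3,
        series_duration_hours=24.0,
        ecg_tokens=3,
        ecg_dim=6,
        note_tokens=3,
        note_dim=6,
        seed=123,
    )
    base.update(overrides)
    return mmrisk.CohortSpec(**base)


def small_model_config(spec: mmrisk.CohortSpec, n_grid: int = 6, **overrides):
    return mmrisk.ModelConfig.small(
        lab_dim=spec.n_lab_features,
        series_dim=spec.n_series_variables,
        n_grid=n_grid,
        ecg_dim=spec.ecg_dim,
        note_dim=spec.note_dim,
        **overrides,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """A preprocessed toy cohort shared by model-level tests."""
    spec = small_spec()
    records = mmrisk.generate_cohort(spec)
    mmrisk.preprocess_cohort(
        records,
        mmrisk.PreprocessConfig(
            n_grid=6,
            imputation=mmrisk.ImputationConfig(n_chains=2, n_iterations=2, seed=0),
        ),
    )
    return spec, records


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    spec, _ = tiny_cohort
    return mmrisk.LatentFusionClassifier(small_model_config(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
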