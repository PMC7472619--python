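import numpy as np
import pytest

from squatval import simulate as S


@pytest.fixture(scope="session")
def noise_free_spec() -> S.PopulationSpec:
    return S.PopulationSpec(n_subjects=1, n_trials=1, seed=7).noise_free()


@pytest.fixture(scope="session")
def noise_free_trial(noise_free_spec) -> S.SyntheticTrial:
    """One noise-free trial with Table-scale multi-plane peaks."""
    return next(S.iter_trials(noise_free_spec))


@pytest.fixture(scope="session")
def sagittal_trial() -> S.SyntheticTrial:
    """Noise-free trial with a pure sagittal squat, knee peak 75 deg."""
    spec = S.PopulationSpec(n_subjects=1, n_trials=1, seed=1).noise_free()
    peaks = {v: 0.0 for v in S.VARIABLES}
    peaks.update(knee_flexion=75.0, hip_flexion=60.0, spine_flexion=15.0)
    return S.make_trial(peaks, spec, S.BodyModel(), np.random.SeedSequence(1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
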