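import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elstm.cohort import preprocess
from elstm.ensemble import EnsembleConfig, train_ensemble
from elstm.evaluate import stratified_split
from elstm.nn import TrainSettings
from elstm.synthetic import SyntheticConfig, generate_cohort, worked_fixture

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def fixture_cohort():
    """The hand-written 6-patient, D=2, T=3 cohort (γ = 2)."""
    return worked_fixture()


def tiny_train_settings(**overrides):
    base = dict(hidden_units=4, dropout_rate=0.0, learning_rate=0.05,
                max_epochs=15, early_stop=False)
    base.update(overrides)
    return TrainSettings(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable synthetic cohort for fast end-to-end tests."""
    config = SyntheticConfig(n_patients=120, D=6, T=5, imbalance_ratio=3.0,
                             n_informative=3, effect_size=0.8,
                             missing_rate=0.05, seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    rng = np.random.default_rng(5)
    train_idx, test_idx = stratified_split(small_cohort.labels, 0.25, rng)
    cohorts, stats = preprocess(
        small_cohort.subset(train_idx), small_cohort.subset(test_idx)
    )
    return cohorts[0], cohorts[1], stats


@pytest.fixture(scope="session")
def small_model(small_split):
    """A 5-learner ensemble trained on the small cohort."""
    train, _, stats = small_split
    config = EnsembleConfig(n_learners=5, subset_size=3,
                            train_settings=tiny_train_settings(),
                            master_seed=7)
    return train_ensemble(train, config, stats=stats)
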