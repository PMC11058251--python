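import numpy as np
import pytest

from somnoscore.cnn import CNNTrainingConfig
from somnoscore.io import epoch_record
from somnoscore.manipulation import ManipulationSet
from somnoscore.sequence import BiLSTMConfig
from somnoscore.synthetic import SyntheticCohortConfig, generate_cohort
from somnoscore.training import ExperimentConfig, train_separated


def tiny_experiment_config(seed=0, combo=None, weighted=True,
                           mode="separated"):
    """One-pass training configs: structure checks, not quality."""
    return ExperimentConfig(
        combo=combo or list(ManipulationSet), weighted=weighted,
        training_mode=mode, seed=seed,
        cnn_config=CNNTrainingConfig(max_training_epochs=1,
                                     validation_interval=2),
        bilstm_config=BiLSTMConfig(hidden_units=16, max_training_epochs=2,
                                   validation_interval=2))


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects x 100 epochs: enough structure for pipeline tests."""
    cfg = SyntheticCohortConfig(n_subjects=6, epochs_per_record=100, seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return [epoch_record(rec, hyp) for rec, hyp in small_cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_records():
    cfg = SyntheticCohortConfig(n_subjects=4, epochs_per_record=60, seed=8)
    return [epoch_record(r, h) for r, h in generate_cohort(cfg)]


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_records):
    """A structurally complete (briefly trained) 15-CNN + BiLSTM ensemble."""
    return train_separated(tiny_records, tiny_experiment_config())
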