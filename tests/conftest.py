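import numpy as np
import pytest

from specqc import (
    ModelSpec,
    NetworkModel,
    SimulationConfig,
    TrainConfig,
    generate_cohort,
    make_split_plan,
    preprocess_dataset,
    train_network,
)


@pytest.fixture(scope="session")
def sep_cohort():
    """Cleanly separable ND-style cohort: 12 subjects (3 per tag) x 100 voxels."""
    return generate_cohort(
        SimulationConfig(
            n_subjects=12, voxels_per_subject=100,
            severity_separation=1.0, rater_noise=0.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def pp_sep(sep_cohort):
    return preprocess_dataset(sep_cohort)


@pytest.fixture(scope="session")
def sep_fold(pp_sep):
    """(train, val, test) datasets for the first rotating fold."""
    plan = make_split_plan(pp_sep, "ND_rotating", seed=1, n_repeats=3)
    tr, va, te = plan.folds[0]
    return pp_sep.subset_subjects(tr), pp_sep.subset_subjects(va), pp_sep.subset_subjects(te)


@pytest.fixture(scope="session")
def trained_cnn(sep_fold):
    """A CNN trained briefly on separable data; good enough for inference,
    feature-extraction, and attribution contracts."""
    train_ds, val_ds, _ = sep_fold
    net = NetworkModel(ModelSpec(kind="CNN"), seed=0)
    net, _curves = train_network(net, train_ds, val_ds, TrainConfig(epochs=3, seed=0))
    return net


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small mixed cohort for I/O and CLI paths."""
    return generate_cohort(SimulationConfig(n_subjects=4, voxels_per_subject=20, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
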