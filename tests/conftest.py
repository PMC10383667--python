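import pytest

from ibdsig import CONTROL_VS_IBD, SimulationConfig, encode_labels, generate_study, split_train_test


@pytest.fixture(scope="session")
def small_planted():
    """A small study with 8 planted genes separating control vs IBD."""
    cfg = SimulationConfig(n_samples=120, n_genes=80, n_informative=8,
                           effect_size=2.0, seed=11)
    study, truth = generate_study(cfg)
    return study, truth


@pytest.fixture(scope="session")
def small_task(small_planted):
    """Train/test matrices for the control-vs-IBD task on the small study."""
    study, truth = small_planted
    y, kept = encode_labels(study, CONTROL_VS_IBD)
    split = split_train_test(study, kept, seed=4)
    pos = {k: i for i, k in enumerate(kept)}
    return dict(
        study=study,
        truth=truth,
        split=split,
        X_train=study.expression[:, split.train],
        X_test=study.expression[:, split.test],
        y_train=y[[pos[i] for i in split.train]],
        y_test=y[[pos[i] for i in split.test]],
    )


@pytest.fixture(scope="session")
def separable_task():
    """Strongly separated two-class data (effect 5): every sane classifier
    should be nearly perfect."""
    cfg = SimulationConfig(n_samples=200, n_genes=20, n_informative=20,
                           effect_size=5.0, class_proportions=(0.5, 0.25, 0.25),
                           seed=7)
    study, truth = generate_study(cfg)
    y, kept = encode_labels(study, CONTROL_VS_IBD)
    split = split_train_test(study, kept, seed=7)
    pos = {k: i for i, k in enumerate(kept)}
    return dict(
        study=study,
        X_train=study.expression[:, split.train],
        X_test=study.expression[:, split.test],
        y_train=y[[pos[i] for i in split.train]],
        y_test=y[[pos[i] for i in split.test]],
    )
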