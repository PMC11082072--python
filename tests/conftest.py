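"""Shared fixtures: synthetic corpora and small trained models.

Training fixtures are session-scoped; tests that mutate a model must
copy it first.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pepclr import (
    EncoderConfig,
    LossWeights,
    TrainConfig,
    build_dual_model,
    split_train_val,
    train,
)
from pepclr.simulate import SignalSpec, generate_labeled_peptides

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Compact encoder used by tests: same structure as the package default,
#: sized for fast CPU runs (peptides here are <= 50 residues, so 52
#: token slots cover single mode with the start token).
SMALL = dict(embed_dim=32, hidden_dim=64, n_layers=1, n_heads=4,
             proj_dim=32, max_len=52)


def small_config(arch: str, **kw) -> EncoderConfig:
    return EncoderConfig(architecture=arch, **{**SMALL, **kw})


@pytest.fixture(scope="session")
def default_corpus():
    train_ds, _ = generate_labeled_peptides(400, SignalSpec(), seed=11)
    test_ds, _ = generate_labeled_peptides(100, SignalSpec(), seed=12)
    return train_ds, test_ds


@pytest.fixture(scope="session")
def tiny_corpus():
    train_ds, _ = generate_labeled_peptides(120, SignalSpec(), seed=21)
    test_ds, _ = generate_labeled_peptides(60, SignalSpec(), seed=22)
    return train_ds, test_ds


def _train_small(arch: str, corpus, epochs: int = 8, seed: int = 0,
                 alpha: float = 0.1):
    train_ds, _ = corpus
    config = TrainConfig(
        epochs=epochs, seed=seed, model=small_config(arch),
        weights=LossWeights(alpha=alpha, beta=0.5, tau=0.2),
    )
    tr, val = split_train_val(train_ds, 0.1, seed)
    model = build_dual_model(config.model, seed)
    record = train(model, tr, val, config)
    return model, record


@pytest.fixture(scope="session")
def trained_cnn(tiny_corpus):
    return _train_small("cnn", tiny_corpus)


@pytest.fixture(scope="session")
def trained_transformer(tiny_corpus):
    return _train_small("transformer", tiny_corpus, epochs=6)
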