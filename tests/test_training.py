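"""Splitting, the optimization loop, grid search, and model selection."""

import numpy as np
import pytest

from pepclr import (
    GridSpec,
    LossWeights,
    TrainConfig,
    build_dual_model,
    evaluate_model,
    forward_pass,
    mixed_cross_entropy,
    split_train_val,
    tokenize_dataset,
    train,
)
from pepclr.metrics import ConfusionCounts, MetricsReport
from pepclr.nn import Adam
from pepclr.simulate import SignalSpec, generate_labeled_peptides
from pepclr.training import RunRecord, grid_search, paired_comparison, select_best

from conftest import small_config


# -- split ---------------------------------------------------------------------

def test_split_sizes_follow_the_ten_percent_rule():
    ds, _ = generate_labeled_peptides(200, SignalSpec(), seed=1)
    tr, val = split_train_val(ds, 0.1, seed=0)
    assert len(val) == 20 and len(tr) == 180


def test_split_is_seed_deterministic_and_a_partition():
    ds, _ = generate_labeled_peptides(97, SignalSpec(), seed=2)
    tr1, val1 = split_train_val(ds, 0.1, seed=5)
    tr2, val2 = split_train_val(ds, 0.1, seed=5)
    assert [r.id for r in tr1] == [r.id for r in tr2]
    assert [r.id for r in val1] == [r.id for r in val2]
    ids = {r.id for r in tr1} | {r.id for r in val1}
    assert ids == {r.id for r in ds}
    assert not {r.id for r in tr1} & {r.id for r in val1}
    tr3, val3 = split_train_val(ds, 0.1, seed=6)
    assert [r.id for r in val3] != [r.id for r in val1]


def test_split_is_stratified():
    ds, _ = generate_labeled_peptides(200, SignalSpec(), seed=3)
    _, val = split_train_val(ds, 0.1, seed=0)
    labels = [r.label for r in val]
    assert 0.3 <= np.mean(labels) <= 0.7


def test_split_validation_errors():
    ds, _ = generate_labeled_peptides(10, SignalSpec(), seed=4)
    with pytest.raises(ValueError, match="val_fraction"):
        split_train_val(ds, 1.5, seed=0)
    with pytest.raises(ValueError, match="val_fraction"):
        split_train_val(ds, 0.0, seed=0)


# -- training loop ---------------------------------------------------------------

@pytest.fixture(scope="module")
def small_sets():
    ds, _ = generate_labeled_peptides(80, SignalSpec(), seed=31)
    return split_train_val(ds, 0.1, seed=0)


def test_alpha_zero_step_equals_ce_only_step(small_sets):
    """The α=0 objective must reproduce a pure cross-entropy update."""
    tr, val = small_sets
    config = TrainConfig(epochs=1, batch_size=len(tr), seed=0,
                         model=small_config("cnn", dropout=0.0),
                         weights=LossWeights(alpha=0.0, beta=0.5, tau=0.2))
    model_a = build_dual_model(config.model, 0)
    model_b = model_a.copy()
    train(model_a, tr, val, config)

    # independent CE-only step: same batch order, plain mixed CE, fresh Adam
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(tr))
    b1 = tokenize_dataset([tr.sequences[i] for i in order], model_b.vocab_1, 52)
    b2 = tokenize_dataset([tr.sequences[i] for i in order], model_b.vocab_2, 52)
    labels = np.asarray(tr.labels)[order]
    model_b.set_training(True)
    out = forward_pass(model_b, b1, b2)
    loss = mixed_cross_entropy(labels, out.probs_1, out.probs_2, 0.5,
                               reduction="mean")
    opt = Adam(model_b.parameters(), lr=config.learning_rate)
    opt.zero_grad()
    loss.backward()
    opt.step()

    for pa, pb in zip(model_a.parameters(), model_b.parameters()):
        assert np.abs(pa.data - pb.data).max() < 1e-7


def test_history_records_the_loss_identity(small_sets):
    tr, val = small_sets
    config = TrainConfig(epochs=3, batch_size=16, seed=1,
                         model=small_config("cnn"),
                         weights=LossWeights(alpha=0.3, beta=0.5, tau=0.2))
    model = build_dual_model(config.model, 1)
    record = train(model, tr, val, config)
    assert len(record.history) == 3
    for entry in record.history:
        blended = 0.7 * entry["l_ce"] + 0.3 * entry["l_cl"]
        assert entry["l_final"] == pytest.approx(blended, abs=1e-6)


def test_training_is_reproducible(small_sets):
    tr, val = small_sets
    config = TrainConfig(epochs=2, batch_size=16, seed=2,
                         model=small_config("cnn"),
                         weights=LossWeights(alpha=0.1, beta=0.5, tau=0.2))
    hashes = []
    for _ in range(2):
        model = build_dual_model(config.model, 2)
        train(model, tr, val, config)
        hashes.append(model.parameter_hash())
    assert hashes[0] == hashes[1]


def test_learnable_signal_reaches_high_training_accuracy():
    """Seed-averaged training accuracy on the separable default signal."""
    ds, _ = generate_labeled_peptides(200, SignalSpec(), seed=41)
    accs = []
    for seed in (0, 1, 2):
        tr, val = split_train_val(ds, 0.1, seed)
        config = TrainConfig(epochs=20, batch_size=32, seed=seed,
                             model=small_config("cnn"),
                             weights=LossWeights(alpha=0.0, beta=0.5, tau=0.2))
        model = build_dual_model(config.model, seed)
        train(model, tr, val, config)
        accs.append(evaluate_model(model, tr, classifier=1).accuracy)
    assert np.mean(accs) >= 0.95


def test_training_input_validation(small_sets):
    tr, val = small_sets
    config = TrainConfig(epochs=1, model=small_config("cnn"))
    from pepclr.records import PeptideDataset, PeptideRecord
    unlabeled = PeptideDataset([PeptideRecord(id="u", sequence="KWKL")])
    model = build_dual_model(config.model, 0)
    with pytest.raises(ValueError, match="labeled"):
        train(model, unlabeled, val, config)
    with pytest.raises(ValueError, match="empty"):
        train(model, PeptideDataset([]), val, config)


# -- grid search -------------------------------------------------------------------

@pytest.fixture(scope="module")
def mini_grid_records(tmp_path_factory):
    train_ds, _ = generate_labeled_peptides(60, SignalSpec(), seed=51)
    test_ds, _ = generate_labeled_peptides(30, SignalSpec(), seed=52)
    grid = GridSpec(alphas=(0.0, 0.5), betas=(0.5,), taus=(0.2,),
                    seeds=(0, 1), architectures=("cnn",))
    base = TrainConfig(epochs=2, batch_size=32, model=small_config("cnn"))
    ledger = tmp_path_factory.mktemp("ledger")
    records = grid_search(train_ds, test_ds, grid, base, ledger_dir=ledger)
    return train_ds, test_ds, grid, base, ledger, records


def test_grid_is_the_cartesian_product(mini_grid_records):
    *_, records = mini_grid_records
    assert len(records) == 4
    combos = {(r.config.weights.alpha, r.config.seed) for r in records}
    assert combos == {(0.0, 0), (0.0, 1), (0.5, 0), (0.5, 1)}


def test_same_seed_points_share_initial_weights(mini_grid_records):
    *_, records = mini_grid_records
    by_seed = {}
    for r in records:
        by_seed.setdefault(r.config.seed, set()).add(r.initial_param_hash)
    for seed, hashes in by_seed.items():
        assert len(hashes) == 1, f"seed {seed} has diverging initial weights"
    assert by_seed[0] != by_seed[1]


def test_grid_ledger_is_resumable(mini_grid_records, monkeypatch):
    train_ds, test_ds, grid, base, ledger, records = mini_grid_records

    def fail_train(*args, **kwargs):
        raise AssertionError("completed grid must not retrain")

    monkeypatch.setattr("pepclr.training.train", fail_train)
    reloaded = grid_search(train_ds, test_ds, grid, base, ledger_dir=ledger)
    assert len(reloaded) == len(records)
    assert [r.config.to_dict() for r in reloaded] == \
           [r.config.to_dict() for r in records]
    for a, b in zip(reloaded, records):
        assert a.test_metrics[1].mcc == pytest.approx(b.test_metrics[1].mcc)


def test_paired_comparison_rows(mini_grid_records):
    *_, records = mini_grid_records
    rows = paired_comparison(records, classifier=1, on="test")
    assert len(rows) == 2  # one contrastive point per seed
    for row in rows:
        assert row["same_init"] is True
        assert row["alpha"] == 0.5


# -- selection ---------------------------------------------------------------------

def _record(mcc, accuracy=0.8, alpha=0.5, seed=0, with_test=True):
    metrics = {1: MetricsReport(accuracy=accuracy, sensitivity=0.8,
                                specificity=0.8, mcc=mcc,
                                counts=ConfusionCounts(4, 4, 1, 1))}
    config = TrainConfig(seed=seed, model=small_config("cnn"),
                         weights=LossWeights(alpha=alpha, beta=0.5, tau=0.2))
    return RunRecord(config=config, history=[],
                     val_metrics=metrics,
                     test_metrics=metrics if with_test else {})


def test_select_best_argmax_and_tiebreaks():
    records = [_record(0.5), _record(0.7), _record(0.6)]
    best, head = select_best(records, classifier=1, on="validation")
    assert best.val_metrics[1].mcc == 0.7 and head == 1

    tie = [_record(0.7, accuracy=0.80), _record(0.7, accuracy=0.85)]
    best, _ = select_best(tie, classifier=1, on="validation")
    assert best.val_metrics[1].accuracy == 0.85

    alpha_tie = [_record(0.7, alpha=0.9), _record(0.7, alpha=0.1)]
    best, _ = select_best(alpha_tie, classifier=1, on="validation")
    assert best.config.weights.alpha == 0.1


def test_select_on_validation_never_touches_test_metrics():
    records = [_record(0.6, with_test=False)]
    best, _ = select_best(records, classifier=1, on="validation")
    assert best.test_metrics == {}
    with pytest.raises(ValueError):
        select_best(records, classifier=1, on="test")


def test_select_best_empty_errors():
    with pytest.raises(ValueError):
        select_best([], classifier=1)
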