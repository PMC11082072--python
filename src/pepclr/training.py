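"""Seeded splitting, the optimization loop, grid search, and model selection.

Training minimizes L_final = (1-α)L_CE + αL_CL per batch with Adam
(lr 1e-3 by default). Both losses are computed on the same batch: the
β-mixed cross-entropy over both heads and the contrastive loss over the
projections (skipped, i.e. treated as 0, for a terminal batch of size 1,
where it is undefined). The grid search walks (architecture, seed, α, β,
τ); every point with the same (architecture, seed) starts from the same
initial weights and the same train/validation split, so baseline (α=0)
and contrastive runs are directly comparable — the paired-comparison
design behind "does contrastive learning help".
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.model_selection import train_test_split

from .losses import LossWeights, combined_loss, contrastive_loss, mixed_cross_entropy
from .metrics import MetricsReport, evaluate_model
from .model import DualModel, EncoderConfig, build_dual_model, forward_pass
from .nn import Adam
from .records import PeptideDataset
from .tokenization import TokenizedBatch, tokenize_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    val_fraction: float = 0.1
    weights: LossWeights = field(default_factory=LossWeights)
    model: EncoderConfig = field(default_factory=EncoderConfig)
    select_epoch_by_val_mcc: bool = False
    loss_reduction: str = "mean"
    include_positive_in_denominator: bool = False
    symmetric_contrastive: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0,1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["weights"] = LossWeights(**d["weights"])
        d["model"] = EncoderConfig(**d["model"])
        return cls(**d)


@dataclass(frozen=True)
class GridSpec:
    """Grid axes; defaults mirror the published sweep (plus the α=0 baseline)."""

    alphas: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9)
    betas: tuple[float, ...] = (0.0, 0.5, 1.0)
    taus: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    architectures: tuple[str, ...] = ("cnn", "lstm", "transformer")

    def __post_init__(self) -> None:
        for name in ("alphas", "betas", "taus", "seeds", "architectures"):
            if not getattr(self, name):
                raise ValueError(f"grid axis {name} must be non-empty")

    def points(self):
        return itertools.product(self.architectures, self.seeds, self.taus,
                                 self.betas, self.alphas)


@dataclass
class RunRecord:
    """One grid point: config, per-epoch history, and frozen metrics."""

    config: TrainConfig
    history: list[dict]
    val_metrics: dict[int, MetricsReport]
    test_metrics: dict[int, MetricsReport] = field(default_factory=dict)
    initial_param_hash: str = ""
    model: Optional[DualModel] = None  # not serialized

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "history": self.history,
            "val_metrics": {str(k): v.to_dict() for k, v in self.val_metrics.items()},
            "test_metrics": {str(k): v.to_dict() for k, v in self.test_metrics.items()},
            "initial_param_hash": self.initial_param_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunRecord":
        return cls(
            config=TrainConfig.from_dict(d["config"]),
            history=d["history"],
            val_metrics={int(k): MetricsReport.from_dict(v)
                         for k, v in d["val_metrics"].items()},
            test_metrics={int(k): MetricsReport.from_dict(v)
                          for k, v in d["test_metrics"].items()},
            initial_param_hash=d.get("initial_param_hash", ""),
        )


def split_train_val(dataset: PeptideDataset, val_fraction: float,
                    seed: int) -> tuple[PeptideDataset, PeptideDataset]:
    """Stratified, seeded train/validation partition.

    Validation gets round(n · val_fraction) records (at least 1, at most
    n-1); the same (dataset, seed) always produces the same membership.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in (0,1), got {val_fraction}")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not dataset.labeled():
        raise ValueError("split requires labeled records (for stratification)")
    n_val = min(max(int(round(n * val_fraction)), 1), n - 1)
    labels = np.asarray(dataset.labels)
    stratify = labels if min(np.bincount(labels, minlength=2)) >= 2 else None
    train_idx, val_idx = train_test_split(
        np.arange(n), test_size=n_val, random_state=seed, stratify=stratify,
    )
    return (dataset.subset(sorted(train_idx), split_tag="train"),
            dataset.subset(sorted(val_idx), split_tag="validation"))


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _slice_batch(batch: TokenizedBatch, idx: np.ndarray) -> TokenizedBatch:
    return TokenizedBatch(indices=batch.indices[idx], mask=batch.mask[idx],
                          lengths=batch.lengths[idx])


def train(model: DualModel, train_set: PeptideDataset, val_set: PeptideDataset,
          config: TrainConfig) -> RunRecord:
    """Optimize the dual model; returns the record with the trained model.

    History logs per-epoch means of L_CE, L_CL and L_final (the recorded
    l_final always equals (1-α)·l_ce + α·l_cl) plus validation MCC for
    both classifiers.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if not (train_set.labeled() and val_set.labeled()):
        raise ValueError("training requires labeled records")
    w = config.weights
    max_len = model.config.max_len
    max_residues = max_len - 1  # start token occupies one slot
    train_set = train_set.truncated(max_residues)
    val_set = val_set.truncated(max_residues)
    batch_1 = tokenize_dataset(train_set.sequences, model.vocab_1, max_len)
    batch_2 = tokenize_dataset(train_set.sequences, model.vocab_2, max_len)
    labels = np.asarray(train_set.labels, dtype=np.int64)
    initial_hash = model.parameter_hash()
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    model.set_training(True)
    history: list[dict] = []
    best_val_mcc = -np.inf
    best_params: Optional[list[np.ndarray]] = None
    for epoch in range(config.epochs):
        ce_sum = cl_sum = final_sum = 0.0
        n_batches = 0
        for idx in _epoch_batches(len(train_set), config.batch_size, rng):
            out = forward_pass(model, _slice_batch(batch_1, idx),
                               _slice_batch(batch_2, idx))
            l_ce = mixed_cross_entropy(labels[idx], out.probs_1, out.probs_2,
                                       w.beta, reduction=config.loss_reduction)
            if w.alpha > 0.0 and len(idx) >= 2:
                l_cl = contrastive_loss(
                    out.z_1, out.z_2, w.tau,
                    include_positive_in_denominator=config.include_positive_in_denominator,
                    symmetric=config.symmetric_contrastive,
                    reduction=config.loss_reduction,
                )
                cl_val = l_cl.item()
            else:
                l_cl = 0.0
                cl_val = 0.0
            loss = combined_loss(l_ce, l_cl, w.alpha)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            ce_sum += l_ce.item()
            cl_sum += cl_val
            final_sum += loss.item()
            n_batches += 1
        model.set_training(False)
        val_mcc = {c: evaluate_model(model, val_set, classifier=c).mcc
                   for c in (1, 2)}
        model.set_training(True)
        entry = {
            "epoch": epoch,
            "l_ce": ce_sum / n_batches,
            "l_cl": cl_sum / n_batches,
            "l_final": final_sum / n_batches,
            "val_mcc_1": val_mcc[1],
            "val_mcc_2": val_mcc[2],
        }
        history.append(entry)
        logger.info(
            "epoch %d: l_final=%.4f l_ce=%.4f l_cl=%.4f val_mcc=(%.3f, %.3f)",
            epoch, entry["l_final"], entry["l_ce"], entry["l_cl"],
            val_mcc[1], val_mcc[2],
        )
        if config.select_epoch_by_val_mcc and max(val_mcc.values()) > best_val_mcc:
            best_val_mcc = max(val_mcc.values())
            best_params = [p.data.copy() for p in model.parameters()]
    if config.select_epoch_by_val_mcc and best_params is not None:
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    model.set_training(False)
    val_metrics = {c: evaluate_model(model, val_set, classifier=c)
                   for c in (1, 2)}
    return RunRecord(config=config, history=history, val_metrics=val_metrics,
                     initial_param_hash=initial_hash, model=model)


def _point_key(arch: str, seed: int, tau: float, beta: float, alpha: float) -> str:
    return f"{arch}_seed{seed}_tau{tau:g}_beta{beta:g}_alpha{alpha:g}"


def grid_search(train_dataset: PeptideDataset, test_dataset: PeptideDataset,
                grid: GridSpec, base: TrainConfig,
                ledger_dir: Optional[str | Path] = None) -> list[RunRecord]:
    """Exhaustive sweep over the grid; one RunRecord per point.

    Per seed, the train/validation split is fixed and the model is
    rebuilt from that seed, so every (α, β, τ) point at a given
    (architecture, seed) starts from identical initial weights. With a
    ``ledger_dir``, completed points are loaded instead of retrained, so
    rerunning a finished grid performs no new training.
    """
    ledger = Path(ledger_dir) if ledger_dir is not None else None
    if ledger is not None:
        ledger.mkdir(parents=True, exist_ok=True)
    records: list[RunRecord] = []
    split_cache: dict[int, tuple[PeptideDataset, PeptideDataset]] = {}
    init_cache: dict[tuple[str, int], DualModel] = {}
    for arch, seed, tau, beta, alpha in grid.points():
        key = _point_key(arch, seed, tau, beta, alpha)
        if ledger is not None:
            path = ledger / f"{key}.json"
            if path.exists():
                records.append(RunRecord.from_dict(json.loads(path.read_text())))
                continue
        if seed not in split_cache:
            split_cache[seed] = split_train_val(train_dataset,
                                                base.val_fraction, seed)
        tr, val = split_cache[seed]
        model_config = replace(base.model, architecture=arch)
        cache_key = (arch, seed)
        if cache_key not in init_cache:
            init_cache[cache_key] = build_dual_model(model_config, seed)
        model = init_cache[cache_key].copy()
        config = replace(base, seed=seed, model=model_config,
                         weights=LossWeights(alpha=alpha, beta=beta, tau=tau))
        record = train(model, tr, val, config)
        record.test_metrics = {c: evaluate_model(model, test_dataset, classifier=c)
                               for c in (1, 2)}
        if ledger is not None:
            (ledger / f"{key}.json").write_text(json.dumps(record.to_dict()))
        records.append(record)
    return records


def select_best(records: list[RunRecord], classifier: int | str = 1,
                on: str = "validation") -> tuple[RunRecord, int]:
    """Pick the record (and head) with the highest MCC on the given split.

    Ties break by higher accuracy, then lower α, then lower seed.
    Selecting on the test split mirrors the published protocol but is
    leakage-prone; validation is the honest default.
    """
    if not records:
        raise ValueError("no records to select from")
    if on not in ("validation", "test"):
        raise ValueError(f"on must be 'validation' or 'test', got {on!r}")
    if on == "test":
        logger.warning("selecting on the test split: metrics will be "
                       "optimistically biased")
    classifiers = (1, 2) if classifier == "both" else (int(classifier),)
    best: Optional[tuple] = None
    for record in records:
        metrics = record.val_metrics if on == "validation" else record.test_metrics
        for c in classifiers:
            if c not in metrics:
                raise ValueError(f"record missing metrics for classifier {c} on {on}")
            m = metrics[c]
            sort_key = (m.mcc, m.accuracy, -record.config.weights.alpha,
                        -record.config.seed)
            if best is None or sort_key > best[0]:
                best = (sort_key, record, c)
    assert best is not None
    return best[1], best[2]


def paired_comparison(records: list[RunRecord], classifier: int = 1,
                      on: str = "test") -> list[dict]:
    """Baseline-vs-contrastive MCC pairs from identical initial weights.

    For every (architecture, seed) with an α=0 record, emits one row per
    contrastive (α>0) record at that point: the scatter behind the
    "does contrastive learning beat the baseline" comparison. Initial
    parameter hashes are carried so pairing can be verified.
    """
    baselines: dict[tuple[str, int], RunRecord] = {}
    for r in records:
        if r.config.weights.alpha == 0.0:
            key = (r.config.model.architecture, r.config.seed)
            prev = baselines.get(key)
            if prev is None or r.config.weights.beta < prev.config.weights.beta:
                baselines[key] = r
    rows = []
    for r in records:
        if r.config.weights.alpha == 0.0:
            continue
        key = (r.config.model.architecture, r.config.seed)
        base = baselines.get(key)
        if base is None:
            continue
        base_m = (base.val_metrics if on == "validation" else base.test_metrics)[classifier]
        cont_m = (r.val_metrics if on == "validation" else r.test_metrics)[classifier]
        rows.append({
            "architecture": key[0],
            "seed": key[1],
            "alpha": r.config.weights.alpha,
            "beta": r.config.weights.beta,
            "tau": r.config.weights.tau,
            "baseline_mcc": base_m.mcc,
            "contrastive_mcc": cont_m.mcc,
            "same_init": base.initial_param_hash == r.initial_param_hash,
        })
    return rows
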