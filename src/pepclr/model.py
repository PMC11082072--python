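"""The two-tower classifier: embedding → encoder backbone → head + projector.

One tower consumes the single-residue tokenization (23-row embedding),
the other the residue-pair tokenization (443 rows). The towers share the
architecture but no parameters. Each tower emits a two-class probability
pair (its "classifier") and an L2-normalized projection vector (the
feature entering the contrastive loss). The two projections of the same
peptide form the positive pair — the augmentation-free substitute for
the augmented views used in image contrastive learning.

Backbones: ``cnn`` (1-D convolutions, kernel sizes 3 and 5 concatenated,
masked global max pooling), ``lstm`` (final hidden state at the true
sequence length), ``transformer`` (pre-norm encoder blocks with learned
positional embeddings, pooled at the start token).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor, concatenate, softmax
from .nn import (
    NEG_INF,
    Conv1dSame,
    Dropout,
    Embedding,
    LayerNorm,
    Linear,
    LSTMLayer,
    Module,
    Parameter,
    TransformerBlock,
)
from .tokenization import TokenizedBatch, Vocabulary, build_vocabulary

logger = logging.getLogger(__name__)

ARCHITECTURES = ("cnn", "lstm", "transformer")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters shared by both towers."""

    architecture: str = "cnn"
    embed_dim: int = 64
    hidden_dim: int = 128
    n_layers: int = 2
    n_heads: int = 4
    proj_dim: int = 64
    dropout: float = 0.1
    max_len: int = 64
    pair_stride: int = 2

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        for name in ("embed_dim", "hidden_dim", "n_layers", "proj_dim", "max_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.architecture == "transformer":
            if self.embed_dim % self.n_heads != 0:
                raise ConfigError(
                    f"embed_dim {self.embed_dim} not divisible by "
                    f"n_heads {self.n_heads}"
                )
        elif self.n_heads != 4:  # non-default value supplied for a non-attention net
            logger.warning(
                "n_heads=%d ignored for architecture %r",
                self.n_heads, self.architecture,
            )


@dataclass
class ForwardOutput:
    """Per-tower class probabilities and unit-norm projection vectors."""

    probs_1: Tensor  # (B, 2)
    probs_2: Tensor  # (B, 2)
    z_1: Tensor  # (B, proj_dim)
    z_2: Tensor  # (B, proj_dim)


def _l2_normalize(z: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((z * z).sum(axis=-1, keepdims=True) + eps).sqrt()
    return z / norm


class Tower(Module):
    """One encoder tower over one vocabulary."""

    def __init__(self, rng: np.random.Generator, vocab_size: int,
                 config: EncoderConfig):
        self.config = config
        c = config
        self.embedding = Embedding(rng, vocab_size, c.embed_dim)
        self.dropout = Dropout(c.dropout, rng)
        arch = c.architecture
        if arch == "transformer":
            self.pos_embedding = Parameter(
                rng.normal(0.0, 0.02, size=(c.max_len, c.embed_dim))
            )
            self.blocks = [
                TransformerBlock(rng, c.embed_dim, c.n_heads, c.hidden_dim,
                                 self.dropout)
                for _ in range(c.n_layers)
            ]
            self.final_norm = LayerNorm(c.embed_dim)
            repr_dim = c.embed_dim
        elif arch == "cnn":
            half = max(1, c.hidden_dim // 2)
            self.conv_layers = []
            in_dim = c.embed_dim
            for _ in range(c.n_layers):
                self.conv_layers.append(
                    (Conv1dSame(rng, in_dim, half, 3), Conv1dSame(rng, in_dim, half, 5))
                )
                in_dim = 2 * half
            repr_dim = in_dim
        else:  # lstm
            self.lstm_layers = []
            in_dim = c.embed_dim
            for _ in range(c.n_layers):
                self.lstm_layers.append(LSTMLayer(rng, in_dim, c.hidden_dim))
                in_dim = c.hidden_dim
            repr_dim = c.hidden_dim
        self.repr_dim = repr_dim
        self.head = Linear(rng, repr_dim, 2)
        self.proj_hidden = Linear(rng, repr_dim, repr_dim)
        self.proj_out = Linear(rng, repr_dim, c.proj_dim)

    def parameters(self) -> list[Parameter]:
        params = super().parameters()
        for value in self.__dict__.values():
            if isinstance(value, list):
                for item in value:
                    if isinstance(item, tuple):
                        for sub in item:
                            if isinstance(sub, Module):
                                params.extend(sub.parameters())
        return params

    def set_training(self, flag: bool) -> None:
        super().set_training(flag)
        for value in self.__dict__.values():
            if isinstance(value, list):
                for item in value:
                    if isinstance(item, tuple):
                        for sub in item:
                            if isinstance(sub, Module):
                                sub.set_training(flag)

    # -- encoding -------------------------------------------------------------
    def embed(self, indices: np.ndarray) -> Tensor:
        return self.embedding(indices)

    def encode_from_embeddings(self, emb: Tensor, mask: np.ndarray,
                               lengths: np.ndarray) -> Tensor:
        """Map embedded tokens (B, T, E) to a pooled representation (B, R).

        Padded positions never influence the pooled vector: the
        transformer masks padded keys and pools the start token, the CNN
        max-pools only over real positions, and the LSTM state is read at
        each sequence's true final token.
        """
        c = self.config
        B, T, _ = emb.shape
        if c.architecture == "transformer":
            x = emb + self.pos_embedding[:T, :]
            x = self.dropout(x)
            for block in self.blocks:
                x = block(x, mask)
            x = self.final_norm(x)
            pooled = x[:, 0, :]  # start-token position
        elif c.architecture == "cnn":
            x = emb
            for conv3, conv5 in self.conv_layers:
                x = concatenate([conv3(x), conv5(x)], axis=2).relu()
                x = self.dropout(x)
            # masked global max pool over positions
            bias = Tensor(((1.0 - mask) * NEG_INF)[:, :, None])
            pooled = (x + bias).max(axis=1)
        else:  # lstm
            x = emb
            for layer in self.lstm_layers:
                x = layer(x)
                x = self.dropout(x)
            pooled = x[np.arange(B), lengths - 1]  # final true-position state
        return pooled

    def forward(self, batch: TokenizedBatch) -> tuple[Tensor, Tensor]:
        """Return (probs, z) for a tokenized batch."""
        emb = self.embed(batch.indices)
        pooled = self.encode_from_embeddings(emb, batch.mask, batch.lengths)
        probs = softmax(self.head(pooled), axis=-1)
        z = _l2_normalize(self.proj_out(self.proj_hidden(pooled).relu()))
        return probs, z


class DualModel(Module):
    """Two independent towers sharing no parameters."""

    def __init__(self, config: EncoderConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.vocab_1 = build_vocabulary("single", pair_stride=config.pair_stride)
        self.vocab_2 = build_vocabulary("pair", pair_stride=config.pair_stride)
        self.tower_1 = Tower(rng, len(self.vocab_1), config)
        self.tower_2 = Tower(rng, len(self.vocab_2), config)
        self.set_training(False)

    def parameter_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def copy(self) -> "DualModel":
        clone = DualModel(self.config, self.seed)
        for dst, src in zip(clone.parameters(), self.parameters()):
            dst.data = src.data.copy()
        return clone


def build_dual_model(config: EncoderConfig, seed: int) -> DualModel:
    """Build a dual model with all parameters determined by (config, seed)."""
    return DualModel(config, seed)


def forward_pass(model: DualModel, batch_1: TokenizedBatch,
                 batch_2: TokenizedBatch) -> ForwardOutput:
    """Run both towers on the two tokenizations of the same peptides.

    The batches must be aligned: row i of each batch is the same peptide,
    otherwise the contrastive positive pairs are meaningless.
    """
    if len(batch_1) != len(batch_2):
        raise ValueError(
            f"batch size mismatch: {len(batch_1)} vs {len(batch_2)} "
            "(towers must see the same ordered peptides)"
        )
    probs_1, z_1 = model.tower_1.forward(batch_1)
    probs_2, z_2 = model.tower_2.forward(batch_2)
    return ForwardOutput(probs_1=probs_1, probs_2=probs_2, z_1=z_1, z_2=z_2)


# -- checkpointing -------------------------------------------------------------

def _vocab_hash(vocab: Vocabulary) -> str:
    payload = json.dumps(sorted(vocab.token_to_index.items())).encode()
    return hashlib.sha256(payload).hexdigest()


def save_checkpoint(model: DualModel, path: str | Path) -> None:
    """Save config + parameters + vocabulary hashes to an .npz file."""
    path = Path(path)
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "vocab_hash_1": _vocab_hash(model.vocab_1),
        "vocab_hash_2": _vocab_hash(model.vocab_2),
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> DualModel:
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = EncoderConfig(**meta["config"])
        model = DualModel(config, meta["seed"])
        if _vocab_hash(model.vocab_1) != meta["vocab_hash_1"] or \
           _vocab_hash(model.vocab_2) != meta["vocab_hash_2"]:
            raise ConfigError(f"{path}: vocabulary hash mismatch")
        params = model.parameters()
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ConfigError(f"{path}: parameter {i} shape mismatch")
            p.data = stored.astype(np.float64)
    return model
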