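"""Attribution-based interpretation of trained dual models.

Integrated gradients assigns each input token a contribution to the
predicted ACP probability by integrating the gradient of the class-1
probability along the straight-line path from a baseline embedding to
the actual embedding:

    IG_j = (x_j - x'_j) · (1/m) Σ_k ∂F(x' + (k-½)/m · (x - x'))/∂x_j

(midpoint Riemann sum, m = n_steps). Per-dimension attributions are
summed over the embedding axis to one score per token. The completeness
axiom — attributions summing to F(x) − F(baseline) — is checked and the
residual gap reported, never hidden: a large gap means n_steps is too
small for the model's curvature.

Per-residue summaries average scores over every occurrence of each amino
acid in a dataset; pair-tower token scores are split equally between the
two residues of the pair. For the transformer backbone, the post-softmax
attention maps of any layer can be extracted per head.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor
from .model import DualModel
from .records import ALPHABET, PeptideDataset, PeptideRecord
from .tokenization import START_TOKEN, pad_and_mask, tokenize


class AttributionError(ValueError):
    pass


@dataclass
class AttributionResult:
    record_id: str
    tokens: list[str]  # token strings, start token included
    per_position_scores: np.ndarray  # one score per token
    is_special: np.ndarray  # True at start/pad positions
    predicted_prob: float
    classifier_id: int
    n_steps: int
    completeness_gap: float
    baseline_prob: float


def _tower_forward_prob(model: DualModel, tower_id: int, emb: Tensor,
                        mask: np.ndarray, lengths: np.ndarray) -> Tensor:
    from .autodiff import softmax

    tower = model.tower_1 if tower_id == 1 else model.tower_2
    pooled = tower.encode_from_embeddings(emb, mask, lengths)
    probs = softmax(tower.head(pooled), axis=-1)
    return probs[:, 1]


def integrated_gradients(model: DualModel, record: PeptideRecord,
                         tower: int = 1, n_steps: int = 64,
                         baseline: str = "pad") -> AttributionResult:
    """Per-token attribution of the class-1 probability, one record.

    ``baseline='pad'`` uses the padding-token embedding at every position
    (the model's native absence token); ``'zero'`` uses the zero vector.
    """
    if n_steps < 2:
        raise AttributionError(f"n_steps must be >= 2, got {n_steps}")
    if tower not in (1, 2):
        raise AttributionError(f"tower must be 1 or 2, got {tower}")
    if baseline not in ("pad", "zero"):
        raise AttributionError(f"baseline must be 'pad' or 'zero', got {baseline!r}")
    model.set_training(False)
    vocab = model.vocab_1 if tower == 1 else model.vocab_2
    tw = model.tower_1 if tower == 1 else model.tower_2
    token_ids = tokenize(record.sequence, vocab)
    T = len(token_ids)
    batch = pad_and_mask([token_ids], T, pad_index=vocab.pad_index)
    emb_table = tw.embedding.weight.data
    x = emb_table[batch.indices[0]]  # (T, E)
    if baseline == "pad":
        x_base = np.tile(emb_table[vocab.pad_index], (T, 1))
    else:
        x_base = np.zeros_like(x)
    diff = x - x_base

    def prob_at(emb_points: np.ndarray) -> tuple[np.ndarray, Tensor]:
        """Forward a stack of embedded inputs; returns probs and the leaf."""
        k = emb_points.shape[0]
        leaf = Tensor(emb_points, requires_grad=True)
        mask = np.ones((k, T))
        lengths = np.full(k, T, dtype=np.int64)
        probs = _tower_forward_prob(model, tower, leaf, mask, lengths)
        return probs, leaf

    # endpoint probabilities
    ends, _ = prob_at(np.stack([x, x_base]))
    f_x, f_base = float(ends.data[0]), float(ends.data[1])
    # midpoint Riemann sum along the path, all steps in one batch
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    points = x_base[None] + alphas[:, None, None] * diff[None]
    probs, leaf = prob_at(points)
    probs.sum().backward()
    avg_grad = leaf.grad.mean(axis=0)  # (T, E)
    attributions = (diff * avg_grad).sum(axis=1)  # (T,)
    gap = abs(float(attributions.sum()) - (f_x - f_base))
    i2t = vocab.index_to_token
    tokens = [i2t[int(i)] for i in token_ids]
    tokens[0] = "[CLS]"
    is_special = np.array([t in ("[CLS]", START_TOKEN) for t in tokens])
    return AttributionResult(
        record_id=record.id,
        tokens=tokens,
        per_position_scores=attributions,
        is_special=is_special,
        predicted_prob=f_x,
        classifier_id=tower,
        n_steps=n_steps,
        completeness_gap=gap,
        baseline_prob=f_base,
    )


@dataclass
class ResidueAttributionSummary:
    """Per-amino-acid mean/dispersion/count of attribution scores."""

    mean: dict[str, Optional[float]]
    std: dict[str, Optional[float]]
    count: dict[str, int]

    def report_fields(self) -> dict:
        fields: dict = {}
        for aa in ALPHABET:
            m = self.mean[aa]
            fields[f"mean_{aa}"] = float("nan") if m is None else m
            fields[f"count_{aa}"] = self.count[aa]
        return fields

    def ranked(self) -> list[tuple[str, float]]:
        """Residues with occurrences, sorted by descending mean score."""
        pairs = [(aa, m) for aa, m in self.mean.items() if m is not None]
        return sorted(pairs, key=lambda kv: -kv[1])


def summarize_attributions(results: list[AttributionResult],
                           dataset: PeptideDataset) -> ResidueAttributionSummary:
    """Average per-residue attribution over every occurrence in a dataset.

    Single-tower tokens map 1:1 to residues; pair-tower token scores are
    split 50/50 between the pair's residues. Special tokens are excluded.
    """
    if not results:
        raise AttributionError("no attribution results to summarize")
    by_id = {r.id: r for r in dataset}
    scores: dict[str, list[float]] = {aa: [] for aa in ALPHABET}
    for res in results:
        record = by_id.get(res.record_id)
        if record is None:
            raise AttributionError(f"record {res.record_id!r} not in dataset")
        for token, score, special in zip(res.tokens, res.per_position_scores,
                                         res.is_special):
            if special:
                continue
            if len(token) == 1:
                scores[token].append(float(score))
            else:  # pair token: split equally between the two residues
                for aa in token:
                    scores[aa].append(float(score) / 2.0)
    mean = {aa: (float(np.mean(v)) if v else None) for aa, v in scores.items()}
    std = {aa: (float(np.std(v)) if v else None) for aa, v in scores.items()}
    count = {aa: len(v) for aa, v in scores.items()}
    return ResidueAttributionSummary(mean=mean, std=std, count=count)


def extract_attention(model: DualModel, record: PeptideRecord,
                      tower: int = 1, layer: int = 0,
                      ) -> tuple[list[np.ndarray], list[str]]:
    """Per-head attention matrices of one transformer layer for one record.

    Returns ``n_heads`` row-stochastic (T × T) matrices and the token
    labels (start token labeled ``[CLS]``). Raises for non-transformer
    backbones.
    """
    if model.config.architecture != "transformer":
        raise AttributionError(
            f"attention extraction requires the transformer backbone, "
            f"model uses {model.config.architecture!r}"
        )
    if not 0 <= layer < model.config.n_layers:
        raise AttributionError(
            f"layer {layer} out of range [0, {model.config.n_layers})"
        )
    model.set_training(False)
    vocab = model.vocab_1 if tower == 1 else model.vocab_2
    tw = model.tower_1 if tower == 1 else model.tower_2
    token_ids = tokenize(record.sequence, vocab)
    T = len(token_ids)
    batch = pad_and_mask([token_ids], T, pad_index=vocab.pad_index)
    tw.forward(batch)
    attn = tw.blocks[layer].attn.last_attention  # (1, heads, T, T)
    matrices = [attn[0, h].copy() for h in range(attn.shape[1])]
    i2t = vocab.index_to_token
    labels = [i2t[int(i)] for i in token_ids]
    labels[0] = "[CLS]"
    return matrices, labels


def attention_long_format(matrices: list[np.ndarray],
                          labels: list[str]) -> list[dict]:
    """Flatten attention maps to rows (head, from_token, to_token, weight)."""
    rows = []
    for h, mat in enumerate(matrices):
        for i, from_tok in enumerate(labels):
            for j, to_tok in enumerate(labels):
                rows.append({"head": h, "from_token": from_tok,
                             "to_token": to_tok, "weight": float(mat[i, j])})
    return rows
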