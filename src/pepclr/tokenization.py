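"""Dual tokenizers: single-residue and residue-pair vocabularies.

The same peptide is tokenized two ways — one index per amino acid
(23-symbol vocabulary: 21 residues + start + pad) and one index per
amino-acid pair (443 symbols: 21² ordered pairs + start + pad). The two
index sequences feed the two encoder towers and act as the positive pair
for contrastive learning, replacing data augmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import ALPHABET

PAD_TOKEN = "<pad>"
START_TOKEN = "<start>"


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Token→index map for one tokenizer mode.

    Index assignment is fixed: pad=0, start=1, then residue tokens in
    alphabetical order (pair mode: lexicographic over the same order).
    """

    mode: str
    token_to_index: dict[str, int] = field(repr=False)
    pair_stride: int = 2

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def start_index(self) -> int:
        return 1

    @property
    def token_length(self) -> int:
        return 1 if self.mode == "single" else 2

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def index_to_token(self) -> dict[int, str]:
        return {v: k for k, v in self.token_to_index.items()}

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("token,index\n")
            for tok, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok},{idx}\n")


def build_vocabulary(mode: str, pair_stride: int = 2) -> Vocabulary:
    """Build the single (size 23) or pair (size 443) vocabulary.

    ``pair_stride`` is carried on the vocabulary so tokenization of pair
    mode can use non-overlapping pairs (stride 2, default) or sliding
    bigrams (stride 1).
    """
    if mode not in ("single", "pair"):
        raise TokenizationError(f"unknown tokenizer mode {mode!r}")
    if pair_stride not in (1, 2):
        raise TokenizationError(f"pair_stride must be 1 or 2, got {pair_stride}")
    mapping = {PAD_TOKEN: 0, START_TOKEN: 1}
    if mode == "single":
        for i, aa in enumerate(ALPHABET):
            mapping[aa] = 2 + i
    else:
        k = 0
        for a in ALPHABET:
            for b in ALPHABET:
                mapping[a + b] = 2 + k
                k += 1
    return Vocabulary(mode=mode, token_to_index=mapping, pair_stride=pair_stride)


def tokenize(sequence: str, vocab: Vocabulary) -> list[int]:
    """Convert a canonical sequence to a start-prefixed index list.

    Single mode emits one index per residue (length n+1). Pair mode reads
    non-overlapping pairs left to right (stride 2 default); odd-length
    sequences are completed with one ``'X'`` for the final pair, giving
    ceil(n/2)+1 indices. With ``pair_stride=1`` sliding bigrams are used.
    """
    if not sequence:
        raise TokenizationError("cannot tokenize an empty sequence")
    t2i = vocab.token_to_index
    out = [vocab.start_index]
    if vocab.mode == "single":
        for pos, aa in enumerate(sequence):
            idx = t2i.get(aa)
            if idx is None:
                raise TokenizationError(
                    f"non-canonical character {aa!r} at position {pos}"
                )
            out.append(idx)
        return out
    stride = vocab.pair_stride
    padded = sequence + "X" if (stride == 2 and len(sequence) % 2 == 1) else sequence
    if stride == 1 and len(padded) == 1:
        padded = padded + "X"
    for pos in range(0, len(padded) - 1, stride):
        pair = padded[pos : pos + 2]
        idx = t2i.get(pair)
        if idx is None:
            bad = pair[0] if pair[0] not in ALPHABET else pair[1]
            raise TokenizationError(
                f"non-canonical character {bad!r} at position {pos}"
            )
        out.append(idx)
    return out


def detokenize(indices: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`tokenize` up to odd-length 'X' completion.

    Drops start/pad tokens and concatenates residue tokens.
    """
    i2t = vocab.index_to_token
    parts = []
    for idx in indices:
        if idx in (vocab.pad_index, vocab.start_index):
            continue
        parts.append(i2t[int(idx)])
    return "".join(parts)


@dataclass
class TokenizedBatch:
    """Padded index matrix with mask and true lengths (start token counted)."""

    indices: np.ndarray  # (batch, max_len) int64
    mask: np.ndarray  # (batch, max_len) float, 1.0 at real tokens
    lengths: np.ndarray  # (batch,) int64

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    @property
    def max_len(self) -> int:
        return int(self.indices.shape[1])


def pad_and_mask(token_lists: Sequence[Sequence[int]], max_len: int,
                 pad_index: int = 0) -> TokenizedBatch:
    """Right-pad token lists to ``max_len`` and build the validity mask.

    Lists longer than ``max_len`` are an error: truncation is the data
    loader's responsibility, before tokenization.
    """
    n = len(token_lists)
    indices = np.full((n, max_len), pad_index, dtype=np.int64)
    mask = np.zeros((n, max_len), dtype=np.float64)
    lengths = np.zeros(n, dtype=np.int64)
    for i, toks in enumerate(token_lists):
        if len(toks) > max_len:
            raise TokenizationError(
                f"token list {i} has length {len(toks)} > max_len {max_len}"
            )
        lengths[i] = len(toks)
        indices[i, : len(toks)] = np.asarray(toks, dtype=np.int64)
        mask[i, : len(toks)] = 1.0
    return TokenizedBatch(indices=indices, mask=mask, lengths=lengths)


def tokenize_dataset(sequences: Sequence[str], vocab: Vocabulary,
                     max_len: int) -> TokenizedBatch:
    """Tokenize and pad a whole collection of canonical sequences."""
    return pad_and_mask([tokenize(s, vocab) for s in sequences], max_len,
                        pad_index=vocab.pad_index)


def pair_token_count(n: int) -> int:
    """Number of pair-mode tokens (incl. start) for a length-n sequence."""
    return math.ceil(n / 2) + 1
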