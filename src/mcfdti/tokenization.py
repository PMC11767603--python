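"""Sequence vocabularies and tokenizers.

Drugs arrive as SMILES strings and are tokenized per character; target proteins
are tokenized both per amino-acid letter (for the convolutional path) and as
byte-pair-encoded subwords (for the transformer path). Every tokenizer is a
total function over text: any character outside the vocabulary — or outside an
optional ``allowed`` alphabet such as the 20 standard amino acids — maps to the
unknown token ``'?'``, which doubles as the padding token; a binary mask, not a
distinct index, marks which positions are real.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

UNKNOWN_TOKEN = "?"

#: single-letter codes of the 20 standard amino acids
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Vocabulary:
    """Deterministic token-to-index map with a total unknown fallback.

    ``'?'`` always sits at index 0 and serves as both the unknown and the
    padding token.
    """

    token_to_index: dict[str, int]

    unknown_token: str = UNKNOWN_TOKEN
    pad_token: str = UNKNOWN_TOKEN

    def __post_init__(self) -> None:
        idx = sorted(self.token_to_index.values())
        if idx != list(range(len(idx))):
            raise ValueError("vocabulary indices must be contiguous from 0")
        if UNKNOWN_TOKEN not in self.token_to_index:
            raise ValueError("vocabulary must contain the unknown token '?'")

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    @property
    def unknown_index(self) -> int:
        return self.token_to_index[UNKNOWN_TOKEN]

    pad_index = unknown_index

    def lookup(self, token: str) -> int:
        return self.token_to_index.get(token, self.unknown_index)

    @classmethod
    def from_tokens(cls, tokens) -> "Vocabulary":
        """Build with '?' at index 0 followed by the remaining tokens sorted."""
        rest = sorted(set(tokens) - {UNKNOWN_TOKEN})
        return cls({t: i for i, t in enumerate([UNKNOWN_TOKEN] + rest)})

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        ordered = sorted(self.token_to_index, key=self.token_to_index.get)
        return json.dumps({"tokens": ordered})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        tokens = json.loads(text)["tokens"]
        return cls({t: i for i, t in enumerate(tokens)})


@dataclass
class TokenizedSequence:
    """Fixed-length index vector plus validity mask for one sequence."""

    indices: np.ndarray       # int64, length max_len
    mask: np.ndarray          # float32, 1 = real token, 0 = padding
    original_length: int

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.mask):
            raise ValueError("indices and mask must have equal length")


def build_smiles_vocabulary(corpus: list[str]) -> Vocabulary:
    """Character vocabulary over a SMILES corpus plus the '?' token."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    chars: set[str] = set()
    for smiles in corpus:
        chars.update(smiles)
    return Vocabulary.from_tokens(chars)


def build_protein_vocabulary() -> Vocabulary:
    """Fixed vocabulary of the 20 standard amino-acid letters plus '?'."""
    return Vocabulary.from_tokens(AMINO_ACIDS)


def tokenize_chars(sequence: str, vocab: Vocabulary, max_len: int,
                   allowed: frozenset[str] | set[str] | None = None,
                   ) -> TokenizedSequence:
    """Per-character tokenization with padding/truncation to ``max_len``."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    unk = vocab.unknown_index
    ids = []
    for ch in sequence[:max_len]:
        if allowed is not None and ch not in allowed:
            ids.append(unk)
        else:
            ids.append(vocab.lookup(ch))
    n_real = len(ids)
    ids.extend([unk] * (max_len - n_real))
    mask = np.zeros(max_len, dtype=np.float32)
    mask[:n_real] = 1.0
    return TokenizedSequence(np.asarray(ids, dtype=np.int64), mask, len(sequence))


# ---------------------------------------------------------------------------
# byte-pair encoding


@dataclass
class BpeModel:
    """Ordered merge rules plus the resulting subword vocabulary."""

    merges: list[tuple[str, str]]
    subword_vocab: Vocabulary
    num_merges: int

    def to_json(self) -> str:
        ordered = sorted(self.subword_vocab.token_to_index,
                         key=self.subword_vocab.token_to_index.get)
        return json.dumps({"merges": [list(m) for m in self.merges],
                           "tokens": ordered, "num_merges": self.num_merges})

    @classmethod
    def from_json(cls, text: str) -> "BpeModel":
        doc = json.loads(text)
        vocab = Vocabulary({t: i for i, t in enumerate(doc["tokens"])})
        return cls([tuple(m) for m in doc["merges"]], vocab, doc["num_merges"])


def _merge_symbols(symbols: list[str], pair: tuple[str, str]) -> list[str]:
    """Replace left-to-right non-overlapping occurrences of ``pair``."""
    a, b = pair
    out: list[str] = []
    i = 0
    n = len(symbols)
    while i < n:
        if i + 1 < n and symbols[i] == a and symbols[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    return out


def train_bpe(corpus: list[str], num_merges: int) -> BpeModel:
    """Learn merge rules by repeatedly fusing the most frequent adjacent pair.

    Ties on pair frequency are broken by lexicographic order of the pair, so
    training is deterministic for a given corpus.
    """
    if not corpus:
        raise ValueError("cannot train BPE on an empty corpus")
    if num_merges < 0:
        raise ValueError("num_merges must be >= 0")
    sequences = [list(s) for s in corpus]
    singles = {ch for s in sequences for ch in s}
    merges: list[tuple[str, str]] = []
    for _ in range(num_merges):
        counts: Counter[tuple[str, str]] = Counter()
        for s in sequences:
            for i in range(len(s) - 1):
                counts[(s[i], s[i + 1])] += 1
        if not counts:
            break
        best = min(counts, key=lambda p: (-counts[p], p))
        merges.append(best)
        sequences = [_merge_symbols(s, best) for s in sequences]
    tokens = singles | {a + b for a, b in merges}
    return BpeModel(merges, Vocabulary.from_tokens(tokens), num_merges)


def encode_bpe(sequence: str, model: BpeModel, max_tokens: int,
               ) -> TokenizedSequence:
    """Apply merges in training order, then index, pad/truncate, and mask."""
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    symbols = list(sequence)
    for pair in model.merges:
        if len(symbols) < 2:
            break
        symbols = _merge_symbols(symbols, pair)
    vocab = model.subword_vocab
    ids = [vocab.lookup(tok) for tok in symbols[:max_tokens]]
    n_real = len(ids)
    ids.extend([vocab.unknown_index] * (max_tokens - n_real))
    mask = np.zeros(max_tokens, dtype=np.float32)
    mask[:n_real] = 1.0
    return TokenizedSequence(np.asarray(ids, dtype=np.int64), mask, len(symbols))


# ---------------------------------------------------------------------------
# file readers


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {record id: sequence} map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_smiles_lines(path: str | Path) -> list[str]:
    """Read one SMILES per line, skipping blanks."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]
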