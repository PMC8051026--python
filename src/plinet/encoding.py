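"""One-hot encoding of protein sequences and ligand SMILES strings.

Proteins are encoded over the 20 standard amino acids into a fixed-size
``20 x 1200`` binary matrix: sequences shorter than the maximum length are
padded at the end with all-zero columns, longer sequences keep their
N-terminal prefix.  Ligand SMILES are tokenized over a pinned 64-symbol
vocabulary (two-character halogens ``Cl``/``Br`` are single tokens) into a
``64 x 200`` matrix with the same padding/truncation rule.

Unknown symbols map to all-zero columns so the matrix shapes stay exact;
optionally they raise.  Positions are 0-based internally; interval files use
BED convention (0-based, half-open).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

PROTEIN_MAX_LEN = 1200
LIGAND_MAX_LEN = 200
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "PROTEIN_MAX_LEN",
    "LIGAND_MAX_LEN",
    "STANDARD_AMINO_ACIDS",
    "TokenVocabulary",
    "ProteinEncoding",
    "LigandEncoding",
    "EncodedPair",
    "UnknownTokenError",
    "load_vocabulary",
    "protein_vocabulary",
    "smiles_vocabulary",
    "tokenize_smiles",
    "encode_protein",
    "encode_smiles",
    "decode_protein",
    "decode_smiles",
]


class UnknownTokenError(ValueError):
    """A token absent from the vocabulary under the ``error`` policy."""


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token inventory; token order defines the one-hot row index.

    ``kind`` is ``"protein"`` (exactly the 20 standard amino-acid letters)
    or ``"smiles"`` (the pinned 64-symbol inventory shipped with the
    package, or a user-supplied file).
    """

    kind: str
    tokens: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)
    _max_token_len: int = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "smiles"):
            raise ValueError(f"vocabulary kind must be 'protein' or 'smiles', got {self.kind!r}")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if any(not t for t in self.tokens):
            raise ValueError("vocabulary tokens must be non-empty strings")
        if self.kind == "protein" and sorted(self.tokens) != sorted(STANDARD_AMINO_ACIDS):
            raise ValueError("protein vocabulary must be exactly the 20 standard amino acids")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})
        object.__setattr__(self, "_max_token_len", max(len(t) for t in self.tokens))

    @property
    def size(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self._index[token]

    def sha256(self) -> str:
        """Hash of the ordered token list; stored in model checkpoints."""
        payload = "\n".join(self.tokens).encode()
        return hashlib.sha256(payload).hexdigest()


def load_vocabulary(path: str | Path, kind: str) -> TokenVocabulary:
    """Read a plain-text vocabulary, one token per line, order = row index."""
    lines = Path(path).read_text().splitlines()
    tokens = tuple(line for line in lines if line.strip())
    return TokenVocabulary(kind=kind, tokens=tokens)


@lru_cache(maxsize=None)
def protein_vocabulary() -> TokenVocabulary:
    text = resources.files("plinet.data").joinpath("protein_vocab.txt").read_text()
    tokens = tuple(line for line in text.splitlines() if line.strip())
    return TokenVocabulary(kind="protein", tokens=tokens)


@lru_cache(maxsize=None)
def smiles_vocabulary() -> TokenVocabulary:
    text = resources.files("plinet.data").joinpath("smiles_vocab.txt").read_text()
    tokens = tuple(line for line in text.splitlines() if line.strip())
    vocab = TokenVocabulary(kind="smiles", tokens=tokens)
    if vocab.size != 64:
        raise RuntimeError("pinned SMILES vocabulary must contain exactly 64 tokens")
    return vocab


@dataclass
class ProteinEncoding:
    """One-hot protein matrix, 20 rows (tokens) x ``max_len`` columns."""

    matrix: np.ndarray
    true_length: int

    def copy(self) -> "ProteinEncoding":
        return ProteinEncoding(self.matrix.copy(), self.true_length)


@dataclass
class LigandEncoding:
    """One-hot ligand matrix, 64 rows (tokens) x ``max_len`` columns."""

    matrix: np.ndarray
    true_length: int

    def copy(self) -> "LigandEncoding":
        return LigandEncoding(self.matrix.copy(), self.true_length)


@dataclass
class EncodedPair:
    """One model input: encoded protein + encoded ligand + task tag + label."""

    protein: ProteinEncoding
    ligand: LigandEncoding
    task: str
    label: float


def _encode_tokens(
    tokens: Sequence[str],
    vocab: TokenVocabulary,
    max_len: int,
    unknown: str,
) -> np.ndarray:
    if unknown not in ("zero", "error"):
        raise ValueError(f"unknown-token policy must be 'zero' or 'error', got {unknown!r}")
    matrix = np.zeros((vocab.size, max_len), dtype=np.float32)
    for pos, tok in enumerate(tokens[:max_len]):
        if tok in vocab:
            matrix[vocab.index(tok), pos] = 1.0
        elif unknown == "error":
            raise UnknownTokenError(f"token {tok!r} at position {pos} not in {vocab.kind} vocabulary")
        # 'zero' policy: leave the column all-zero, keep the position
    return matrix


def encode_protein(
    sequence: str,
    vocab: TokenVocabulary | None = None,
    max_len: int = PROTEIN_MAX_LEN,
    unknown: str = "zero",
) -> ProteinEncoding:
    """Encode an amino-acid string into a one-hot matrix.

    Sequences longer than ``max_len`` residues are truncated to the
    N-terminal prefix; shorter ones are padded at the end with all-zero
    columns.  Input is upper-cased before lookup.
    """
    if not sequence:
        raise ValueError("protein sequence must be non-empty")
    if vocab is None:
        vocab = protein_vocabulary()
    tokens = list(sequence.upper())
    matrix = _encode_tokens(tokens, vocab, max_len, unknown)
    return ProteinEncoding(matrix=matrix, true_length=min(len(tokens), max_len))


def tokenize_smiles(smiles: str, vocab: TokenVocabulary | None = None) -> list[str]:
    """Deterministic greedy (longest-match) SMILES tokenization.

    Multi-character tokens in the vocabulary (``Cl``, ``Br``) are matched
    before single characters; characters not in the vocabulary are emitted
    as single-character tokens (the encoder decides their fate).
    """
    if not smiles:
        raise ValueError("SMILES string must be non-empty")
    if vocab is None:
        vocab = smiles_vocabulary()
    out: list[str] = []
    i, n = 0, len(smiles)
    max_tok = vocab._max_token_len
    while i < n:
        for width in range(min(max_tok, n - i), 1, -1):
            cand = smiles[i : i + width]
            if cand in vocab:
                out.append(cand)
                i += width
                break
        else:
            out.append(smiles[i])
            i += 1
    return out


def encode_smiles(
    smiles: str,
    vocab: TokenVocabulary | None = None,
    max_len: int = LIGAND_MAX_LEN,
    unknown: str = "zero",
) -> LigandEncoding:
    """Tokenize and one-hot encode a SMILES string (64 x ``max_len``)."""
    if vocab is None:
        vocab = smiles_vocabulary()
    tokens = tokenize_smiles(smiles, vocab)
    matrix = _encode_tokens(tokens, vocab, max_len, unknown)
    return LigandEncoding(matrix=matrix, true_length=min(len(tokens), max_len))


def _decode_columns(matrix: np.ndarray, true_length: int, vocab: TokenVocabulary, placeholder: str) -> list[str]:
    tokens = []
    for pos in range(true_length):
        col = matrix[:, pos]
        hits = np.flatnonzero(col)
        if hits.size == 0:
            tokens.append(placeholder)
        elif hits.size == 1:
            tokens.append(vocab.tokens[hits[0]])
        else:
            raise ValueError(f"column {pos} has {hits.size} set rows; not one-hot")
    return tokens


def decode_protein(encoding: ProteinEncoding, vocab: TokenVocabulary | None = None) -> str:
    """Inverse of :func:`encode_protein` for in-vocabulary inputs ('X' for zero columns)."""
    if vocab is None:
        vocab = protein_vocabulary()
    return "".join(_decode_columns(encoding.matrix, encoding.true_length, vocab, "X"))


def decode_smiles(encoding: LigandEncoding, vocab: TokenVocabulary | None = None) -> str:
    """Inverse of :func:`encode_smiles` for in-vocabulary inputs ('?' for zero columns)."""
    if vocab is None:
        vocab = smiles_vocabulary()
    return "".join(_decode_columns(encoding.matrix, encoding.true_length, vocab, "?"))
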