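"""SMILES tokenization: vocabulary, integer encoding, decoding.

The token inventory is the standard SMILES regex-tokenizer family:
bracket atoms ``[...]`` as single tokens, two-character halogens Cl/Br,
organic-subset atoms, ring-closure digits and ``%nn`` pairs, and
bond/branch punctuation. Four special tokens occupy the low ids:
PAD=0, BOS=1, EOS=2, UNK=3. Encoded sequences carry BOS/EOS framing and
must fit the decoder context window (102 positions by default); strings
that exceed the budget are rejected rather than truncated, since a
truncated SMILES is chemical garbage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, TokenizationError

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)

DEFAULT_CONTEXT = 102

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]"        # bracket atoms, single token
    r"|Br|Cl"             # two-character halogens
    r"|%\d{2}"            # two-digit ring closures
    r"|[BCNOPSFIbcnops]"  # organic subset
    r"|[0-9]"             # ring-closure digits
    r"|[=#\-\+\(\)\.\\/:~@\*\$])"  # bonds, branches, misc
)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; reject uncovered characters."""
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(smiles):
        if m.start() != pos:
            raise TokenizationError(
                f"untokenizable characters {smiles[pos:m.start()]!r} in {smiles!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"untokenizable tail {smiles[pos:]!r} in {smiles!r}"
        )
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> id mapping; specials first, then lexicographic."""

    tokens: tuple[str, ...]
    token_to_id: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if tuple(self.tokens[: len(SPECIALS)]) != SPECIALS:
            raise ConfigurationError("vocabulary must start with the special tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise ConfigurationError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "token_to_id", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def id_of(self, token: str) -> int:
        return self.token_to_id[token]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text().splitlines()
        return cls(tuple(lines))


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Token inventory of a corpus: specials + observed tokens, sorted.

    Deterministic regardless of corpus order; every corpus string encodes
    without UNK under the result.
    """
    observed: set[str] = set()
    n = 0
    for smiles in corpus:
        observed.update(tokenize(smiles))
        n += 1
    if n == 0:
        raise ConfigurationError("empty corpus")
    return Vocabulary(SPECIALS + tuple(sorted(observed)))


def encode(
    smiles: str, vocab: Vocabulary, context: int = DEFAULT_CONTEXT
) -> list[int]:
    """BOS + token ids + EOS. Strict on unknown tokens and over-length."""
    tokens = tokenize(smiles)
    if len(tokens) + 2 > context:
        raise TokenizationError(
            f"{len(tokens)} payload tokens exceed the {context}-position budget"
        )
    ids = [vocab.bos_id]
    for t in tokens:
        if t not in vocab.token_to_id:
            raise TokenizationError(f"token {t!r} not in vocabulary (strict mode)")
        ids.append(vocab.id_of(t))
    ids.append(vocab.eos_id)
    return ids


def decode(ids: Sequence[int], vocab: Vocabulary, strict: bool = True) -> str:
    """Inverse of :func:`encode`.

    Strict mode demands BOS framing and a terminating EOS with no interior
    PAD. Lenient mode (for sampled sequences) concatenates whatever payload
    tokens precede the first EOS/PAD, tolerating a missing EOS.
    """
    ids = list(ids)
    if not ids or ids[0] != vocab.bos_id:
        if strict:
            raise TokenizationError("sequence does not start with BOS")
    else:
        ids = ids[1:]
    payload: list[str] = []
    terminated = False
    for i in ids:
        if i == vocab.eos_id:
            terminated = True
            break
        if i == vocab.pad_id:
            if strict:
                raise TokenizationError("interior PAD in sequence")
            break
        if i == vocab.unk_id and strict:
            raise TokenizationError("UNK in sequence")
        if not 0 <= i < len(vocab):
            raise TokenizationError(f"id {i} outside vocabulary")
        payload.append(vocab.tokens[i])
    if strict and not terminated:
        raise TokenizationError("sequence missing EOS")
    return "".join(payload)


def encode_corpus(
    corpus: Sequence[str], vocab: Vocabulary, context: int = DEFAULT_CONTEXT
) -> tuple[list[list[int]], int]:
    """Encode many strings, dropping over-length ones; returns (sequences, n_dropped)."""
    out, dropped = [], 0
    for s in corpus:
        try:
            out.append(encode(s, vocab, context))
        except TokenizationError as exc:
            if "budget" in str(exc):
                dropped += 1
            else:
                raise
    return out, dropped
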