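"""Cleaning, segmentation, indexing, and padding of subjective-note text.

The subjective component of a progress note mixes Chinese and English.
The pipeline lowercases Latin text, deletes numerals, replaces punctuation
and symbols (half-width and full-width) with spaces, segments CJK runs
against a lexicon, and encodes each document as a fixed-length vector of
token indices (default length 218) with trailing zero padding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "CleaningRules",
    "Vocabulary",
    "DocumentVector",
    "clean_text",
    "segment",
    "build_vocabulary",
    "encode_pad",
    "decode",
    "register_segmenter",
    "get_segmenter",
    "read_lexicon",
    "write_lexicon",
]

PAD_INDEX = 0
OOV_INDEX = 1

# CJK unified ideographs (base + extension A). The synthetic generator and
# realistic clinical notes stay inside the base block.
_CJK_RANGES = ((0x4E00, 0x9FFF), (0x3400, 0x4DBF))


def _is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in _CJK_RANGES)


@dataclass(frozen=True)
class CleaningRules:
    """Character-level filters applied before segmentation.

    Defaults reproduce the canonical pipeline: only CJK characters and
    lowercase Latin letters survive, separated by single spaces.  Numerals
    are deleted in place (no space inserted); punctuation and symbols —
    half-width or full-width — become spaces.  The strip flags can be
    turned off to retain numerals/symbols as future-work experiments.
    """

    lowercase_latin: bool = True
    strip_numerals: bool = True
    strip_punctuation_and_symbols: bool = True


def clean_text(raw: str, rules: CleaningRules = CleaningRules()) -> str:
    """Apply the cleaning rules to one document.  Total and idempotent."""
    out: list[str] = []
    for ch in raw:
        if _is_cjk(ch):
            out.append(ch)
        elif "a" <= ch <= "z":
            out.append(ch)
        elif "A" <= ch <= "Z":
            out.append(ch.lower() if rules.lowercase_latin else ch)
        elif ch.isdigit():
            if not rules.strip_numerals:
                out.append(ch)
            # deleted in place: "38" vanishes without splitting its word
        elif ch.isspace():
            out.append(" ")
        else:
            if rules.strip_punctuation_and_symbols:
                out.append(" ")
            else:
                out.append(ch)
    return re.sub(r" +", " ", "".join(out)).strip()


# ---------------------------------------------------------------------------
# Segmentation

Segmenter = Callable[[str, frozenset], list[str]]
_SEGMENTERS: dict[str, Segmenter] = {}


def register_segmenter(name: str, fn: Segmenter) -> None:
    """Register an alternative segmenter (e.g. an adapter around an
    external CJK tokenizer).  The built-in ``"greedy"`` segmenter is the
    deterministic default."""
    _SEGMENTERS[name] = fn


def get_segmenter(name: str = "greedy") -> Segmenter:
    try:
        return _SEGMENTERS[name]
    except KeyError:
        raise KeyError(f"unknown segmenter {name!r}; registered: {sorted(_SEGMENTERS)}")


def _greedy_segment(cleaned: str, lexicon: frozenset) -> list[str]:
    tokens: list[str] = []
    max_word = max((len(w) for w in lexicon), default=1)
    for run in cleaned.split():
        if not _is_cjk(run[0]) and not any(_is_cjk(c) for c in run):
            tokens.append(run)
            continue
        # A run may interleave CJK and Latin characters; split into script
        # runs first, then dictionary-match the CJK spans.
        i = 0
        n = len(run)
        while i < n:
            if _is_cjk(run[i]):
                j = i
                while j < n and _is_cjk(run[j]):
                    j += 1
                span = run[i:j]
                p = 0
                while p < len(span):
                    for width in range(min(max_word, len(span) - p), 1, -1):
                        if span[p : p + width] in lexicon:
                            tokens.append(span[p : p + width])
                            p += width
                            break
                    else:
                        tokens.append(span[p])  # single-character fallback
                        p += 1
                i = j
            else:
                j = i
                while j < n and not _is_cjk(run[j]):
                    j += 1
                tokens.append(run[i:j])
                i = j
    return tokens


register_segmenter("greedy", _greedy_segment)


def segment(
    cleaned: str,
    lexicon: Iterable[str] = (),
    *,
    segmenter: str = "greedy",
) -> list[str]:
    """Tokenize cleaned text.

    Latin runs split on whitespace; CJK runs are segmented by greedy
    longest-match against ``lexicon``, falling back to single characters.
    Deterministic for a fixed lexicon.
    """
    lex = lexicon if isinstance(lexicon, frozenset) else frozenset(lexicon)
    return get_segmenter(segmenter)(cleaned, lex)


# ---------------------------------------------------------------------------
# Vocabulary and document vectors


class Vocabulary:
    """Token -> index table with reserved indices 0 (padding) and 1 (OOV)."""

    def __init__(self, token_to_index: dict[str, int]):
        self.token_to_index = token_to_index
        self._index_to_token: dict[int, str] | None = None

    @property
    def size(self) -> int:
        """Distinct tokens plus the two reserved indices."""
        return len(self.token_to_index) + 2

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, OOV_INDEX)

    def token(self, index: int) -> str | None:
        if self._index_to_token is None:
            self._index_to_token = {i: t for t, i in self.token_to_index.items()}
        return self._index_to_token.get(index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def __len__(self) -> int:
        return self.size

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for token, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{token}\t{idx}\n")

    @classmethod
    def read(cls, path: str | Path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                token, idx = line.rstrip("\n").split("\t")
                mapping[token] = int(idx)
        return cls(mapping)


@dataclass(frozen=True)
class DocumentVector:
    """Fixed-length index sequence with trailing zero padding."""

    indices: np.ndarray  # shape (max_len,), int32
    n_real_tokens: int

    def __post_init__(self):
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int32))


def build_vocabulary(corpus: Sequence[Sequence[str]]) -> Vocabulary:
    """Assign indices >= 2 to distinct tokens in first-appearance order."""
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    mapping: dict[str, int] = {}
    next_index = 2
    for doc in corpus:
        for token in doc:
            if token not in mapping:
                mapping[token] = next_index
                next_index += 1
    return Vocabulary(mapping)


def encode_pad(tokens: Sequence[str], vocab: Vocabulary, max_len: int = 218) -> DocumentVector:
    """Map tokens to indices, truncate to the first ``max_len``, post-pad
    with zeros.  Unknown tokens map to the reserved OOV index 1."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept = tokens[:max_len]
    indices = np.zeros(max_len, dtype=np.int32)
    for i, token in enumerate(kept):
        indices[i] = vocab.index(token)
    return DocumentVector(indices=indices, n_real_tokens=len(kept))


def decode(vector: DocumentVector, vocab: Vocabulary) -> list[str]:
    """Recover the in-vocabulary token prefix of a document vector."""
    out: list[str] = []
    for idx in vector.indices[: vector.n_real_tokens]:
        token = vocab.token(int(idx))
        out.append(token if token is not None else "<oov>" if idx == OOV_INDEX else "<pad>")
    return out


def read_lexicon(path: str | Path) -> frozenset:
    """One token per line, UTF-8."""
    words = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip()
            if word:
                words.append(word)
    return frozenset(words)


def write_lexicon(tokens: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for token in sorted(tokens):
            fh.write(token + "\n")
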