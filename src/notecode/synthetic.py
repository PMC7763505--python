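"""Seeded synthetic bilingual medical-record corpora.

The real subjective-component corpus this pipeline targets is private, so
the generator emulates its statistical structure: single-label ICD-9-coded
free-text documents mixing Chinese and lowercase-English tokens, a
long-tailed class distribution, right-skewed document lengths, and
class-conditional signature keywords (the generative premise: a handful of
complaint words — "intermittent", "tachypnea", ... — carry the diagnostic
signal).  Every record carries the full 11-field progress-note schema;
only the subjective text and the ICD-9 code are non-placeholder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .hierarchy import HierarchyTable, load_hierarchy, parse_code

__all__ = ["CorpusSpec", "MedicalRecord", "generate_corpus", "default_benchmark_spec",
           "RECORD_FIELDS"]

RECORD_FIELDS = (
    "inpatient_id", "date", "time", "record_id", "author", "subject",
    "icd9_code", "subjective", "objective", "assessment", "plan",
)


@dataclass(frozen=True)
class MedicalRecord:
    """One progress-note row (11 fields); the pipeline consumes
    (subjective, icd9_code)."""

    inpatient_id: str
    date: str
    time: str
    record_id: str
    author: str
    subject: str
    icd9_code: str
    subjective: str
    objective: str
    assessment: str
    plan: str


def _default_code_set() -> list[str]:
    # 20 codes over 9 chapters, with sibling full codes sharing a category
    # (518.81/518.82, 770.6/770.8, 250.0/250.4) and same-chapter pairs in
    # different blocks, so all four match levels separate.
    return [
        "518.81", "518.82", "486", "466.0",
        "770.8", "770.6", "779.3",
        "431", "434.91", "410.9", "428.0",
        "250.0", "250.4", "276.5",
        "008.8", "038.9",
        "599.0", "780.6", "553.3", "820.8",
    ]


@dataclass(frozen=True)
class CorpusSpec:
    """Generation parameters for one synthetic corpus.

    ``class_weights`` defaults to a geometric long tail (ratio 0.8) over
    ``code_set``.  Each document draws its length from a clipped negative
    binomial on [1, max_len] (right-skewed, mean ~25 words); each token
    slot emits one of the class's signature tokens with probability
    ``signature_injection_rate`` and a background token otherwise, CJK
    with probability ``chinese_fraction``.
    """

    n_records: int = 2000
    code_set: Sequence[str] = field(default_factory=_default_code_set)
    class_weights: Sequence[float] | None = None  # None -> geometric(0.8)
    signature_tokens_per_class: int = 5
    signature_injection_rate: float = 0.8
    background_vocab_size: int = 500
    mean_length: float = 25.0
    length_dispersion: float = 2.0
    max_len: int = 218
    chinese_fraction: float = 0.5
    seed: int = 0

    def resolved_weights(self) -> np.ndarray:
        if self.class_weights is None:
            w = 0.8 ** np.arange(len(self.code_set))
        else:
            w = np.asarray(self.class_weights, dtype=float)
        return w / w.sum()

    def validate(self, table: HierarchyTable | None = None) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        if len(self.code_set) < 2:
            raise ValueError("code_set needs at least 2 codes")
        if len(set(self.code_set)) != len(self.code_set):
            raise ValueError("code_set entries must be distinct")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if len(w) != len(self.code_set):
                raise ValueError("class_weights length must equal code_set length")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-8):
                raise ValueError("class_weights must be non-negative and sum to 1")
        if not (0.0 <= self.signature_injection_rate <= 1.0):
            raise ValueError("signature_injection_rate must be a probability")
        if not (0.0 <= self.chinese_fraction <= 1.0):
            raise ValueError("chinese_fraction must be a probability")
        if self.max_len < 1 or self.mean_length < 1:
            raise ValueError("max_len and mean_length must be >= 1")
        table = table if table is not None else load_hierarchy()
        for code in self.code_set:
            parse_code(code, table)  # raises ICD9ParseError if invalid


# Fixed CJK codepoint pool for pseudo-words; real common-use characters so
# the cleaning rules keep them.
_CJK_POOL_START = 0x4E00
_CJK_POOL_SIZE = 1200
_LATIN_ONSETS = ["b", "c", "d", "f", "g", "h", "j", "k", "l", "m",
                 "n", "p", "r", "s", "t", "v", "w", "z", "ch", "sh"]
_LATIN_NUCLEI = ["a", "e", "i", "o", "u", "ai", "ou", "ea"]


def _latin_word(rng: np.random.Generator, n_syllables: int) -> str:
    parts = []
    for _ in range(n_syllables):
        parts.append(_LATIN_ONSETS[rng.integers(len(_LATIN_ONSETS))])
        parts.append(_LATIN_NUCLEI[rng.integers(len(_LATIN_NUCLEI))])
    return "".join(parts)


def _cjk_word(rng: np.random.Generator) -> str:
    a, b = rng.integers(_CJK_POOL_SIZE, size=2)
    return chr(_CJK_POOL_START + int(a)) + chr(_CJK_POOL_START + int(b))


def _token_pool(rng: np.random.Generator, n: int, chinese_fraction: float,
                taken: set) -> list[str]:
    """n distinct tokens, CJK 2-character pseudo-words or Latin syllables."""
    pool: list[str] = []
    while len(pool) < n:
        if rng.random() < chinese_fraction:
            word = _cjk_word(rng)
        else:
            word = _latin_word(rng, int(rng.integers(2, 4)))
        if word not in taken:
            taken.add(word)
            pool.append(word)
    return pool


def _is_cjk_token(token: str) -> bool:
    return ord(token[0]) >= _CJK_POOL_START


def generate_corpus(
    spec: CorpusSpec, table: HierarchyTable | None = None
) -> tuple[list[MedicalRecord], frozenset]:
    """Generate records plus the CJK lexicon needed to re-segment them.

    Deterministic: the same spec (including seed) yields byte-identical
    records.  Adjacent CJK tokens are concatenated without spaces, as in
    real Chinese text; the returned lexicon lets greedy longest-match
    segmentation reconstruct the token sequence exactly.
    """
    spec.validate(table)
    rng = np.random.default_rng(spec.seed)
    weights = spec.resolved_weights()
    codes = list(spec.code_set)

    taken: set = set()
    background = _token_pool(rng, spec.background_vocab_size, spec.chinese_fraction, taken)
    signatures = {
        code: _token_pool(rng, spec.signature_tokens_per_class, spec.chinese_fraction, taken)
        for code in codes
    }
    # mildly Zipf-weighted background usage
    bg_weights = 1.0 / np.arange(1, len(background) + 1)
    bg_weights /= bg_weights.sum()

    p_nb = spec.length_dispersion / (spec.length_dispersion + spec.mean_length - 1.0)

    records: list[MedicalRecord] = []
    for i in range(spec.n_records):
        ci = int(rng.choice(len(codes), p=weights))
        code = codes[ci]
        length = int(np.clip(rng.negative_binomial(spec.length_dispersion, p_nb) + 1,
                             1, spec.max_len))
        tokens: list[str] = []
        for _ in range(length):
            if rng.random() < spec.signature_injection_rate:
                sig = signatures[code]
                tokens.append(sig[int(rng.integers(len(sig)))])
            else:
                tokens.append(background[int(rng.choice(len(background), p=bg_weights))])
        pieces: list[str] = []
        prev_cjk = False
        for token in tokens:
            cjk = _is_cjk_token(token)
            if pieces and not (cjk and prev_cjk):
                pieces.append(" ")
            pieces.append(token)
            prev_cjk = cjk
        subjective = "".join(pieces)
        records.append(MedicalRecord(
            inpatient_id=f"P{i:06d}",
            date="2017-01-01",
            time=f"{i % 24:02d}:00",
            record_id=f"R{i:06d}",
            author=f"author{i % 7}",
            subject="progress note",
            icd9_code=code,
            subjective=subjective,
            objective="-",
            assessment="-",
            plan="-",
        ))

    lexicon = frozenset(
        t for toks in ([*background, *(w for sig in signatures.values() for w in sig)],)
        for t in toks if _is_cjk_token(t)
    )
    return records, lexicon


def default_benchmark_spec(seed: int = 20170) -> CorpusSpec:
    """The canonical benchmark: 20 codes over 9 chapters (with sibling
    full-code pairs such as 518.81/518.82 so every match level is
    exercised), 2,000 records, geometric long-tail class weights,
    injection rate 0.8."""
    return CorpusSpec(seed=seed)


def signature_tokens(spec: CorpusSpec) -> dict[str, list[str]]:
    """Regenerate the class -> signature-token map for a spec (same stream
    position as generate_corpus), for oracle classifiers in analyses."""
    rng = np.random.default_rng(spec.seed)
    taken: set = set()
    _token_pool(rng, spec.background_vocab_size, spec.chinese_fraction, taken)
    return {
        code: _token_pool(rng, spec.signature_tokens_per_class, spec.chinese_fraction, taken)
        for code in spec.code_set
    }
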