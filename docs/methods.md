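# Methods

## Problem setting

Each inpatient progress note is a SOAP record with eleven fields; only
two enter the pipeline: the free-text *subjective component* (the
patient's self-reported complaints, mixing Chinese and lowercase
English) and the single ICD-9 code the physician assigned. The task is
single-label multiclass classification of the code from the subjective
text alone, scored not only by exact-code accuracy but at all four
levels of the ICD-9 hierarchy, because a prediction that lands in the
right chapter or block retains clinical value even when the full code is
wrong.

## The ICD-9 hierarchy table

ICD-9 organises diagnoses as chapter → block → three-digit category →
full code. The bundled resource (`data/icd9_hierarchy.tsv`, tab-delimited,
columns `kind, id, label, range_start, range_end`) encodes 17 disease
chapters whose category ranges partition 001–999, the E and V
supplementary classifications with their own block lists, and 135
disease blocks. The block inventory is this package's own curation of
the ICD-9 tabular list: the published tabular-list sections are fewer
than 135, so the broadest sections are subdivided at rubric-group
boundaries (for example syphilis 090–097 vs other venereal diseases
098–099, or intracranial hemorrhage and occlusion 430–434 vs other
cerebrovascular disease 435–438) to reach the 135-block layout used by
Taiwan-adapted ICD-9 coding. Block membership only matters through the
Block Match criterion; all the worked code pairs exercised in the tests
(518.81/518.82 sharing block 510–519; 770.8 vs 431 in different
chapters) are invariant to this subdivision.

Parsing is strict: codes are normalized strings (`410.0` ≠ `410`;
E-codes take a four-character category), and a well-formed category that
no block claims is an error rather than a silently guessed chapter —
tolerating it would corrupt every downstream metric. Chapter/block
resolution uses a bisect over sorted range starts; the test suite checks
it against a brute-force linear scan of every range.

Match criteria: two codes match at CHAPTER/BLOCK/CATEGORY/FULL when
their group labels at that level are equal. Because the levels nest,
agreement at a finer level implies agreement at every coarser one
(downward closure); `match_level` returns the finest agreeing level.

## Text preprocessing

Cleaning keeps only CJK characters and lowercase Latin letters:
uppercase is lowered, numerals are deleted *in place* (so "38°C" yields
"c", not a stray token boundary), and all other characters — half-width
or full-width punctuation and symbols — become spaces, which then
collapse. The function is total and idempotent. Retention of numerals
and symbols is exposed as `CleaningRules` flags (off by default).

Segmentation splits Latin runs on whitespace and segments CJK runs by
deterministic greedy longest-match against a lexicon, emitting
single-character tokens where no lexicon entry extends. The segmenter is
pluggable (`register_segmenter`) so an external CJK tokenizer can be
adapted in; the built-in one is the default because evaluation requires
run-to-run determinism and no external dictionary state.

Encoding assigns indices ≥ 2 in first-appearance order (0 = padding,
1 = out-of-vocabulary, kept distinct because conflating OOV with padding
deletes signal at inference time), truncates to the first `max_len`
tokens, and post-pads with zeros. `max_len` defaults to 218 — the
documented maximum subjective-component length in the corpora this
pipeline targets — and should be set to the observed maximum on other
corpora.

## The convolutional classifier

Layer stack: embedding lookup (vocab × k, trainable, random normal
σ = 0.1) → 1-D convolution over word windows (window w × k, stride 1,
F filters, He-scaled init) → ReLU → global max pooling over positions →
inverted dropout → batch normalization (momentum 0.9, ε = 1e-5) → dense
softmax. Defaults: k = 400, w = 5, F = 128, dropout 0.5, Adam at 1e-3,
100 epochs, batch 64. Loss is categorical cross-entropy (forced by the
single-label softmax design). The filter count and learning rate are the
conventional operating points for this architecture family; both are
config fields.

Numerical/design choices worth recording:

- **Padding.** Convolution runs over the full padded sequence (no
  masking). The padding embedding (row 0) is initialized at zero and its
  gradient is zeroed every step, so the padding tail contributes only
  bias-driven activations that are identical for any amount of padding;
  predictions therefore do not depend on padding layout.
- **Output layer initialized at zero.** An untrained model outputs the
  exact uniform distribution (useful as a neutral baseline and for
  tie-break tests); gradients still flow because the pooled features are
  nonzero. Ties in arg-max resolve to the lowest class index.
- **Determinism.** One config seed drives initialization, epoch
  shuffling, and dropout masks through a single `numpy` Generator;
  training twice with the same seed gives identical loss curves.
  Inference disables dropout and uses batch-norm running statistics, so
  repeated predictions agree exactly.
- **Divergence.** A non-finite loss aborts training with a diagnostic
  suggesting a smaller learning rate rather than returning NaN metrics.
- The network is implemented directly in numpy with handwritten
  backpropagation. The stack is small and fixed; an im2col view feeds
  the convolution to BLAS, which trains the benchmark sizes in minutes
  on one CPU and keeps the package dependency-light and reproducible.

## Evaluation protocol

`cross_validate` runs the preprocessing once over the whole corpus
(vocabulary included — mirroring the single-corpus protocol this
pipeline follows), then k-fold CV (default 10). Folds are stratified by
full code for classes with at least k members (round-robin after a
seeded shuffle); rarer records are dealt unstratified to the smallest
folds. Classes that never appear in a training fold are legal — the
model simply cannot predict them, which depresses recall, as it should.
Per-fold models derive their seeds from the CV seed.

Metrics are computed on the pooled prediction pairs (per-fold mean ± sd
accuracy is reported alongside). Precision/recall/F1 use support-weighted
averaging by default — the convention under which multiclass recall is
identically accuracy, and groups that are predicted but never actual
contribute precision 0 with weight 0; macro and micro averaging are
options. F1 is the support-weighted mean of per-group F1 scores (not the
harmonic mean of the aggregated precision and recall; both conventions
exist, the first is the default here). The majority baseline at a level
is (largest actual group)/(total). Confusion matrices rank the top-N
groups by actual-label frequency (ties lexicographic), absorb
out-of-top-N predictions into an explicit "other" column, then normalize
each supported row to sum to 1.

## Synthetic corpus generator

The generator emulates the statistical structure of a private bilingual
EMR corpus, not its language:

- **Classes.** Default 20 codes spanning 9 chapters, including sibling
  full codes sharing a category (518.81/518.82, 770.6/770.8,
  250.0/250.4) and same-chapter/different-block pairs, so all four match
  levels separate. Class weights default to a geometric long tail with
  ratio 0.8 — the documented corpora are strongly long-tailed, and a
  geometric profile is the simplest one-parameter emulation; no fidelity
  to any particular printed distribution is claimed.
- **Documents.** Length ~ 1 + NegativeBinomial(r = 2, mean ≈ 25),
  clipped to [1, max_len = 218]: right-skewed with most notes a few
  dozen words and a long upper tail, matching how subjective components
  distribute. Each token slot emits one of the class's
  `signature_tokens_per_class = 5` signature words with probability
  `signature_injection_rate = 0.8`, else a background token (500-word
  pool, mildly Zipf-weighted). The injection rate is the separability
  dial: at 0.0 documents carry no class signal by construction.
- **Bilingual form.** Tokens are CJK with probability 0.5 (two-character
  pseudo-words from a fixed pool of real CJK codepoints) or Latin
  syllable strings. Adjacent CJK tokens are concatenated without spaces,
  as in real Chinese text, and the companion lexicon of all CJK
  pseudo-words is returned with the corpus so greedy longest-match
  segmentation reconstructs the token stream exactly — making the whole
  preprocessing stage round-trip-testable.
- The nine unused record fields are deterministic functions of the
  record index, so corpora are byte-stable fixtures.

What passing tests on this corpus do **not** show: performance on real
clinical language (no grammar, no synonymy, no misspellings, no
segmentation ambiguity against a real dictionary, no label noise), and
no E/V codes in the default code set (the parser and evaluator support
them; the default corpus uses disease chapters only).

## Benchmark sizes

The reference benchmark is 2,000 records over the 20 default codes with
injection rate 0.8, evaluated by 10-fold CV with a reduced network
(embedding 48, 32 filters, 10 epochs) that this corpus size trains
fully; the separability sweep uses 600-record corpora at rates
0.0/0.4/0.8 with 6 epochs. On these conditions full-code CV accuracy is
≥ 0.9 and rises monotonically with the injection rate — a parameter
recovery check of the whole pipeline, not a claim about hospital-scale
data, where thousands of classes and far weaker signal make absolute
numbers incomparable.

## Known limitations

- The greedy segmenter has no statistical disambiguation; on real
  Chinese clinical text a trained tokenizer with a medical dictionary
  would segment better (the adapter hook exists for that reason).
- Vocabulary is built before the CV split, so fold models see test-fold
  *tokens* (not labels); this mirrors the protocol the pipeline
  reproduces but slightly flatters OOV behavior relative to a strict
  train-only vocabulary.
- Single-label prediction only; notes with multiple plausible codes are
  outside scope, as is any ICD-10 mapping.
- Batch normalization uses running statistics at inference; with very
  small training sets those statistics are noisy, which is one reason
  the benchmark uses ≥ hundreds of records.
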