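"""k-fold cross-validation and four-level hierarchical match evaluation.

A prediction is scored at each of the four ICD-9 match levels by
projecting both the predicted and the actual code to that level's group
label (chapter id, block id, three-digit category, or full code) and
comparing.  Per-level precision/recall/F1 are support-weighted by default,
which makes multiclass recall coincide exactly with accuracy; the
majority-class baseline is the relative size of the largest actual group
at that level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .hierarchy import (
    HierarchyTable,
    ICD9Components,
    MatchLevel,
    load_hierarchy,
    parse_code,
)
from .model import CNNConfig, TextCNN
from .preprocess import CleaningRules, build_vocabulary, clean_text, encode_pad, segment

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionPair",
    "MetricsRow",
    "ConfusionMatrix",
    "EvaluationReport",
    "stratified_folds",
    "cross_validate",
    "compute_metrics",
    "majority_baseline",
    "normalized_confusion_matrix",
    "full_report",
]


@dataclass(frozen=True)
class PredictionPair:
    predicted: ICD9Components
    actual: ICD9Components
    fold_id: int = 0


@dataclass(frozen=True)
class MetricsRow:
    level: MatchLevel
    recall: float
    precision: float
    f1: float
    accuracy: float
    baseline: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized confusion matrix over the top-N most prevalent
    actual groups; predictions outside the top N fall into "other"."""

    level: MatchLevel
    labels: list[str]          # row groups, most prevalent first
    matrix: np.ndarray         # shape (N, N+1): columns = labels + ["other"]
    supports: np.ndarray       # raw actual counts per row

    @property
    def column_labels(self) -> list[str]:
        return [*self.labels, "other"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("actual\\predicted\t" + "\t".join(self.column_labels) + "\tsupport\n")
            for i, label in enumerate(self.labels):
                cells = "\t".join(f"{v:.6f}" for v in self.matrix[i])
                fh.write(f"{label}\t{cells}\t{int(self.supports[i])}\n")


@dataclass
class EvaluationReport:
    rows: list[MetricsRow]                      # ordered CHAPTER -> FULL
    matrices: dict[MatchLevel, ConfusionMatrix]
    n_pairs: int
    per_fold_accuracy: dict[MatchLevel, tuple[float, float]] = field(default_factory=dict)

    def row(self, level: MatchLevel) -> MetricsRow:
        return next(r for r in self.rows if r.level is level)

    def metrics_tsv(self) -> str:
        lines = ["Rule (Match Criteria)\tRecall\tPrecision\tF1-Score\tAccuracy\tBaseline"]
        for r in self.rows:
            lines.append(
                f"{r.level.display_name}\t{r.recall:.3f}\t{r.precision:.3f}"
                f"\t{r.f1:.3f}\t{r.accuracy:.3f}\t{r.baseline:.3f}"
            )
        return "\n".join(lines) + "\n"

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "metrics.tsv").write_text(self.metrics_tsv(), encoding="utf-8")
        for level, cm in self.matrices.items():
            cm.to_tsv(directory / f"confusion_{level.name.lower()}.tsv")

    def save_heatmaps(self, directory: str | Path) -> None:
        """Optional visual export of the confusion matrices."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for level, cm in self.matrices.items():
            fig, ax = plt.subplots(figsize=(8, 7))
            im = ax.imshow(cm.matrix, cmap="Blues", vmin=0.0, vmax=1.0)
            ax.set_xticks(range(len(cm.column_labels)), cm.column_labels,
                          rotation=90, fontsize=7)
            ax.set_yticks(range(len(cm.labels)), cm.labels, fontsize=7)
            ax.set_xlabel("predicted")
            ax.set_ylabel("actual")
            ax.set_title(f"Normalized confusion matrix ({level.display_name})")
            fig.colorbar(im, ax=ax, fraction=0.046)
            fig.tight_layout()
            fig.savefig(directory / f"confusion_{level.name.lower()}.png", dpi=150)
            plt.close(fig)


# ---------------------------------------------------------------------------
# Folds


def stratified_folds(labels: Sequence[str], k: int, seed: int) -> np.ndarray:
    """Assign each record a fold id in [0, k).

    Classes with at least k members are dealt round-robin across folds
    after a seeded shuffle; records of rarer classes are pooled, shuffled,
    and dealt to the currently smallest folds.  Deterministic for a given
    seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    rng = np.random.default_rng(seed)
    fold_of = np.full(n, -1, dtype=np.int64)
    classes, counts = np.unique(labels, return_counts=True)
    leftover: list[int] = []
    offset = 0
    for cls, count in zip(classes, counts):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        if count >= k:
            for j, record in enumerate(idx):
                fold_of[record] = (offset + j) % k
            offset += len(idx)
        else:
            leftover.extend(int(r) for r in idx)
    if leftover:
        leftover = [leftover[i] for i in rng.permutation(len(leftover))]
        sizes = np.bincount(fold_of[fold_of >= 0], minlength=k)
        for record in leftover:
            f = int(np.argmin(sizes))
            fold_of[record] = f
            sizes[f] += 1
    return fold_of


# ---------------------------------------------------------------------------
# Cross-validation


def cross_validate(
    records: Sequence,
    k: int,
    config: CNNConfig,
    seed: int,
    *,
    table: HierarchyTable | None = None,
    lexicon: Iterable[str] = (),
    rules: CleaningRules = CleaningRules(),
) -> list[PredictionPair]:
    """k-fold cross-validation of the text CNN over medical records.

    The text pipeline (clean, segment, vocabulary, encode/pad) runs over
    the whole corpus; folds are stratified by full code where a class has
    at least k members.  One model is trained per fold on the other k-1
    folds and evaluated on the held-out fold, yielding one
    :class:`PredictionPair` per record.  Classes that never occur in a
    training fold are legal — the model simply cannot predict them.
    """
    table = table if table is not None else load_hierarchy()
    records = list(records)
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")

    actual = [parse_code(r.icd9_code, table) for r in records]
    lex = frozenset(lexicon)
    token_docs = [segment(clean_text(r.subjective, rules), lex) for r in records]
    vocab = build_vocabulary(token_docs)
    X = np.stack([
        encode_pad(doc, vocab, config.max_len).indices for doc in token_docs
    ])

    codes = sorted({a.full_code for a in actual})
    code_index = {c: i for i, c in enumerate(codes)}
    y = np.array([code_index[a.full_code] for a in actual], dtype=np.int64)

    fold_of = stratified_folds([a.full_code for a in actual], k, seed)
    parsed_cache: dict[str, ICD9Components] = {}

    pairs: list[PredictionPair] = []
    for fold in range(k):
        test = fold_of == fold
        train = ~test
        train_y = y[train]
        present = np.unique(train_y)
        # remap to the classes present in this training fold
        remap = {int(c): j for j, c in enumerate(present)}
        fold_codes = [codes[int(c)] for c in present]
        fold_config = CNNConfig(**{**config.__dict__, "seed": (config.seed + 7919 * fold) % (2**31)})
        model = TextCNN(fold_config, vocab.size, fold_codes)
        model.fit(X[train], np.array([remap[int(c)] for c in train_y]))
        predicted_codes = model.predict_labels(X[test])
        for rec_idx, code in zip(np.nonzero(test)[0], predicted_codes):
            if code not in parsed_cache:
                parsed_cache[code] = parse_code(code, table)
            pairs.append(PredictionPair(
                predicted=parsed_cache[code],
                actual=actual[int(rec_idx)],
                fold_id=fold,
            ))
        logger.info("fold %d/%d: %d test records", fold + 1, k, int(test.sum()))
    return pairs


# ---------------------------------------------------------------------------
# Metrics


def _project(pairs: Sequence[PredictionPair], level: MatchLevel):
    y_true = [p.actual.at_level(level) for p in pairs]
    y_pred = [p.predicted.at_level(level) for p in pairs]
    return y_true, y_pred


def compute_metrics(
    pairs: Sequence[PredictionPair],
    level: MatchLevel,
    table: HierarchyTable | None = None,
    *,
    average: str = "weighted",
    baseline: float | None = None,
) -> MetricsRow:
    """Accuracy and averaged precision/recall/F1 at one match level.

    With the default support-weighted averaging, recall equals accuracy
    exactly (each record contributes once with weight 1/n); groups that
    are predicted but never actual get precision 0 with weight 0.
    ``average`` may also be "macro" or "micro".
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    if average not in ("weighted", "macro", "micro"):
        raise ValueError(f"unknown averaging mode {average!r}")
    y_true, y_pred = _project(pairs, level)
    accuracy = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average=average, zero_division=0
    )
    if baseline is None:
        baseline = majority_baseline([p.actual for p in pairs], level, table)
    return MetricsRow(
        level=level,
        recall=float(recall),
        precision=float(precision),
        f1=float(f1),
        accuracy=accuracy,
        baseline=float(baseline),
    )


def majority_baseline(
    actual_codes: Sequence[ICD9Components],
    level: MatchLevel,
    table: HierarchyTable | None = None,
) -> float:
    """Accuracy of always predicting the largest actual group at this
    level: (size of largest group) / (total count)."""
    if len(actual_codes) == 0:
        raise ValueError("actual_codes must be non-empty")
    groups: dict[str, int] = {}
    for c in actual_codes:
        g = c.at_level(level)
        groups[g] = groups.get(g, 0) + 1
    return max(groups.values()) / len(actual_codes)


def normalized_confusion_matrix(
    pairs: Sequence[PredictionPair],
    level: MatchLevel,
    top_n: int = 20,
    table: HierarchyTable | None = None,
) -> ConfusionMatrix:
    """Row-normalized confusion matrix A(i,j)/A(i,*) over the top-N most
    prevalent actual groups (ties broken lexicographically); predicted
    groups outside the top N are absorbed by an "other" column."""
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    y_true, y_pred = _project(pairs, level)
    freq: dict[str, int] = {}
    for t in y_true:
        freq[t] = freq.get(t, 0) + 1
    ranked = sorted(freq, key=lambda g: (-freq[g], g))[:top_n]
    pos = {g: i for i, g in enumerate(ranked)}
    n = len(ranked)
    counts = np.zeros((n, n + 1), dtype=np.float64)
    for t, p in zip(y_true, y_pred):
        if t not in pos:
            continue
        counts[pos[t], pos.get(p, n)] += 1.0
    supports = counts.sum(axis=1)
    matrix = np.zeros_like(counts)
    nonzero = supports > 0
    matrix[nonzero] = counts[nonzero] / supports[nonzero, None]
    return ConfusionMatrix(level=level, labels=ranked, matrix=matrix,
                           supports=supports.astype(np.int64))


def full_report(
    pairs: Sequence[PredictionPair],
    table: HierarchyTable | None = None,
    *,
    top_n: int = 20,
    average: str = "weighted",
) -> EvaluationReport:
    """One metrics row per match level (CHAPTER -> FULL), majority
    baselines from the same pairs' actual labels, confusion matrices, and
    a per-fold accuracy mean +/- sd alongside the pooled metrics."""
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    rows = [compute_metrics(pairs, level, table, average=average) for level in MatchLevel]
    matrices = {
        level: normalized_confusion_matrix(pairs, level, top_n=top_n, table=table)
        for level in MatchLevel
    }
    per_fold: dict[MatchLevel, tuple[float, float]] = {}
    fold_ids = sorted({p.fold_id for p in pairs})
    if len(fold_ids) > 1:
        for level in MatchLevel:
            accs = []
            for f in fold_ids:
                sub = [p for p in pairs if p.fold_id == f]
                y_true, y_pred = _project(sub, level)
                accs.append(float(np.mean([t == p for t, p in zip(y_true, y_pred)])))
            per_fold[level] = (float(np.mean(accs)), float(np.std(accs, ddof=1)))
    return EvaluationReport(rows=rows, matrices=matrices, n_pairs=len(pairs),
                            per_fold_accuracy=per_fold)
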