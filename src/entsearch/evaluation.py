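"""Extraction and ranking quality metrics.

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = harmonic mean of the two;
precision@k compares a ranked entity list against a relevance set.  Metrics
are fractions in [0, 1]; an undefined metric (zero denominator) is reported
as None rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .dictionary import Mention


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise EvaluationError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


def prf1(counts: EvalCounts) -> tuple[float | None, float | None, float | None]:
    """(precision, recall, F1); a metric with a zero denominator is None."""
    if counts.tp == counts.fp == counts.fn == 0:
        raise EvaluationError("all counts are zero; metrics undefined")
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if p is None or r is None or p + r == 0:
        f1 = None
    else:
        f1 = 2 * p * r / (p + r)
    return p, r, f1


def match_mentions(
    gold: Mapping[str, Sequence[Mention]],
    predicted: Mapping[str, Sequence[Mention]],
    mode: str = "concept-level",
    known_docs: Iterable[str] | None = None,
) -> EvalCounts:
    """Accumulate TP/FP/FN per document.

    ``gold`` and ``predicted`` map doc_id -> mentions.  ``strict-span``
    requires an identical (start, end, concept) triple; ``concept-level``
    requires only that the concept appears in the document's gold set (and
    counts each distinct concept once per document).
    """
    if mode not in ("strict-span", "concept-level"):
        raise EvaluationError(f"unknown matching mode {mode!r}")
    if known_docs is not None:
        known = set(known_docs)
        stray = (set(gold) | set(predicted)) - known
        if stray:
            raise EvaluationError(
                f"mentions reference unknown documents: {sorted(stray)}"
            )
    total = EvalCounts()
    for doc_id in sorted(set(gold) | set(predicted)):
        g = list(gold.get(doc_id, ()))
        p = list(predicted.get(doc_id, ()))
        if mode == "strict-span":
            gset = {(m.start, m.end, m.concept_id) for m in g}
            pset = {(m.start, m.end, m.concept_id) for m in p}
        else:
            gset = {m.concept_id for m in g}
            pset = {m.concept_id for m in p}
        tp = len(gset & pset)
        total = total + EvalCounts(tp=tp, fp=len(pset) - tp, fn=len(gset) - tp)
    return total


def precision_at_k(
    ranked: Sequence[str], relevant: Iterable[str], k: int
) -> float:
    """|top-k ∩ relevant| / k, case-insensitive on whitespace-normalized
    names; computed over the available items when fewer than k are ranked."""
    if k < 1:
        raise EvaluationError("k must be >= 1")
    rel = {_norm(name) for name in relevant}
    if not rel:
        raise EvaluationError("relevance set is empty")
    top = [_norm(name) for name in ranked[:k]]
    if len(ranked) < k:
        import warnings
        warnings.warn(
            f"precision@{k} computed over only {len(ranked)} ranked items",
            stacklevel=2,
        )
    hits = sum(1 for name in top if name in rel)
    return hits / k


def _norm(name: str) -> str:
    return " ".join(name.split()).casefold()
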