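"""Scoring of annotation sets: inter-annotator agreement and
precision/recall/F1 with MUC-style partial-positive credit.

A *partial positive* (PP) is a prediction that overlaps a gold entity but
captures only its root term ("kinase" for "Ser/Thr kinase") or misses a
trailing isoform marker ("carboxylesterase" for "carboxylesterase 2").
PPs receive half credit: pp/2 is added to the true positives and pp/2 to
the false negatives (and, by default, to the false positives as well, so
that both precision and recall feel the partial credit).

Agreement is a Jaccard index: exact at the entity level, overlap-based at
the character level (computed over annotated character-position sets).
True negatives never enter any score — annotations are sets of entities,
not token grids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .bioc_io import Annotation

__all__ = [
    "Span", "MatchCounts", "EvalScores", "AgreementResult",
    "classify_matches", "scores", "agreement",
]

#: a trailing token that marks an isoform: a number, a roman numeral, or a
#: single letter optionally followed by digits ("2", "IV", "A", "B1")
_ISOFORM_RE = re.compile(r"^(\d+|[IVXivx]+|[A-Za-z]\d*)$")


@dataclass(frozen=True)
class Span:
    """A minimal annotation: character offset, length and surface text."""

    start: int
    length: int
    text: str

    @property
    def end(self) -> int:
        return self.start + self.length


def _as_span(obj: "Span | Annotation | tuple") -> Span:
    if isinstance(obj, Span):
        return obj
    if isinstance(obj, Annotation):
        return Span(obj.offset, obj.length, obj.text)
    start, length, text = obj
    return Span(int(start), int(length), str(text))


@dataclass(frozen=True)
class MatchCounts:
    """TP/FP/FN tallies plus separately tracked partial positives."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    pp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.pp) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn, self.pp + other.pp)


@dataclass(frozen=True)
class EvalScores:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class AgreementResult:
    jaccard: float
    agreed: int
    a_only: int
    b_only: int


def _tokens(text: str) -> list[str]:
    return text.split()


def _is_partial(pred: Span, gold: Span) -> bool:
    """PP: prediction is the gold's root-term suffix, or the gold minus a
    trailing isoform token."""
    p = _tokens(pred.text.lower())
    g = _tokens(gold.text.lower())
    if not p or not g:
        return False
    # root-term (or longer) suffix of the gold entity
    if len(p) < len(g) and g[-len(p):] == p:
        return True
    # gold minus a trailing isoform marker
    if len(g) == len(p) + 1 and g[:-1] == p and _ISOFORM_RE.match(g[-1]):
        return True
    return False


def classify_matches(
    pred: Iterable["Span | Annotation | tuple"],
    gold: Iterable["Span | Annotation | tuple"],
) -> MatchCounts:
    """Pair predictions with gold annotations and tally TP/FP/FN/PP.

    Pairing is greedy in document order and one-to-one: an exact span match
    is a TP; an overlapping pair in a root-suffix or missing-isoform
    relation is a PP; everything unmatched is FP (prediction side) or FN
    (gold side).
    """
    preds = sorted((_as_span(x) for x in pred), key=lambda s: (s.start, s.end))
    golds = sorted((_as_span(x) for x in gold), key=lambda s: (s.start, s.end))
    used = [False] * len(golds)
    tp = fp = pp = 0
    for p in preds:
        paired = False
        for i, g in enumerate(golds):
            if used[i]:
                continue
            if g.start >= p.end:
                break
            if g.end <= p.start:
                continue
            if (g.start, g.length) == (p.start, p.length):
                tp += 1
                used[i] = True
                paired = True
                break
            if _is_partial(p, g) or _is_partial(g, p):
                pp += 1
                used[i] = True
                paired = True
                break
        if not paired:
            fp += 1
    fn = used.count(False)
    return MatchCounts(tp=tp, fp=fp, fn=fn, pp=pp)


def scores(counts: MatchCounts, pp_in_fp: bool = True) -> EvalScores:
    """Precision, recall and F1 with partial positives split half/half.

    Effective counts are tp' = tp + pp/2 and fn' = fn + pp/2; with
    ``pp_in_fp`` (default) fp' = fp + pp/2 as well, so precision also
    discounts partial matches.  All-zero counts give all-zero scores.
    """
    half = counts.pp / 2.0
    tp = counts.tp + half
    fp = counts.fp + (half if pp_in_fp else 0.0)
    fn = counts.fn + half
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvalScores(precision=precision, recall=recall, f1=f1)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def agreement(
    a: Iterable["Span | Annotation | tuple"],
    b: Iterable["Span | Annotation | tuple"],
    level: str = "entity",
) -> AgreementResult:
    """Jaccard inter-annotator agreement between two annotation sets.

    ``entity`` level counts exact (offset, length, text) matches as agreed;
    ``character`` level computes the Jaccard index of the two annotated
    character-position sets.  Symmetric; empty-vs-empty gives 0.
    """
    spans_a = {(s.start, s.length, s.text) for s in map(_as_span, a)}
    spans_b = {(s.start, s.length, s.text) for s in map(_as_span, b)}
    if level == "entity":
        agreed = len(spans_a & spans_b)
        a_only = len(spans_a - spans_b)
        b_only = len(spans_b - spans_a)
    elif level == "character":
        chars_a: set[int] = set()
        chars_b: set[int] = set()
        for start, length, _ in spans_a:
            chars_a.update(range(start, start + length))
        for start, length, _ in spans_b:
            chars_b.update(range(start, start + length))
        agreed = len(chars_a & chars_b)
        a_only = len(chars_a - chars_b)
        b_only = len(chars_b - chars_a)
    else:
        raise ValueError(f"unknown level {level!r}")
    total = agreed + a_only + b_only
    return AgreementResult(
        jaccard=agreed / total if total else 0.0,
        agreed=agreed,
        a_only=a_only,
        b_only=b_only,
    )


def corpus_agreement(
    pairs: Sequence[tuple[Iterable, Iterable]], level: str = "entity"
) -> AgreementResult:
    """Micro-averaged agreement over (a, b) annotation-set pairs."""
    agreed = a_only = b_only = 0
    for a, b in pairs:
        r = agreement(a, b, level=level)
        agreed += r.agreed
        a_only += r.a_only
        b_only += r.b_only
    total = agreed + a_only + b_only
    return AgreementResult(
        jaccard=agreed / total if total else 0.0,
        agreed=agreed,
        a_only=a_only,
        b_only=b_only,
    )
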