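"""Category-aware event scoring with approximate span and recursive
event matching.

Events are compared as whole trees: types must agree, triggers must match
(exactly, or within the gold span extended by one word on each side in
approximate mode), and there must exist a one-to-one role-preserving
pairing of arguments in which entity arguments match as mentions and event
arguments match recursively down to the flat level.  Precision, recall and
F1 are reported for all events and separately for the nested, overlapping
and flat categories (and per event type); category membership is taken
from the predicted side for precision and the gold side for recall.  An
event that is both nested and overlapping counts in both categories.

Matching is greedy in document order with deterministic tie-breaking; this
approximates, but does not replay, the shared-task server evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .standoff import (
    AnnotatedDocument,
    EventStructure,
    Mention,
    categorize_events,
)

__all__ = ["EvalReport", "match_mention", "match_event", "score", "extend_span"]

CATEGORIES = ("all", "nested", "overlapping", "flat")


def extend_span(text: str, start: int, end: int) -> Tuple[int, int]:
    """Extend a span by one word on each side (the approximate-span rule)."""
    i = start
    while i > 0 and text[i - 1].isspace():
        i -= 1
    while i > 0 and not text[i - 1].isspace():
        i -= 1
    j = end
    while j < len(text) and text[j].isspace():
        j += 1
    while j < len(text) and not text[j].isspace():
        j += 1
    return i, j


def match_mention(
    predicted: Mention,
    gold: Mention,
    mode: str = "approximate",
    text: Optional[str] = None,
) -> bool:
    """Exact: identical offsets and type.  Approximate: same type and the
    predicted span lies within the gold span extended by one word."""
    if predicted.label != gold.label:
        return False
    if mode == "exact":
        return predicted.start == gold.start and predicted.end == gold.end
    if mode != "approximate":
        raise ValueError(f"unknown matching mode {mode!r}")
    if text is None:
        raise ValueError("approximate matching requires the document text")
    lo, hi = extend_span(text, gold.start, gold.end)
    return lo <= predicted.start and predicted.end <= hi


def match_event(
    predicted: EventStructure,
    gold: EventStructure,
    mode: str = "approximate",
    text: Optional[str] = None,
    _memo: Optional[dict] = None,
    _stack: Optional[set] = None,
) -> bool:
    """Recursive whole-tree comparison of two events."""
    memo = _memo if _memo is not None else {}
    stack = _stack if _stack is not None else set()
    key = (predicted.id, gold.id)
    if key in memo:
        return memo[key]
    if key in stack:
        raise ValueError(f"cyclic event structure at {predicted.id}/{gold.id}")
    stack.add(key)
    try:
        ok = _match_event_inner(predicted, gold, mode, text, memo, stack)
    finally:
        stack.discard(key)
    memo[key] = ok
    return ok


def _match_event_inner(predicted, gold, mode, text, memo, stack) -> bool:
    if predicted.event_type != gold.event_type:
        return False
    if not match_mention(predicted.trigger, gold.trigger, mode, text):
        return False
    p_args = list(predicted.arguments)
    g_args = list(gold.arguments)
    if len(p_args) != len(g_args):
        return False

    def backtrack(i: int, used: int) -> bool:
        if i == len(p_args):
            return True
        p_role, p_t = p_args[i]
        for j, (g_role, g_t) in enumerate(g_args):
            if used & (1 << j) or p_role != g_role:
                continue
            if isinstance(p_t, Mention) != isinstance(g_t, Mention):
                continue
            if isinstance(p_t, Mention):
                hit = match_mention(p_t, g_t, mode, text)
            else:
                hit = match_event(p_t, g_t, mode, text, memo, stack)
            if hit and backtrack(i + 1, used | (1 << j)):
                return True
        return False

    return backtrack(0, 0)


@dataclass
class _Cell:
    """Counts for one category: TPs are tallied on the predicted side for
    precision and on the matched gold side for recall, since an event's
    category flags can differ between the two sides (e.g. a matched event
    whose overlapping sibling was not predicted)."""

    tp_predicted: int = 0
    tp_gold: int = 0
    predicted: int = 0
    gold: int = 0

    @property
    def precision(self) -> float:
        return self.tp_predicted / self.predicted if self.predicted else 0.0

    @property
    def recall(self) -> float:
        return self.tp_gold / self.gold if self.gold else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_dict(self) -> dict:
        return {
            "tp_predicted": self.tp_predicted,
            "tp_gold": self.tp_gold,
            "predicted": self.predicted,
            "gold": self.gold,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class EvalReport:
    """P/R/F1 per category and, within each category, per event type."""

    by_category: Dict[str, _Cell] = field(
        default_factory=lambda: {c: _Cell() for c in CATEGORIES}
    )
    by_type: Dict[str, Dict[str, _Cell]] = field(default_factory=dict)
    mode: str = "approximate"

    def cell(self, category: str, event_type: Optional[str] = None) -> _Cell:
        if event_type is None:
            return self.by_category[category]
        return self.by_type.setdefault(
            event_type, {c: _Cell() for c in CATEGORIES}
        )[category]

    def precision(self, category: str = "all") -> float:
        return self.by_category[category].precision

    def recall(self, category: str = "all") -> float:
        return self.by_category[category].recall

    def f1(self, category: str = "all") -> float:
        return self.by_category[category].f1

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "by_category": {
                    c: cell.to_dict() for c, cell in self.by_category.items()
                },
                "by_type": {
                    t: {c: cell.to_dict() for c, cell in cells.items()}
                    for t, cells in self.by_type.items()
                },
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["scope\tcategory\tTP\tpredicted\tgold\tP\tR\tF1"]
        def fmt(scope, cat, cell):
            return (
                f"{scope}\t{cat}\t{cell.tp_predicted}\t{cell.predicted}\t"
                f"{cell.gold}\t{cell.precision:.4f}\t{cell.recall:.4f}\t"
                f"{cell.f1:.4f}"
            )
        for c in CATEGORIES:
            lines.append(fmt("overall", c, self.by_category[c]))
        for t in sorted(self.by_type):
            for c in CATEGORIES:
                lines.append(fmt(t, c, self.by_type[t][c]))
        return "\n".join(lines) + "\n"


def _categories_of(flags: Dict[str, bool]) -> List[str]:
    cats = ["all"]
    if flags["is_nested"]:
        cats.append("nested")
    if flags["is_flat"]:
        cats.append("flat")
    if flags["is_overlapping"]:
        cats.append("overlapping")
    return cats


def score(
    predicted_docs: Iterable[AnnotatedDocument],
    gold_docs: Iterable[AnnotatedDocument],
    mode: str = "approximate",
) -> EvalReport:
    """Greedy maximal matching per document; each gold matches at most once."""
    preds = {d.doc_id: d for d in predicted_docs}
    golds = {}
    for d in gold_docs:
        if d.doc_id in golds:
            raise ValueError(f"duplicate gold document id {d.doc_id!r}")
        golds[d.doc_id] = d
    if len(preds) != len(set(p for p in preds)):
        raise ValueError("duplicate predicted document ids")
    orphans = set(preds) - set(golds)
    if orphans:
        raise ValueError(f"predicted documents without gold: {sorted(orphans)}")

    report = EvalReport(mode=mode)
    for doc_id, gold_doc in sorted(golds.items()):
        pred_doc = preds.get(
            doc_id,
            AnnotatedDocument(doc_id=doc_id, text=gold_doc.text),
        )
        g_flags = categorize_events(gold_doc, inter_sentence=False)
        p_flags = categorize_events(pred_doc, inter_sentence=False)
        memo: dict = {}
        matched_gold: set = set()
        for pev in pred_doc.events:
            p_cats = _categories_of(p_flags[pev.id])
            hit_gold = None
            for gev in gold_doc.events:
                if gev.id in matched_gold:
                    continue
                if match_event(pev, gev, mode, gold_doc.text, memo, set()):
                    hit_gold = gev
                    matched_gold.add(gev.id)
                    break
            for c in p_cats:
                report.cell(c).predicted += 1
                report.cell(c, pev.event_type).predicted += 1
                if hit_gold is not None:
                    report.cell(c).tp_predicted += 1
                    report.cell(c, pev.event_type).tp_predicted += 1
            if hit_gold is not None:
                for c in _categories_of(g_flags[hit_gold.id]):
                    report.cell(c).tp_gold += 1
                    report.cell(c, hit_gold.event_type).tp_gold += 1
        for gev in gold_doc.events:
            for c in _categories_of(g_flags[gev.id]):
                report.cell(c).gold += 1
                report.cell(c, gev.event_type).gold += 1
    return report
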