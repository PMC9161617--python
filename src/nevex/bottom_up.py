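"""Bottom-up event detection over the relation DAG.

Detection starts at level g = 0 (triggers whose arguments are all
entities) and climbs: each trigger's relations are grounded against the
events already predicted at lower levels — one candidate argument per
(relation, sub-event prediction) pair — and the configured detector (SBNN
beam search or EXNN exhaustive classification) decides which structures
become events.  A relation whose event-argument has no predictions is
dropped, so branches above a rejected trigger stop expanding naturally,
while independent chains continue.  Every accepted event keeps its composed
representation so upper levels can consume it as an argument.

The trace records per-group prediction counts and the number of scorer
invocations (action scorings for SBNN, candidate classifications for
EXNN) — the hardware-independent efficiency metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

from .construction import RelationGraph, TemplateSet
from .detection import CandidateArg, Scorer, ScoredEvent, TriggerContext
from .exnn import DEFAULT_MAX_ARGS, detect_trigger_events
from .neural import NeuralCore, tokenize_with_offsets
from .sbnn import SBNNConfig, search_trigger
from .standoff import AnnotatedDocument, EventStructure, Mention

__all__ = [
    "DetectionTrace",
    "TriggerStructures",
    "ground_substructures",
    "detect_document",
    "predictions_to_document",
    "SBNNDetector",
    "EXNNDetector",
]


@dataclass
class TriggerStructures:
    """Candidate structures associated with one trigger at its group."""

    trigger: Mention
    structures: List[List[Tuple[str, Mention]]] = field(default_factory=list)


@dataclass
class DetectionTrace:
    per_group: List[dict] = field(default_factory=list)
    classification_count: int = 0
    stop_reason: str = "completed"

    def to_dict(self) -> dict:
        return {
            "per_group": self.per_group,
            "classification_count": self.classification_count,
            "stop_reason": self.stop_reason,
        }


def ground_substructures(
    trigger: Mention,
    arguments: Sequence[Tuple[str, Mention]],
    predictions_so_far: Dict[str, List[ScoredEvent]],
    event_arg_ids: set,
) -> List[List[CandidateArg]]:
    """Bind every event-argument to each of its predicted sub-events.

    Returns the Cartesian product over the event-arguments' prediction
    lists (entity arguments pass through unchanged); empty if any
    event-argument has zero predictions.
    """
    slots: List[List[CandidateArg]] = []
    for role, arg in arguments:
        source = (trigger.id, role, arg.id)
        if arg.id in event_arg_ids:
            preds = predictions_so_far.get(arg.id, [])
            if not preds:
                return []
            slots.append(
                [
                    CandidateArg(role, arg, p.event_type, source, p, p.repr)
                    for p in preds
                ]
            )
        else:
            slots.append([CandidateArg(role, arg, arg.label, source, None, None)])
    return [list(combo) for combo in product(*slots)]


class _DocumentContext:
    """Per-document sentence encodings for neural detectors."""

    def __init__(self, core: Optional[NeuralCore]):
        self.core = core
        self.doc: Optional[AnnotatedDocument] = None
        self._sent_cache: Dict[int, tuple] = {}
        self._mention_cache: Dict[str, object] = {}

    def start_document(self, doc: Optional[AnnotatedDocument]):
        self.doc = doc
        self._sent_cache.clear()
        self._mention_cache.clear()

    def _sentence(self, offset: int):
        doc = self.doc
        idx = doc.sentence_index(offset)
        if idx is None:
            idx = -1
        if idx not in self._sent_cache:
            start, end = (
                doc.sentence_spans[idx] if idx >= 0 else (0, len(doc.text))
            )
            toks = tokenize_with_offsets(doc.text[start:end])
            vecs = self.core.encode_sentence([t for t, _, _ in toks])
            spans = [(s, e) for _, s, e in toks]
            self._sent_cache[idx] = (start, spans, vecs)
        return self._sent_cache[idx]

    def mention_repr(self, mention: Mention):
        if self.core is None or self.doc is None:
            return None
        if mention.id not in self._mention_cache:
            offset, spans, vecs = self._sentence(mention.start)
            self._mention_cache[mention.id] = self.core.mention_representation(
                mention, spans, vecs, sentence_offset=offset
            )
        return self._mention_cache[mention.id]


class SBNNDetector:
    """Per-trigger beam-search detection bound to a scorer and templates."""

    def __init__(
        self,
        scorer: Scorer,
        templates: TemplateSet,
        config: Optional[SBNNConfig] = None,
        core: Optional[NeuralCore] = None,
    ):
        self.scorer = scorer
        self.templates = templates
        self.config = config or SBNNConfig()
        self.ctx = _DocumentContext(core)

    def start_document(self, doc):
        self.ctx.start_document(doc)
        if hasattr(self.scorer, "begin_sentence"):
            self.scorer.begin_sentence()

    def trigger_context(self, mention: Mention) -> TriggerContext:
        return TriggerContext(mention, self.ctx.mention_repr(mention))

    def entity_repr(self, mention: Mention):
        return self.ctx.mention_repr(mention)

    def detect(self, trigger: TriggerContext, candidate_args) -> List[ScoredEvent]:
        return search_trigger(
            trigger, candidate_args, self.templates, self.config, self.scorer
        )


class EXNNDetector:
    """Exhaustive enumeration + classification bound to a scorer."""

    def __init__(
        self,
        scorer: Scorer,
        templates: TemplateSet,
        threshold: float = 0.5,
        max_args: int = DEFAULT_MAX_ARGS,
        core: Optional[NeuralCore] = None,
    ):
        self.scorer = scorer
        self.templates = templates
        self.threshold = threshold
        self.max_args = max_args
        self.ctx = _DocumentContext(core)

    def start_document(self, doc):
        self.ctx.start_document(doc)
        if hasattr(self.scorer, "begin_sentence"):
            self.scorer.begin_sentence()

    def trigger_context(self, mention: Mention) -> TriggerContext:
        return TriggerContext(mention, self.ctx.mention_repr(mention))

    def entity_repr(self, mention: Mention):
        return self.ctx.mention_repr(mention)

    def detect(self, trigger: TriggerContext, candidate_args) -> List[ScoredEvent]:
        return detect_trigger_events(
            trigger,
            candidate_args,
            self.templates,
            self.threshold,
            self.scorer,
            self.max_args,
        )


def detect_document(
    graph: RelationGraph,
    detector,
    doc: Optional[AnnotatedDocument] = None,
) -> Tuple[List[ScoredEvent], DetectionTrace]:
    """Run group-wise bottom-up detection over a relation graph.

    Groups are processed in ascending level order, triggers within a group
    in text-offset order.  Returns all accepted events (lower levels first)
    and the detection trace.
    """
    trace = DetectionTrace()
    detector.start_document(doc)
    calls_before = detector.scorer.calls
    trigger_ids = {t for (t, _, _) in graph.edges}
    predictions: Dict[str, List[ScoredEvent]] = {}
    all_events: List[ScoredEvent] = []

    for g, group in enumerate(graph.levels):
        group_events = 0
        for tid in group:
            trig = graph.nodes[tid]
            arguments = graph.arguments_of(tid)
            cargs: List[CandidateArg] = []
            for role, arg in arguments:
                source = (tid, role, arg.id)
                if arg.id in trigger_ids:
                    for p in predictions.get(arg.id, []):
                        cargs.append(
                            CandidateArg(role, arg, p.event_type, source, p, p.repr)
                        )
                else:
                    cargs.append(
                        CandidateArg(
                            role, arg, arg.label, source, None,
                            detector.entity_repr(arg) if doc is not None else None,
                        )
                    )
            if cargs:
                ctx = detector.trigger_context(trig)
                evs = detector.detect(ctx, cargs)
            else:
                evs = []
            for ev in evs:
                ev.level = g
            predictions[tid] = evs
            group_events += len(evs)
            all_events.extend(evs)
        trace.per_group.append(
            {"group": g, "triggers": len(group), "events": group_events}
        )
    trace.classification_count = detector.scorer.calls - calls_before

    # bottom-up soundness: every event-argument is itself a prediction
    predicted_keys = {ev.key() for ev in all_events}
    for ev in all_events:
        for _, a in ev.arguments:
            if a.event is not None:
                assert a.event.key() in predicted_keys, (
                    "dangling sub-event reference in prediction"
                )
    return all_events, trace


def predictions_to_document(
    doc: AnnotatedDocument, events: Sequence[ScoredEvent]
) -> AnnotatedDocument:
    """Clone a document with its gold events replaced by predictions."""
    made: Dict[tuple, EventStructure] = {}
    out_events: List[EventStructure] = []
    for i, ev in enumerate(sorted(events, key=lambda e: e.level), start=1):
        k = ev.key()
        if k in made:
            continue
        es = ev.to_event_structure(f"E{i}", made)
        made[k] = es
        out_events.append(es)
    return AnnotatedDocument(
        doc_id=doc.doc_id,
        text=doc.text,
        entities=list(doc.entities),
        triggers=list(doc.triggers),
        events=out_events,
        sentence_spans=list(doc.sentence_spans),
    )
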