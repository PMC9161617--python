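"""Shared types for event detection: grounded candidate arguments, scored
event predictions, and the scorer interface (with an oracle for testing).

A *candidate argument* is one grounded realisation of a pairwise relation:
for entity arguments the relation itself, for event arguments the relation
bound to one specific previously predicted sub-event.  Candidate arguments
remember their source relation so a structure never uses two groundings of
the same relation — which makes relation-level grounding equivalent to the
per-structure Cartesian product over sub-event predictions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

from .standoff import EventStructure, Mention

__all__ = [
    "CandidateArg",
    "ScoredEvent",
    "TriggerContext",
    "Scorer",
    "OracleScorer",
    "AcceptAllScorer",
    "RejectAllScorer",
    "gold_structure_keys",
]

ADD, IGNORE, CONSTRUCT = "ADD", "IGNORE", "CONSTRUCT"


@dataclass(frozen=True)
class CandidateArg:
    """A grounded candidate argument of a trigger."""

    role: str
    mention: Mention  # the argument mention (entity or sub-event trigger)
    arg_type: str  # entity label, or the grounded sub-event's type
    source: Tuple[str, str, str]  # underlying relation (trigger, role, arg)
    event: Optional["ScoredEvent"] = None  # grounding for event arguments
    repr: object = field(default=None, compare=False, hash=False)

    def key(self):
        """Identity of the grounded target (recursive for sub-events)."""
        return self.event.key() if self.event is not None else ("m", self.mention.id)


@dataclass
class ScoredEvent:
    """A predicted event structure with its score and composed representation."""

    trigger: Mention
    event_type: str
    arguments: List[Tuple[str, CandidateArg]]
    score: float
    repr: object = None
    level: int = 0

    def key(self):
        """Recursive structural identity down to flat events."""
        return (
            "e",
            self.trigger.id,
            tuple(sorted((role, arg.key()) for role, arg in self.arguments)),
        )

    def multiset(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(sorted((role, a.arg_type) for role, a in self.arguments))

    def to_event_structure(
        self, eid: str, made: Dict[tuple, EventStructure]
    ) -> EventStructure:
        """Convert to a standoff event, reusing already-converted sub-events."""
        args = []
        for role, a in self.arguments:
            if a.event is not None:
                args.append((role, made[a.event.key()]))
            else:
                args.append((role, a.mention))
        return EventStructure(eid, self.event_type, self.trigger, args)


@dataclass
class TriggerContext:
    """A trigger mention plus its neural representation (None for oracles)."""

    mention: Mention
    repr: object = None


def _gold_key(ev: EventStructure):
    args = []
    for role, t in ev.arguments:
        if isinstance(t, Mention):
            args.append((role, ("m", t.id)))
        else:
            args.append((role, _gold_key(t)))
    return ("e", ev.trigger.id, tuple(sorted(args)))


def gold_structure_keys(events) -> Dict[str, set]:
    """Per trigger id, the recursive structural keys of its gold events."""
    by_trigger: Dict[str, set] = {}
    for ev in events:
        by_trigger.setdefault(ev.trigger.id, set()).add(_gold_key(ev))
    return by_trigger


class Scorer:
    """Scoring interface shared by SBNN and EXNN detectors.

    ``score_structure`` receives the (argument, action) items of a
    completed candidate and returns (probability, event representation).
    ``score_actions`` evaluates the three successor structures of a beam
    state in one invocation (they share the consumed prefix).  Every
    invocation increments ``calls`` — the hardware-independent
    classification count (action scorings for SBNN, candidate
    classifications for EXNN).
    """

    calls: int = 0

    def score_structure(self, ctx: TriggerContext, items) -> Tuple[float, object]:
        raise NotImplementedError

    def score_actions(self, ctx: TriggerContext, items, head) -> Dict[str, float]:
        raise NotImplementedError

    def score_state(self, ctx: TriggerContext, items, head, action) -> float:
        """Probability of applying ``action`` to the buffer head."""
        return self.score_actions(ctx, items, head)[action]

    def reset_counter(self):
        self.calls = 0


class OracleScorer(Scorer):
    """Accepts exactly the gold structures of a document.

    Completed structures (last action CONSTRUCT, or plain candidate lists
    from exhaustive enumeration) score 1.0 iff they equal a gold structure
    of the trigger.  Partially-built structures score 1.0 while their chosen
    multiset is still extensible to some gold structure, which steers beam
    search along gold paths.
    """

    def __init__(self, gold_events):
        self.by_trigger = gold_structure_keys(gold_events)
        self._gold_arg_counters: Dict[str, List[Counter]] = {}
        for ev in gold_events:
            c = Counter((role, _arg_key(t)) for role, t in ev.arguments)
            self._gold_arg_counters.setdefault(ev.trigger.id, []).append(c)
        self.calls = 0

    def _chosen_counter(self, items) -> Counter:
        return Counter(
            (a.role, a.key()) for a, act in items if act in (ADD, CONSTRUCT)
        )

    def _is_gold(self, tid: str, counter: Counter) -> bool:
        key = ("e", tid, tuple(sorted(counter.elements())))
        return key in self.by_trigger.get(tid, ())

    def _is_prefix(self, tid: str, counter: Counter) -> bool:
        return any(
            all(gold[k] >= v for k, v in counter.items())
            for gold in self._gold_arg_counters.get(tid, ())
        )

    def score_structure(self, ctx, items):
        self.calls += 1
        items = list(items)
        counter = self._chosen_counter(items)
        tid = ctx.mention.id
        if bool(items) and items[-1][1] == CONSTRUCT:
            return (1.0 if self._is_gold(tid, counter) else 0.0), None
        return (1.0 if self._is_prefix(tid, counter) else 0.0), None

    def score_actions(self, ctx, items, head):
        self.calls += 1
        tid = ctx.mention.id
        counter = self._chosen_counter(items)
        with_head = counter.copy()
        with_head[(head.role, head.key())] += 1
        return {
            ADD: 1.0 if self._is_prefix(tid, with_head) else 0.0,
            IGNORE: 1.0 if self._is_prefix(tid, counter) else 0.0,
            CONSTRUCT: 1.0 if self._is_gold(tid, with_head) else 0.0,
        }


def _arg_key(t: Union[Mention, EventStructure]):
    return ("m", t.id) if isinstance(t, Mention) else _gold_key(t)


class AcceptAllScorer(Scorer):
    """Scores every structure 1.0 (used by enumeration-equivalence tests)."""

    def __init__(self):
        self.calls = 0

    def score_structure(self, ctx, items):
        self.calls += 1
        return 1.0, None

    def score_actions(self, ctx, items, head):
        self.calls += 1
        return {ADD: 1.0, IGNORE: 1.0, CONSTRUCT: 1.0}


class RejectAllScorer(Scorer):
    """Scores every structure 0.0."""

    def __init__(self):
        self.calls = 0

    def score_structure(self, ctx, items):
        self.calls += 1
        return 0.0, None

    def score_actions(self, ctx, items, head):
        self.calls += 1
        return {ADD: 0.0, IGNORE: 0.0, CONSTRUCT: 0.0}
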