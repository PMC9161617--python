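"""EXhaustive Neural Network (EXNN) event detector.

Instead of searching, EXNN enumerates every template-valid candidate
structure from a trigger's relations and classifies each one.  Every
relation of the trigger is represented (trigger ⊕ role ⊕ argument) and
concatenated with a trainable IN or OUT embedding marking whether the
relation belongs to the candidate.  The marked relation representations are
the children of a single Child-Sum Tree-LSTM step whose output is the event
representation; an MLP reduces it to 2 values and a softmax classifies the
structure as an event or not.  Because children are summed, the score is
invariant to the order of a trigger's relations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .autograd import Tensor, concat, matvec, row, stack_sum
from .construction import CandidateMultiset, TemplateSet, match_template
from .detection import ADD, CONSTRUCT, CandidateArg, Scorer, ScoredEvent, TriggerContext
from .neural import NeuralCore

__all__ = [
    "MarkedCandidate",
    "EXNNScorer",
    "enumerate_candidates",
    "classify_candidate",
    "detect_trigger_events",
    "DEFAULT_MAX_ARGS",
]

log = logging.getLogger(__name__)

DEFAULT_MAX_ARGS = 10  # combinatorial guard on per-trigger argument count

IN, OUT = 0, 1


@dataclass
class MarkedCandidate:
    """A candidate structure as IN/OUT marks over the trigger's relations."""

    trigger: TriggerContext
    relations: Tuple[CandidateArg, ...]  # all relations of the trigger
    in_mask: Tuple[bool, ...]  # True where the relation is part of the event

    def __post_init__(self):
        if len(self.relations) != len(self.in_mask):
            raise ValueError("one IN/OUT mark per relation is required")
        if sum(self.in_mask) < 1:
            raise ValueError("a candidate must contain at least one relation")

    def chosen(self) -> List[CandidateArg]:
        return [a for a, m in zip(self.relations, self.in_mask) if m]


def enumerate_candidates(
    trigger: TriggerContext,
    candidate_args: Sequence[CandidateArg],
    templates: TemplateSet,
    max_args: int = DEFAULT_MAX_ARGS,
) -> List[MarkedCandidate]:
    """All template-valid argument subsets of a trigger, in deterministic
    order (subset size, then buffer positions).

    Subset size is capped at the maximum template arity for the trigger's
    type; triggers with more than ``max_args`` relations are skipped with a
    warning.  Subsets never contain two groundings of one relation.
    """
    args = tuple(
        sorted(candidate_args, key=lambda a: (a.mention.start, a.role, a.key()))
    )
    if not args:
        return []
    if len(args) > max_args:
        log.warning(
            "trigger %s has %d candidate arguments (> %d); skipping",
            trigger.mention.id,
            len(args),
            max_args,
        )
        return []
    etype = trigger.mention.label
    arity_cap = min(templates.max_arity(etype), len(args))
    out: List[MarkedCandidate] = []
    for size in range(1, arity_cap + 1):
        for idxs in combinations(range(len(args)), size):
            subset = [args[i] for i in idxs]
            if len({a.source for a in subset}) < size:
                continue
            pairs = [(a.role, a.arg_type) for a in subset]
            if match_template(CandidateMultiset.from_pairs(etype, pairs), templates):
                mask = tuple(i in idxs for i in range(len(args)))
                out.append(MarkedCandidate(trigger, args, mask))
    return out


def classify_candidate(marked: MarkedCandidate, scorer: Scorer) -> float:
    """Probability that a marked candidate forms an event."""
    items = [(a, ADD) for a in marked.chosen()]
    items[-1] = (items[-1][0], CONSTRUCT)  # completed-structure convention
    if isinstance(scorer, EXNNScorer):
        prob, _ = scorer.score_marked(marked)
    else:
        prob, _ = scorer.score_structure(marked.trigger, items)
    return prob


def detect_trigger_events(
    trigger: TriggerContext,
    candidate_args: Sequence[CandidateArg],
    templates: TemplateSet,
    threshold: float,
    scorer: Scorer,
    max_args: int = DEFAULT_MAX_ARGS,
) -> List[ScoredEvent]:
    """Enumerate, classify, and keep candidates at or above the threshold."""
    out: List[ScoredEvent] = []
    for marked in enumerate_candidates(trigger, candidate_args, templates, max_args):
        prob = classify_candidate(marked, scorer)
        if prob < threshold:
            continue
        ev = ScoredEvent(
            trigger=trigger.mention,
            event_type=trigger.mention.label,
            arguments=[(a.role, a) for a in marked.chosen()],
            score=prob,
        )
        if hasattr(scorer, "event_representation_marked"):
            ev.repr = scorer.event_representation_marked(marked)
        out.append(ev)
    # deduplicate identical grounded structures, keeping the best score
    best: Dict[tuple, ScoredEvent] = {}
    for ev in out:
        k = ev.key()
        if k not in best or ev.score > best[k].score:
            best[k] = ev
    return sorted(best.values(), key=lambda e: (e.multiset(), e.key()))


class EXNNScorer(Scorer):
    """Child-Sum Tree-LSTM over IN/OUT-marked relation representations."""

    def __init__(self, core: NeuralCore):
        self.core = core
        self.calls = 0
        cfg = core.config
        rng = np.random.default_rng(cfg.seed + 2)
        self.params: Dict[str, Tensor] = {}

        def P(name, shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
            t = Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)
            self.params[name] = t
            return t

        child_dim = cfg.relation_dim + cfg.io_dim
        h = cfg.hidden_size
        self.io_emb = P("io_emb", (2, cfg.io_dim), 0.1)
        # leaf projections of marked relations into (hidden, cell) space
        self.Wleaf_h = P("Wleaf_h", (h, child_dim))
        self.Wleaf_c = P("Wleaf_c", (h, child_dim))
        # Child-Sum gates: input is the trigger representation
        x_dim = cfg.mention_dim
        self.Wi = P("Wi", (h, x_dim)); self.Ui = P("Ui", (h, h)); self.bi = P("bi", (h,), 0.0)
        self.Wf = P("Wf", (h, x_dim)); self.Uf = P("Uf", (h, h)); self.bf = P("bf", (h,), 0.0)
        self.Wo = P("Wo", (h, x_dim)); self.Uo = P("Uo", (h, h)); self.bo = P("bo", (h,), 0.0)
        self.Wu = P("Wu", (h, x_dim)); self.Uu = P("Uu", (h, h)); self.bu = P("bu", (h,), 0.0)
        # MLP head: hidden -> 2 logits (event / not event)
        self.W1 = P("W1", (cfg.mlp_hidden, h))
        self.b1 = P("b1", (cfg.mlp_hidden,), 0.0)
        self.W2 = P("W2", (2, cfg.mlp_hidden))
        self.b2 = P("b2", (2,), 0.0)
        self.Wev = P("Wev", (cfg.mention_dim, h))
        self.bev = P("bev", (cfg.mention_dim,), 0.0)
        self._rel_cache: Dict[tuple, Tensor] = {}

    def all_params(self) -> List[Tensor]:
        return list(self.core.params.values()) + list(self.params.values())

    def begin_sentence(self):
        self._rel_cache.clear()

    def _relation_rep(self, ctx: TriggerContext, arg: CandidateArg) -> Tensor:
        # keyed by stable identity: object ids can be reused within a document
        key = (arg.source, arg.key())
        cached = self._rel_cache.get(key)
        if cached is None:
            cached = self.core.relation_representation(ctx.repr, arg.role, arg.repr)
            self._rel_cache[key] = cached
        return cached

    def _tree_lstm(self, marked: MarkedCandidate) -> Tensor:
        """One Child-Sum composition over all marked relations."""
        ctx = marked.trigger
        hs, cs = [], []
        for arg, is_in in zip(marked.relations, marked.in_mask):
            child = concat(
                [self._relation_rep(ctx, arg), row(self.io_emb, IN if is_in else OUT)]
            )
            hs.append(matvec(self.Wleaf_h, child).tanh())
            cs.append(matvec(self.Wleaf_c, child).tanh())
        h_sum = stack_sum(hs)
        x = ctx.repr
        i = (matvec(self.Wi, x) + matvec(self.Ui, h_sum) + self.bi).sigmoid()
        o = (matvec(self.Wo, x) + matvec(self.Uo, h_sum) + self.bo).sigmoid()
        u = (matvec(self.Wu, x) + matvec(self.Uu, h_sum) + self.bu).tanh()
        fcs = []
        for hk, ck in zip(hs, cs):
            f = (matvec(self.Wf, x) + matvec(self.Uf, hk) + self.bf).sigmoid()
            fcs.append(f * ck)
        c = i * u + stack_sum(fcs)
        return o * c.tanh()

    def logits(self, marked: MarkedCandidate) -> Tuple[Tensor, Tensor]:
        """2-class logits plus the Tree-LSTM event representation."""
        h = self._tree_lstm(marked)
        z = (matvec(self.W1, h) + self.b1).relu()
        return matvec(self.W2, z) + self.b2, h

    def score_marked(self, marked: MarkedCandidate) -> Tuple[float, Tensor]:
        self.calls += 1
        logits, h = self.logits(marked)
        prob = float(logits.softmax()[1])
        return prob, h

    def score_structure(self, ctx, items):
        """Scorer-interface adapter: items define the IN set; relations not
        listed are unavailable here, so the candidate is its chosen set."""
        rels = tuple(a for a, act in items if act in (ADD, CONSTRUCT))
        marked = MarkedCandidate(ctx, rels, tuple(True for _ in rels))
        return self.score_marked(marked)

    def event_representation_marked(self, marked: MarkedCandidate) -> Tensor:
        h = self._tree_lstm(marked)
        return (matvec(self.Wev, h) + self.bev).tanh()
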