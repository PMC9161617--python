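"""Search-Based Neural Network (SBNN) event detector.

For each trigger, beam search over the ordered buffer of candidate
arguments applies one of three actions to the buffer head at every time
step: ADD, IGNORE, or CONSTRUCT (add the head and emit the structure built
so far).  The beam keeps the top-k states by score; states scoring below
the probability threshold are filtered out of the beam, which — together
with k — limits how many structures ever reach the network.  Emitted
structures are collected from *all* retained beams across all time steps,
which is what lets a single trigger yield several overlapping events;
emissions failing template matching or whose structure probability is
below the threshold are dropped.

What the network scores is the partially-built event structure: the sum of
(relation representation ⊕ action embedding) over the consumed arguments
— chosen ones under ADD/CONSTRUCT, skipped ones under IGNORE — combined
with the trigger representation through an MLP with a sigmoid head.  One
scorer invocation evaluates all three successor structures of a state
(they share the consumed prefix), and the CONSTRUCT score is the emitted
structure's final probability.  A companion projection yields the composed
event representation that upper levels consume as an argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor, concat, dot, matvec, row, stack_sum
from .construction import CandidateMultiset, TemplateSet, match_template
from .detection import (
    ADD,
    CONSTRUCT,
    IGNORE,
    CandidateArg,
    Scorer,
    ScoredEvent,
    TriggerContext,
)
from .neural import NeuralCore

__all__ = ["SBNNConfig", "BeamState", "SBNNScorer", "expand_state", "search_trigger"]

log = logging.getLogger(__name__)

_ACTIONS = (ADD, IGNORE, CONSTRUCT)
_ACTION_INDEX = {a: i for i, a in enumerate(_ACTIONS)}


@dataclass
class SBNNConfig:
    """Beam width k, structure-probability threshold, and seed.

    k = 8 is the best-performing width reported for the search-based
    model; the threshold default of 0.5 is the natural cut on a sigmoid
    probability (its value is a free parameter).
    """

    k: int = 8
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("beam width k must be >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class BeamState:
    """One beam hypothesis over a trigger's argument buffer.

    ``items`` records every consumed argument with the action applied to
    it; the chosen multiset is the ADD/CONSTRUCT subset.
    """

    trigger: TriggerContext
    buffer: Tuple[CandidateArg, ...]
    position: int = 0
    items: Tuple[Tuple[CandidateArg, str], ...] = ()
    score: float = 0.5
    emitted: bool = False

    @property
    def head(self) -> Optional[CandidateArg]:
        return self.buffer[self.position] if self.position < len(self.buffer) else None

    @property
    def chosen(self) -> Tuple[Tuple[CandidateArg, str], ...]:
        return tuple((a, act) for a, act in self.items if act != IGNORE)

    @property
    def action_history(self) -> Tuple[str, ...]:
        return tuple(act for _, act in self.items)

    def done(self) -> bool:
        return self.position >= len(self.buffer)

    def chosen_sources(self) -> set:
        return {a.source for a, act in self.items if act != IGNORE}


def expand_state(state: BeamState, scorer: Scorer) -> List[BeamState]:
    """Apply each action to the buffer head, yielding up to 3 successors.

    All three successors share the consumed prefix, so one scorer
    invocation evaluates them jointly.  A head whose source relation is
    already chosen (a second grounding of the same relation) only admits
    IGNORE.
    """
    head = state.head
    if head is None:
        raise ValueError("cannot expand a state with an empty buffer")
    blocked = head.source in state.chosen_sources()
    scores = scorer.score_actions(state.trigger, state.items, head)
    succ: List[BeamState] = []
    for action in _ACTIONS:
        if action != IGNORE and blocked:
            continue
        succ.append(
            BeamState(
                trigger=state.trigger,
                buffer=state.buffer,
                position=state.position + 1,
                items=state.items + ((head, action),),
                score=scores[action],
                emitted=action == CONSTRUCT,
            )
        )
    return succ


def search_trigger(
    trigger: TriggerContext,
    candidate_args: Sequence[CandidateArg],
    templates: TemplateSet,
    config: SBNNConfig,
    scorer: Scorer,
) -> List[ScoredEvent]:
    """Beam search over one trigger's candidate arguments.

    Returns the deduplicated, template-valid emissions with structure
    probability at or above the threshold, collected from all retained
    beams.
    """
    buffer = tuple(
        sorted(candidate_args, key=lambda a: (a.mention.start, a.role, a.key()))
    )
    if not buffer:
        return []
    etype = trigger.mention.label
    beams = [BeamState(trigger=trigger, buffer=buffer)]
    results: Dict[tuple, ScoredEvent] = {}

    while beams and not beams[0].done():
        successors: List[BeamState] = []
        for st in beams:
            successors.extend(expand_state(st, scorer))
        # stable prune: score desc, then action history (ADD-dense first)
        successors.sort(key=lambda s: s.action_history)
        successors.sort(key=lambda s: -s.score)
        retained = [
            s for s in successors[: config.k] if s.score >= config.threshold
        ]
        for st in retained:
            if not st.emitted:
                continue
            chosen = st.chosen
            pairs = [(a.role, a.arg_type) for a, _ in chosen]
            if not match_template(
                CandidateMultiset.from_pairs(etype, pairs), templates
            ):
                continue
            ev = ScoredEvent(
                trigger=trigger.mention,
                event_type=etype,
                arguments=[(a.role, a) for a, _ in chosen],
                score=st.score,
            )
            key = ev.key()
            if key not in results or st.score > results[key].score:
                results[key] = ev
        beams = retained
    out = sorted(results.values(), key=lambda e: (e.multiset(), e.key()))
    if out and hasattr(scorer, "event_representation"):
        for ev in out:
            ev.repr = scorer.event_representation(trigger, ev)
    return out


class SBNNScorer(Scorer):
    """Neural scorer over partially-built structures with action embeddings."""

    def __init__(self, core: NeuralCore):
        self.core = core
        self.calls = 0
        cfg = core.config
        rng = np.random.default_rng(cfg.seed + 1)
        in_dim = cfg.mention_dim + cfg.relation_dim + cfg.action_dim
        self.params: Dict[str, Tensor] = {}

        def P(name, shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
            t = Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)
            self.params[name] = t
            return t

        self.action_emb = P("action_emb", (len(_ACTIONS), cfg.action_dim), 0.1)
        self.W1 = P("W1", (cfg.mlp_hidden, in_dim))
        self.b1 = P("b1", (cfg.mlp_hidden,), 0.0)
        self.w2 = P("w2", (cfg.mlp_hidden,))
        self.b2 = P("b2", (1,), 0.0)
        self.Wev = P("Wev", (cfg.mention_dim, cfg.mlp_hidden))
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

    def structure_logit(self, ctx: TriggerContext, items) -> Tuple[Tensor, Tensor]:
        """Logit and hidden layer for a partially-built structure."""
        cfg = self.core.config
        vecs = [
            concat(
                [self._relation_rep(ctx, a), row(self.action_emb, _ACTION_INDEX[act])]
            )
            for a, act in items
        ]
        pooled = (
            stack_sum(vecs)
            if vecs
            else Tensor(np.zeros(cfg.relation_dim + cfg.action_dim))
        )
        h = (matvec(self.W1, concat([ctx.repr, pooled])) + self.b1).tanh()
        logit = dot(self.w2, h) + self.b2.slice(0, 1).sum()
        return logit, h

    def action_logits(self, ctx: TriggerContext, items, head):
        """The three successor structure logits of one state (shared prefix)."""
        return {
            action: self.structure_logit(ctx, tuple(items) + ((head, action),))[0]
            for action in _ACTIONS
        }

    def score_actions(self, ctx, items, head):
        self.calls += 1
        return {
            action: float(logit.sigmoid().data)
            for action, logit in self.action_logits(ctx, items, head).items()
        }

    def score_structure(self, ctx, items):
        """Probability of a completed structure (same head as the search)."""
        self.calls += 1
        logit, _ = self.structure_logit(ctx, items)
        return float(logit.sigmoid().data), None

    def event_representation(self, ctx: TriggerContext, ev: ScoredEvent) -> Tensor:
        """Composed representation of an accepted structure (argument for
        upper levels); same dimensionality as a mention representation."""
        items = [(a, ADD) for _, a in ev.arguments]
        _, h = self.structure_logit(ctx, items)
        return (matvec(self.Wev, h) + self.bev).tanh()
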