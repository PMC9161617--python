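"""Training and prediction for the neural event detectors.

Training is bottom-up with teacher forcing: examples are derived from the
(gold or noisy) relation set of each trigger with event arguments grounded
to the *gold* sub-events.  The EXNN classifier sees every template-valid
candidate subset, labelled positive iff it equals a gold structure, and is
trained with 2-class cross-entropy; its heavy negative-candidate imbalance
is countered by a positive-class weight, by default #neg/#pos.  The SBNN
scorer is trained transition-style on the beam states that lie on a gold
action path (chosen = gold ∩ consumed prefix): at each such state the
three successor structures (ADD/IGNORE/CONSTRUCT on the buffer head) get
binary cross-entropy against whether they remain on a gold path — with the
CONSTRUCT successor positive exactly at a complete gold structure.  Around
triggers with no constructible gold only the all-IGNORE spine is
supervised, with all-zero labels, so the beam learns to die there.

The example inventory and labels do not depend on model parameters, so
they are planned once per corpus and replayed every epoch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bottom_up import (
    EXNNDetector,
    SBNNDetector,
    _DocumentContext,
    detect_document,
    predictions_to_document,
)
from .construction import (
    CandidateMultiset,
    TemplateSet,
    build_adjacency,
    build_graph,
    extract_templates,
    match_template,
)
from .detection import ADD, CONSTRUCT, IGNORE, CandidateArg, ScoredEvent, TriggerContext
from .exnn import DEFAULT_MAX_ARGS, EXNNScorer, MarkedCandidate
from .neural import EmbeddingConfig, NeuralCore, Vocabulary, tokenize_with_offsets
from .sbnn import SBNNConfig, SBNNScorer
from .standoff import AnnotatedDocument, EventStructure, Mention, RelationTriple, decompose_events
from .autograd import Adam, Tensor

__all__ = ["TrainConfig", "EventModel", "train_model", "predict_corpus"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    model: str = "exnn"  # "sbnn" | "exnn"
    epochs: int = 20
    lr: float = 0.01
    seed: int = 0
    k: int = 8
    threshold: float = 0.5
    max_args: int = DEFAULT_MAX_ARGS
    pos_weight: Optional[float] = None  # None = #neg/#pos per epoch
    early_stop_loss: float = 0.02
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    def __post_init__(self):
        if self.model not in ("sbnn", "exnn"):
            raise ValueError("model must be 'sbnn' or 'exnn'")


# ---------------------------------------------------------------------------
# training example plans (static per corpus)


@dataclass
class _RelDesc:
    role: str
    arg: Mention
    arg_type: str  # entity label or gold sub-event type
    gold_sub: Optional[str]  # gold event id grounding an event argument


@dataclass
class _TriggerPlan:
    trigger: Mention
    rels: List[_RelDesc]
    candidates: List[Tuple[Tuple[int, ...], int]]  # EXNN: (indices, label)
    # SBNN: on-path beam states — (chosen indices, step t, per-action labels)
    states: List[Tuple[Tuple[int, ...], int, Dict[str, int]]]


@dataclass
class _DocPlan:
    doc: AnnotatedDocument
    triggers: List[_TriggerPlan]
    n_pos: int = 0
    n_neg: int = 0


def _gold_events_by_trigger(doc) -> Dict[str, List[EventStructure]]:
    out: Dict[str, List[EventStructure]] = {}
    for ev in doc.events:
        out.setdefault(ev.trigger.id, []).append(ev)
    return out


def _gold_key_of(ev: EventStructure):
    from .detection import gold_structure_keys

    return next(iter(gold_structure_keys([ev])[ev.trigger.id]))


def _plan_document(
    doc: AnnotatedDocument,
    triples: Sequence[RelationTriple],
    templates: TemplateSet,
    cfg: TrainConfig,
) -> _DocPlan:
    from itertools import combinations

    by_trigger = _gold_events_by_trigger(doc)
    gold_keys = {
        tid: {_gold_key_of(ev) for ev in evs} for tid, evs in by_trigger.items()
    }
    gold_event_of = {
        tid: {ev.id: ev for ev in evs} for tid, evs in by_trigger.items()
    }
    adjacency = build_adjacency(triples)
    plans: List[_TriggerPlan] = []
    n_pos = n_neg = 0
    for tid in sorted(adjacency.lists, key=lambda t: adjacency.mentions[t].start):
        trig = adjacency.mentions[tid]
        rels: List[_RelDesc] = []
        for role, arg in adjacency[tid]:
            subs = by_trigger.get(arg.id)
            if subs is not None and arg.id != tid:
                for sub in subs:  # teacher-forced grounding per gold sub-event
                    rels.append(_RelDesc(role, arg, sub.event_type, sub.id))
            else:
                rels.append(_RelDesc(role, arg, arg.label, None))
        if not rels or len(rels) > cfg.max_args:
            continue

        def rel_key(r: _RelDesc):
            if r.gold_sub is not None:
                return _gold_key_of(gold_event_of[r.arg.id][r.gold_sub])
            return ("m", r.arg.id)

        # buffer order must match the search's ordering exactly
        rels.sort(key=lambda r: (r.arg.start, r.role, rel_key(r)))
        etype = trig.label
        gks = gold_keys.get(tid, set())

        def cand_key(idxs):
            return (
                "e",
                tid,
                tuple(sorted((rels[i].role, rel_key(rels[i])) for i in idxs)),
            )

        # gold structures as index sets over the buffer (skipping golds whose
        # relations were dropped by upstream noise)
        gold_sets: List[frozenset] = []
        for gk in sorted(gks):  # stable order despite per-process str hashing
            want = list(gk[2])
            idxs = []
            ok = True
            for role, key in want:
                found = next(
                    (
                        i
                        for i in range(len(rels))
                        if i not in idxs
                        and rels[i].role == role
                        and rel_key(rels[i]) == key
                    ),
                    None,
                )
                if found is None:
                    ok = False
                    break
                idxs.append(found)
            if ok:
                gold_sets.append(frozenset(idxs))

        cands: List[Tuple[Tuple[int, ...], int]] = []
        if cfg.model == "exnn":
            arity = min(templates.max_arity(etype), len(rels))
            for size in range(1, arity + 1):
                for idxs in combinations(range(len(rels)), size):
                    srcs = {(rels[i].role, rels[i].arg.id) for i in idxs}
                    if len(srcs) < size:
                        continue
                    pairs = [(rels[i].role, rels[i].arg_type) for i in idxs]
                    if not match_template(
                        CandidateMultiset.from_pairs(etype, pairs), templates
                    ):
                        continue
                    label = 1 if cand_key(idxs) in gks else 0
                    cands.append((idxs, label))
                    n_pos += label
                    n_neg += 1 - label

        states: List[Tuple[Tuple[int, ...], int, Dict[str, int]]] = []
        if cfg.model == "sbnn":
            n = len(rels)
            # on-path states: chosen = G ∩ first t for some gold G; when no
            # gold is constructible only the all-IGNORE spine is supervised,
            # with all-zero labels, teaching the beam to die on such triggers
            for t in range(n):
                on_path: set = set()
                if gold_sets:
                    for G in gold_sets:
                        on_path.add(frozenset(i for i in G if i < t))
                else:
                    on_path.add(frozenset())
                for chosen in sorted(on_path, key=sorted):
                    with_head = chosen | {t}
                    labels = {
                        ADD: int(
                            any(
                                with_head == frozenset(i for i in G if i <= t)
                                and t in G
                                for G in gold_sets
                            )
                        ),
                        IGNORE: int(
                            any(
                                chosen == frozenset(i for i in G if i <= t)
                                for G in gold_sets
                            )
                        ),
                        CONSTRUCT: int(with_head in gold_sets),
                    }
                    states.append((tuple(sorted(chosen)), t, labels))
        if cands or states:
            plans.append(_TriggerPlan(trig, rels, cands, states))
    return _DocPlan(doc, plans, n_pos, n_neg)


# ---------------------------------------------------------------------------
# model container


class EventModel:
    """A trained (or initialised) detector: core + scorer + templates."""

    def __init__(self, kind: str, core: NeuralCore, scorer, templates: TemplateSet,
                 config: TrainConfig):
        self.kind = kind
        self.core = core
        self.scorer = scorer
        self.templates = templates
        self.config = config

    def detector(self):
        if self.kind == "sbnn":
            return SBNNDetector(
                self.scorer,
                self.templates,
                SBNNConfig(self.config.k, self.config.threshold, self.config.seed),
                core=self.core,
            )
        return EXNNDetector(
            self.scorer,
            self.templates,
            threshold=self.config.threshold,
            max_args=self.config.max_args,
            core=self.core,
        )

    # -- persistence (JSON; parameters are small) -------------------------

    def save(self, path: str) -> None:
        state = {
            "format": "nevex-checkpoint-v1",
            "kind": self.kind,
            "config": {
                **{k: v for k, v in asdict(self.config).items() if k != "embedding"},
                "embedding": asdict(self.config.embedding),
            },
            "core": self.core.state_dict(),
            "scorer": {k: v.data.tolist() for k, v in self.scorer.params.items()},
            "templates": json.loads(self.templates.to_json()),
        }
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def load(cls, path: str) -> "EventModel":
        with open(path) as fh:
            state = json.load(fh)
        emb = EmbeddingConfig(**state["config"].pop("embedding"))
        cfg = TrainConfig(embedding=emb, **state["config"])
        core = NeuralCore.from_state(state["core"])
        scorer = SBNNScorer(core) if state["kind"] == "sbnn" else EXNNScorer(core)
        for k, v in state["scorer"].items():
            scorer.params[k].data = np.asarray(v, dtype=np.float64)
        templates = TemplateSet.from_json(json.dumps(state["templates"]))
        return cls(state["kind"], core, scorer, templates, cfg)


def build_model(
    train_docs: Sequence[AnnotatedDocument], cfg: TrainConfig
) -> EventModel:
    """Initialise vocabulary, templates and parameters from training gold."""
    if not any(d.events for d in train_docs):
        raise ValueError("no gold events in the training documents")
    tokens = []
    for d in train_docs:
        tokens.extend(t for t, _, _ in tokenize_with_offsets(d.text))
    vocab = Vocabulary.fit(tokens)
    labels = set()
    roles = set()
    for d in train_docs:
        labels.update(m.label for m in d.entities)
        labels.update(m.label for m in d.triggers)
        for ev in d.events:
            roles.update(role for role, _ in ev.arguments)
    emb = EmbeddingConfig(**{**asdict(cfg.embedding), "seed": cfg.seed})
    core = NeuralCore(
        emb,
        vocab,
        Vocabulary(sorted(labels)),
        Vocabulary(sorted(roles), warn_unknown=True),
    )
    scorer = SBNNScorer(core) if cfg.model == "sbnn" else EXNNScorer(core)
    templates = extract_templates(train_docs)
    return EventModel(cfg.model, core, scorer, templates, cfg)


# ---------------------------------------------------------------------------
# the training loop


def _gold_scored_events(
    doc: AnnotatedDocument, ctxh: _DocumentContext, scorer, kind: str
) -> Dict[str, ScoredEvent]:
    """Teacher-forced ScoredEvents (with representations) for gold events."""
    made: Dict[str, ScoredEvent] = {}

    def build(ev: EventStructure) -> ScoredEvent:
        if ev.id in made:
            return made[ev.id]
        args: List[Tuple[str, CandidateArg]] = []
        for role, t in ev.arguments:
            if isinstance(t, Mention):
                args.append(
                    (role, CandidateArg(
                        role, t, t.label, (ev.trigger.id, role, t.id),
                        None, ctxh.mention_repr(t),
                    ))
                )
            else:
                sub = build(t)
                args.append(
                    (role, CandidateArg(
                        role, t.trigger, t.event_type,
                        (ev.trigger.id, role, t.trigger.id), sub, sub.repr,
                    ))
                )
        sev = ScoredEvent(ev.trigger, ev.event_type, args, 1.0)
        ctx = TriggerContext(ev.trigger, ctxh.mention_repr(ev.trigger))
        if kind == "sbnn":
            sev.repr = scorer.event_representation(ctx, sev)
        else:
            rels = tuple(a for _, a in args)
            marked = MarkedCandidate(ctx, rels, tuple(True for _ in rels))
            sev.repr = scorer.event_representation_marked(marked)
        made[ev.id] = sev
        return sev

    for ev in doc.events:
        build(ev)
    return made


def train_model(
    train_docs: Sequence[AnnotatedDocument],
    cfg: TrainConfig,
    train_relations: Optional[Dict[str, List[RelationTriple]]] = None,
) -> Tuple[EventModel, List[float]]:
    """Train a detector; returns the model and the per-epoch mean loss.

    ``train_relations`` supplies scenario-specific (possibly noisy)
    relations per document id; by default the gold decomposition is used.
    Training stops early once the mean loss falls below
    ``cfg.early_stop_loss`` (the loss history records realised epochs).
    """
    model = build_model(train_docs, cfg)
    scorer = model.scorer
    ctxh = _DocumentContext(model.core)
    plans: List[_DocPlan] = []
    for doc in train_docs:
        triples = (
            train_relations[doc.doc_id]
            if train_relations is not None
            else decompose_events(doc)
        )
        plan = _plan_document(doc, triples, model.templates, cfg)
        if plan.triggers:
            plans.append(plan)
    if not plans:
        raise ValueError("no trainable candidate structures in the corpus")

    n_pos = sum(p.n_pos for p in plans)
    n_neg = sum(p.n_neg for p in plans)
    pos_w = (
        cfg.pos_weight
        if cfg.pos_weight is not None
        else max(1.0, n_neg / max(1, n_pos))
    )
    opt = Adam(scorer.all_params(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 23)
    history: List[float] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(plans))
        total_loss = 0.0
        total_n = 0
        for pi in order:
            plan = plans[pi]
            ctxh.start_document(plan.doc)
            scorer.begin_sentence()
            gold_scored = _gold_scored_events(plan.doc, ctxh, scorer, cfg.model)
            losses = []
            for tp in plan.triggers:
                ctx = TriggerContext(tp.trigger, ctxh.mention_repr(tp.trigger))
                cargs: List[CandidateArg] = []
                for r in tp.rels:
                    if r.gold_sub is not None:
                        sub = gold_scored[r.gold_sub]
                        cargs.append(
                            CandidateArg(
                                r.role, r.arg, r.arg_type,
                                (tp.trigger.id, r.role, r.arg.id), sub, sub.repr,
                            )
                        )
                    else:
                        cargs.append(
                            CandidateArg(
                                r.role, r.arg, r.arg_type,
                                (tp.trigger.id, r.role, r.arg.id),
                                None, ctxh.mention_repr(r.arg),
                            )
                        )
                if cfg.model == "exnn":
                    for idxs, label in tp.candidates:
                        mask = tuple(
                            i in idxs for i in range(len(cargs))
                        )
                        marked = MarkedCandidate(ctx, tuple(cargs), mask)
                        logits, _ = scorer.logits(marked)
                        loss = logits.cross_entropy(label)
                        if label == 1:
                            loss = loss * Tensor(pos_w)
                        losses.append(loss)
                else:
                    for chosen, t, labels in tp.states:
                        chosen_set = set(chosen)
                        items = tuple(
                            (cargs[i], ADD if i in chosen_set else IGNORE)
                            for i in range(t)
                        )
                        logits = scorer.action_logits(ctx, items, cargs[t])
                        for action, logit in logits.items():
                            losses.append(logit.bce_with_logit(labels[action]))
            if not losses:
                continue
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            loss = loss * Tensor(1.0 / len(losses))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += loss.item() * len(losses)
            total_n += len(losses)
        mean = total_loss / max(1, total_n)
        history.append(mean)
        log.info("epoch %d mean loss %.4f", epoch + 1, mean)
        if mean < cfg.early_stop_loss:
            break
    return model, history


def predict_corpus(
    model: EventModel,
    docs: Sequence[AnnotatedDocument],
    relations: Optional[Dict[str, List[RelationTriple]]] = None,
):
    """Bottom-up prediction over a corpus.

    Returns (predicted documents, per-document traces).  ``relations``
    supplies predicted relations per document id; by default the gold
    decomposition is used (upper-bound regime).
    """
    detector = model.detector()
    pred_docs: List[AnnotatedDocument] = []
    traces = []
    for doc in docs:
        triples = (
            relations[doc.doc_id] if relations is not None else decompose_events(doc)
        )
        graph = build_graph(build_adjacency(triples))
        events, trace = detect_document(graph, detector, doc)
        pred_docs.append(predictions_to_document(doc, events))
        traces.append(trace)
    return pred_docs, traces
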