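"""Seeded synthetic standoff corpora with controllable event structure.

The generator emulates the shape of event-annotated biomedical corpora —
flat, nested and overlapping events over typed entity and trigger mentions
in sentence-sized documents — without mimicking real lexical statistics:
text is token soup whose lexical cues are *predictive* of structure.  Each
(event type, template) pair owns its trigger lexemes, so a model reading
the trigger's context can learn which argument multiset the trigger
licenses; this is what makes the corpora separable for the learned
detectors.  Entities are fresh typed tokens, reused across events to
create overlapping structures.

Relation-level noise emulates an upstream relation extractor: gold
relations are dropped (false negatives) and type-plausible spurious
relations added (false positives), which supports the three pipeline
training scenarios (gold/gold, gold+FP/noisy, noisy/noisy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .standoff import (
    AnnotatedDocument,
    EventStructure,
    Mention,
    RelationTriple,
    decompose_events,
)

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "inject_relation_noise",
    "make_scenario_datasets",
    "ScenarioData",
    "DEFAULT_EVENT_TYPES",
    "DEFAULT_ENTITY_TYPES",
]

Template = Tuple[Tuple[str, str], ...]  # (role, argument-type) pairs

DEFAULT_ENTITY_TYPES = ("GGP", "Cancer")

# Per event type: trigger lexeme base and the template inventory.  Argument
# types naming another event type make the template nested.  Several types
# deliberately admit both a one-argument and a two-argument template
# (multiplicity-sensitive for Binding's repeated Themes), so that proper
# subsets of gold structures are template-valid negatives the models must
# learn to reject from the trigger lexeme; the multi-Theme Binding
# templates also push the mean argument count per event above 2.
DEFAULT_EVENT_TYPES: Dict[str, dict] = {
    "Blood_vessel_development": {
        "base": "angiogen",
        "templates": [(("Theme", "Cancer"),)],
    },
    "Gene_expression": {
        "base": "express",
        "templates": [(("Theme", "GGP"),)],
    },
    "Binding": {
        "base": "bind",
        "templates": [
            (("Theme", "GGP"), ("Theme", "GGP")),
            (("Theme", "GGP"), ("Theme", "GGP"), ("Theme", "GGP")),
            (("Theme", "GGP"),) * 4,
            (("Theme", "GGP"),) * 5,
        ],
    },
    "Positive_regulation": {
        "base": "induct",
        "templates": [
            (("Cause", "GGP"), ("Theme", "Blood_vessel_development")),
            (("Cause", "GGP"), ("Theme", "Gene_expression")),
            (("Cause", "GGP"), ("Theme", "Binding")),
            (("Theme", "GGP"),),
            (("Cause", "GGP"), ("Theme", "GGP")),
        ],
    },
    "Regulation": {
        "base": "regul",
        "templates": [
            (("Cause", "GGP"), ("Theme", "Positive_regulation")),
            (("Cause", "GGP"), ("Theme", "GGP")),
        ],
    },
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 100
    sentences_per_doc: int = 1
    events_per_sentence: Tuple[int, int] = (2, 3)
    vocab_size: int = 60  # filler-token vocabulary
    entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES
    event_types: Dict[str, dict] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_EVENT_TYPES.items()
        }
    )
    nested_fraction: float = 0.35
    overlap_fraction: float = 0.4
    max_depth: int = 3
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    # the lower-bound pipeline regime uses an upstream extractor that is
    # itself trained on predicted inputs, hence noisier than the pipeline
    # regime's; its rates are the base rates scaled by this factor
    scenario3_noise_scale: float = 1.5
    cue_strength: float = 1.0

    def validate(self) -> None:
        for name in ("nested_fraction", "overlap_fraction", "fp_rate",
                     "fn_rate", "cue_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not self.event_types or not any(
            spec["templates"] for spec in self.event_types.values()
        ):
            raise ValueError("template inventory must be non-empty")
        lo, hi = self.events_per_sentence
        if not (1 <= lo <= hi):
            raise ValueError("events_per_sentence must be a valid (lo, hi) range")
        if self.nested_fraction > 0 and hi < 2:
            raise ValueError(
                "nested_fraction > 0 requires at least 2 events per sentence "
                "(a nested event needs a sub-event in the same sentence)"
            )
        if self.overlap_fraction >= 1.0 and hi < 2:
            raise ValueError(
                "overlap_fraction = 1 requires at least 2 events per sentence"
            )
        if self.nested_fraction > 0 and not self._nested_child_types():
            raise ValueError(
                "nested_fraction > 0 but no template has an event-typed argument"
            )
        for etype, spec in self.event_types.items():
            for tpl in spec["templates"]:
                n_event_slots = sum(
                    1 for _, atype in tpl if atype in self.event_types
                )
                if n_event_slots > 1:
                    raise ValueError(
                        f"template {tpl} of {etype}: the generator supports "
                        "at most one event-typed argument per template"
                    )

    def _nested_child_types(self) -> Dict[str, List[Tuple[str, Template]]]:
        """Child event type -> [(parent type, template)] for nested templates."""
        out: Dict[str, List[Tuple[str, Template]]] = {}
        for etype, spec in self.event_types.items():
            for tpl in spec["templates"]:
                for _, atype in tpl:
                    if atype in self.event_types:
                        out.setdefault(atype, []).append((etype, tpl))
        return out

    def flat_templates(self) -> List[Tuple[str, int, Template]]:
        out = []
        for etype, spec in self.event_types.items():
            for ti, tpl in enumerate(spec["templates"]):
                if all(atype not in self.event_types for _, atype in tpl):
                    out.append((etype, ti, tpl))
        return out


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.tokens: List[str] = []
        self.entities: List[Mention] = []
        self.triggers: List[Mention] = []
        self.events: List[EventStructure] = []
        self.sentence_token_bounds: List[Tuple[int, int]] = []

    def add_token(self, tok: str) -> int:
        self.tokens.append(tok)
        return len(self.tokens) - 1

    def finish(self) -> AnnotatedDocument:
        # materialise text and char offsets from token positions
        offsets = []
        pos = 0
        for t in self.tokens:
            offsets.append((pos, pos + len(t)))
            pos += len(t) + 1
        text = " ".join(self.tokens)

        def realise(m):
            s, e = offsets[m["tok"]]
            return Mention(m["id"], m["label"], s, e, text[s:e])

        entities = [realise(m) for m in self.entities]
        triggers = [realise(m) for m in self.triggers]
        by_id = {m.id: m for m in entities + triggers}
        events: List[EventStructure] = []
        made: Dict[str, EventStructure] = {}
        for ev in self.events:
            args = []
            for role, ref in ev["args"]:
                args.append((role, made[ref] if ref in made else by_id[ref]))
            es = EventStructure(ev["id"], ev["type"], by_id[ev["trigger"]], args)
            made[ev["id"]] = es
            events.append(es)
        spans = [
            (offsets[a][0], offsets[b - 1][1])
            for a, b in self.sentence_token_bounds
        ]
        doc = AnnotatedDocument(
            doc_id=self.doc_id,
            text=text,
            entities=entities,
            triggers=triggers,
            events=events,
            sentence_spans=spans,
        )
        return doc


def generate_corpus(config: GeneratorConfig) -> List[AnnotatedDocument]:
    """Generate a seeded corpus of annotated documents.

    The realised nested fraction tracks ``nested_fraction`` by a running
    quota (subject to per-sentence feasibility), so at corpus scale it sits
    within sampling error of the target.  Overlap is the probability that a
    non-initial event reuses an argument of an earlier event in the same
    sentence; because overlap flags both sharers, the realised flagged
    fraction exceeds this probability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nested_children = config._nested_child_types()
    flat_templates = config.flat_templates()
    docs: List[AnnotatedDocument] = []
    total_events = 0
    total_nested = 0

    for d in range(config.n_docs):
        b = _DocBuilder(f"synth{d:04d}")
        eid = tid = mid = 0
        for _ in range(config.sentences_per_doc):
            sent_start_tok = len(b.tokens)
            # events of this sentence, with their builder records and depths
            sent_events: List[dict] = []
            # entity mentions of this sentence by type, for overlap reuse
            sent_entities: Dict[str, List[dict]] = {}
            n_events = int(rng.integers(
                config.events_per_sentence[0], config.events_per_sentence[1] + 1
            ))

            def new_entity(etype: str) -> dict:
                nonlocal mid
                mid += 1
                rec = {
                    "id": f"T{mid}",
                    "label": etype,
                    "tok": b.add_token(
                        f"{etype.lower()}{int(rng.integers(0, 999)):03d}"
                    ),
                }
                b.entities.append(rec)
                sent_entities.setdefault(etype, []).append(rec)
                return rec

            def get_entity(etype: str, allow_reuse: bool, used_ids: set) -> dict:
                # an event's argument targets must be distinct, otherwise its
                # relation decomposition would collapse repeated arguments
                pool = [
                    m for m in sent_entities.get(etype, [])
                    if m["id"] not in used_ids
                ]
                if (
                    allow_reuse
                    and pool
                    and rng.random() < config.overlap_fraction
                ):
                    return pool[int(rng.integers(0, len(pool)))]
                return new_entity(etype)

            def make_event(etype: str, ti: int, tpl: Template,
                           child: Optional[dict]) -> dict:
                nonlocal eid, tid
                tid += 1
                base = config.event_types[etype]["base"]
                if rng.random() < config.cue_strength:
                    lex = f"{base}{ti}{'ab'[int(rng.integers(0, 2))]}"
                else:
                    lex = f"{base}x"
                trig = {"id": f"TR{tid}", "label": etype, "tok": None}
                used_child = False
                used_ids: set = set()
                arg_refs = []
                for role, atype in tpl:
                    if atype in config.event_types and not used_child:
                        arg_refs.append((role, child["id"]))
                        used_child = True
                    else:
                        ent = get_entity(
                            atype, allow_reuse=bool(sent_events), used_ids=used_ids
                        )
                        used_ids.add(ent["id"])
                        arg_refs.append((role, ent["id"]))
                # layout: filler, args (new ones already emitted), trigger
                if rng.random() < 0.5:
                    b.add_token(f"w{int(rng.integers(0, config.vocab_size)):02d}")
                trig["tok"] = b.add_token(lex)
                b.triggers.append(trig)
                eid += 1
                depth = 1 + (child["depth"] if child is not None else 0)
                rec = {
                    "id": f"E{eid}",
                    "type": etype,
                    "trigger": trig["id"],
                    "args": arg_refs,
                    "depth": depth,
                }
                b.events.append(
                    {k: rec[k] for k in ("id", "type", "trigger", "args")}
                )
                sent_events.append(rec)
                return rec

            for _ in range(n_events):
                # running quota keeps the corpus-level nested rate on target
                want_nested = (
                    total_nested + 1 <= config.nested_fraction * (total_events + 1)
                )
                candidates = [
                    ev
                    for ev in sent_events
                    if ev["type"] in nested_children and ev["depth"] < config.max_depth
                ]
                if want_nested and candidates:
                    child = candidates[int(rng.integers(0, len(candidates)))]
                    parents = nested_children[child["type"]]
                    ptype, tpl = parents[int(rng.integers(0, len(parents)))]
                    ti = config.event_types[ptype]["templates"].index(tpl)
                    make_event(ptype, ti, tpl, child)
                    total_nested += 1
                else:
                    ptype, ti, tpl = flat_templates[
                        int(rng.integers(0, len(flat_templates)))
                    ]
                    make_event(ptype, ti, tpl, None)
                total_events += 1
            b.add_token(".")
            b.sentence_token_bounds.append((sent_start_tok, len(b.tokens)))
        docs.append(b.finish())
    return docs


def _plausible_fp_pool(
    doc: AnnotatedDocument,
    sent_span: Tuple[int, int],
    config: GeneratorConfig,
    gold_keys: set,
) -> List[RelationTriple]:
    """Type-plausible (trigger, role, argument) pairs absent from gold."""
    s, e = sent_span
    trigs = [m for m in doc.triggers if s <= m.start < e]
    ents = [m for m in doc.entities if s <= m.start < e]
    pool: List[RelationTriple] = []
    for trig in trigs:
        spec = config.event_types.get(trig.label)
        if spec is None:
            continue
        pairs = {(role, atype) for tpl in spec["templates"] for role, atype in tpl}
        for role, atype in sorted(pairs):
            if atype in config.event_types:
                targets = [
                    m for m in trigs if m.label == atype and m.id != trig.id
                ]
            else:
                targets = [m for m in ents if m.label == atype]
            for t in targets:
                if (trig.id, role, t.id) not in gold_keys:
                    pool.append(RelationTriple(trig, role, t))
    pool.sort(key=RelationTriple.sort_key)
    return pool


def inject_relation_noise(
    gold_triples: Sequence[RelationTriple],
    doc: AnnotatedDocument,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[RelationTriple]:
    """Emulate an imperfect upstream relation extractor.

    Each gold triple is dropped with probability ``fn_rate``; with
    probability ``fp_rate`` per sentence one type-plausible spurious triple
    is added.  Deterministic given the generator seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 7)
    kept = [t for t in gold_triples if rng.random() >= config.fn_rate]
    gold_keys = {(t.trigger.id, t.role, t.argument.id) for t in gold_triples}
    out = list(kept)
    for span in doc.sentence_spans:
        if rng.random() < config.fp_rate:
            pool = _plausible_fp_pool(doc, span, config, gold_keys)
            if pool:
                out.append(pool[int(rng.integers(0, len(pool)))])
    out.sort(key=RelationTriple.sort_key)
    return out


@dataclass
class ScenarioData:
    """Relation inputs for one pipeline training scenario."""

    name: str
    train_relations: Dict[str, List[RelationTriple]]
    eval_relations: Dict[str, List[RelationTriple]]


def make_scenario_datasets(
    corpus: Sequence[AnnotatedDocument],
    config: GeneratorConfig,
    n_train: int,
) -> Dict[str, ScenarioData]:
    """Three pipeline regimes over a train/eval document split.

    scenario1 (upper bound): gold relations for training and evaluation.
    scenario2 (pipeline): gold relations plus false positives for training,
    noisy relations for evaluation.  scenario3 (lower bound): noisy
    relations on both sides, at the base rates scaled by
    ``scenario3_noise_scale`` — emulating that an upstream extractor
    trained on predicted inputs is itself degraded.
    """
    train_docs = list(corpus[:n_train])
    eval_docs = list(corpus[n_train:])
    gold = {d.doc_id: decompose_events(d) for d in corpus}

    s = config.scenario3_noise_scale
    cfg3 = GeneratorConfig(
        **{
            **config.__dict__,
            "fn_rate": min(1.0, config.fn_rate * s),
            "fp_rate": min(1.0, config.fp_rate * s),
        }
    )
    rng_fp = np.random.default_rng(config.seed + 11)
    fp_only = GeneratorConfig(**{**config.__dict__, "fn_rate": 0.0})
    train_fp = {
        d.doc_id: inject_relation_noise(gold[d.doc_id], d, fp_only, rng_fp)
        for d in train_docs
    }
    rng_tr = np.random.default_rng(config.seed + 13)
    train_noisy = {
        d.doc_id: inject_relation_noise(gold[d.doc_id], d, cfg3, rng_tr)
        for d in train_docs
    }
    rng_ev = np.random.default_rng(config.seed + 17)
    eval_noisy = {
        d.doc_id: inject_relation_noise(gold[d.doc_id], d, config, rng_ev)
        for d in eval_docs
    }
    rng_ev3 = np.random.default_rng(config.seed + 19)
    eval_noisy3 = {
        d.doc_id: inject_relation_noise(gold[d.doc_id], d, cfg3, rng_ev3)
        for d in eval_docs
    }
    gold_train = {d.doc_id: gold[d.doc_id] for d in train_docs}
    gold_eval = {d.doc_id: gold[d.doc_id] for d in eval_docs}
    return {
        "scenario1": ScenarioData("scenario1", gold_train, gold_eval),
        "scenario2": ScenarioData("scenario2", train_fp, eval_noisy),
        "scenario3": ScenarioData("scenario3", train_noisy, eval_noisy3),
    }
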