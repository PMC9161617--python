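"""BioNLP-ST standoff I/O, event decomposition and corpus statistics.

A document is distributed over three files: ``.txt`` (raw text), ``.a1``
(given entities, ``T`` lines) and ``.a2`` (event triggers as ``T`` lines
and events as ``E`` lines).  An event line reads::

    E1<TAB>Positive_regulation:TR1 Theme:E2 Cause:T1

Offsets are 0-based half-open character offsets into the ``.txt`` content.
Role names carry enumeration suffixes in the original annotation
(``Theme1``, ``Theme2``); these are always stripped to the bare role.

Events fall into categories: *flat* (all arguments are entities), *nested*
(at least one argument is itself an event) and *overlapping* (two events
sharing at least one common argument — an entity or a sub-event).  Flat
and nested are complementary; overlapping cuts across both.
"""

from __future__ import annotations

import io
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

__all__ = [
    "Mention",
    "EventStructure",
    "AnnotatedDocument",
    "RelationTriple",
    "EventCategoryReport",
    "CorpusStats",
    "StandoffParseError",
    "StandoffStructureError",
    "read_document",
    "write_a2",
    "decompose_events",
    "categorize_events",
    "corpus_stats",
    "split_sentences",
    "strip_role_enumeration",
    "read_corpus_dir",
    "write_corpus_dir",
    "read_relations_tsv",
    "write_relations_tsv",
]


class StandoffParseError(ValueError):
    """Malformed or dangling standoff annotation."""


class StandoffStructureError(ValueError):
    """Structurally invalid annotation (cycles, unresolvable references)."""


@dataclass(frozen=True)
class Mention:
    """An annotated text span: a given entity or an event trigger."""

    id: str
    label: str
    start: int
    end: int
    surface: str

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


ArgumentTarget = Union[Mention, "EventStructure"]


@dataclass
class EventStructure:
    """A trigger plus an unordered multiset of role-labelled arguments."""

    id: str
    event_type: str
    trigger: Mention
    arguments: List[Tuple[str, ArgumentTarget]]

    def is_flat(self) -> bool:
        return all(isinstance(t, Mention) for _, t in self.arguments)

    def argument_keys(self) -> Tuple[str, ...]:
        """Identity keys of the argument targets (for overlap checks)."""
        return tuple(
            t.id if isinstance(t, Mention) else t.id for _, t in self.arguments
        )

    def multiset(self) -> Tuple[Tuple[str, str], ...]:
        """Canonical (role, argument-type) multiset of this event.

        An event argument contributes the sub-event's type.
        """
        pairs = [
            (role, t.label if isinstance(t, Mention) else t.event_type)
            for role, t in self.arguments
        ]
        return tuple(sorted(pairs))

    def structure_key(self):
        """Structural identity: (trigger id, multiset of (role, target id))."""
        return (
            self.trigger.id,
            tuple(
                sorted((role, t.id) for role, t in self.arguments)
            ),
        )


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: List[Mention] = field(default_factory=list)
    triggers: List[Mention] = field(default_factory=list)
    events: List[EventStructure] = field(default_factory=list)
    sentence_spans: List[Tuple[int, int]] = field(default_factory=list)
    equivs: List[Tuple[str, ...]] = field(default_factory=list)

    def mention(self, mid: str) -> Mention:
        for m in self.entities:
            if m.id == mid:
                return m
        for m in self.triggers:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def event(self, eid: str) -> EventStructure:
        for e in self.events:
            if e.id == eid:
                return e
        raise KeyError(eid)

    def sentence_index(self, offset: int) -> Optional[int]:
        for i, (s, e) in enumerate(self.sentence_spans):
            if s <= offset < e:
                return i
        return None


@dataclass(frozen=True)
class RelationTriple:
    """A pairwise (trigger, role, trigger/entity) relation."""

    trigger: Mention
    role: str
    argument: Mention

    def sort_key(self):
        return (self.trigger.start, self.trigger.id, self.role,
                self.argument.start, self.argument.id)


_ROLE_ENUM = re.compile(r"^(.*?[^0-9])([0-9]+)$")


def strip_role_enumeration(role: str) -> str:
    """Theme2 -> Theme; roles without a trailing enumeration pass through."""
    m = _ROLE_ENUM.match(role)
    return m.group(1) if m else role


_SENT_BOUNDARY = re.compile(r"[.!?]\s+|\n+")


def split_sentences(text: str) -> List[Tuple[int, int]]:
    """Simple period/newline sentence splitter returning character spans.

    This is deliberately naive; any statistic that depends on sentence
    boundaries records that this splitter produced them.
    """
    spans = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.end()
        if end > start:
            spans.append((start, end))
        start = end
    if start < len(text):
        spans.append((start, len(text)))
    return spans


SENTENCE_SPLITTER_NAME = "period-newline-v1"


def _as_lines(stream) -> List[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    if isinstance(stream, (io.TextIOBase, io.StringIO)) or hasattr(stream, "read"):
        return stream.read().splitlines()
    return list(stream)


def _parse_t_line(line: str, text: str, lineno_ctx: str) -> Mention:
    try:
        tid, ann, surface = line.split("\t", 2)
    except ValueError:
        try:
            tid, ann = line.split("\t", 1)
            surface = None
        except ValueError:
            raise StandoffParseError(f"malformed T line ({lineno_ctx}): {line!r}")
    parts = ann.split(" ")
    if len(parts) != 3 or ";" in ann:
        raise StandoffParseError(
            f"unsupported span annotation ({lineno_ctx}): {line!r}"
        )
    label, start_s, end_s = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise StandoffParseError(f"non-integer offsets ({lineno_ctx}): {line!r}")
    if not (0 <= start < end <= len(text)):
        raise StandoffParseError(
            f"offsets [{start},{end}) outside text of length {len(text)} "
            f"({lineno_ctx}): {line!r}"
        )
    slice_ = text[start:end]
    if surface is not None and surface != slice_:
        raise StandoffParseError(
            f"surface {surface!r} does not match text slice {slice_!r} "
            f"({lineno_ctx}): {line!r}"
        )
    return Mention(tid, label, start, end, slice_)


def read_document(
    txt_stream,
    a1_stream,
    a2_stream,
    doc_id: str = "doc",
    sentence_spans: Optional[List[Tuple[int, int]]] = None,
) -> AnnotatedDocument:
    """Parse a standoff document from its three streams (or strings).

    Role enumeration suffixes are stripped; ``*  Equiv`` lines are recorded
    on the document but never expanded.  Raises :class:`StandoffParseError`
    for dangling references or bad offsets and
    :class:`StandoffStructureError` for cyclic event references.
    """
    text = txt_stream.read() if hasattr(txt_stream, "read") else str(txt_stream)
    doc = AnnotatedDocument(doc_id=doc_id, text=text)

    for ln in _as_lines(a1_stream):
        if not ln.strip():
            continue
        if ln.startswith("T"):
            doc.entities.append(_parse_t_line(ln, text, f"{doc_id}.a1"))
        elif ln.startswith("*"):
            doc.equivs.append(tuple(ln.split("\t", 1)[1].split(" ")[1:]))
        # other line kinds (attributes, notes) are ignored

    event_lines: List[Tuple[str, str]] = []
    for ln in _as_lines(a2_stream):
        if not ln.strip():
            continue
        if ln.startswith("T"):
            doc.triggers.append(_parse_t_line(ln, text, f"{doc_id}.a2"))
        elif ln.startswith("E"):
            eid, ann = ln.split("\t", 1)
            event_lines.append((eid, ann))
        elif ln.startswith("*"):
            doc.equivs.append(tuple(ln.split("\t", 1)[1].split(" ")[1:]))

    mentions: Dict[str, Mention] = {m.id: m for m in doc.entities}
    mentions.update({m.id: m for m in doc.triggers})

    # first pass: headers and raw argument references
    raw: Dict[str, Tuple[str, str, List[Tuple[str, str]]]] = {}
    order: List[str] = []
    for eid, ann in event_lines:
        fields = ann.split(" ")
        etype, _, trig_id = fields[0].partition(":")
        if trig_id not in mentions:
            raise StandoffParseError(
                f"event {eid} references unknown trigger {trig_id!r}"
            )
        args = []
        for f in fields[1:]:
            if not f:
                continue
            role, _, ref = f.partition(":")
            args.append((strip_role_enumeration(role), ref))
        if eid in raw:
            raise StandoffParseError(f"duplicate event id {eid}")
        raw[eid] = (etype, trig_id, args)
        order.append(eid)

    # second pass: resolve, detecting cycles via DFS colouring
    resolved: Dict[str, EventStructure] = {}
    visiting: set = set()

    def resolve(eid: str) -> EventStructure:
        if eid in resolved:
            return resolved[eid]
        if eid in visiting:
            raise StandoffStructureError(f"cyclic event reference at {eid}")
        visiting.add(eid)
        etype, trig_id, args = raw[eid]
        targets: List[Tuple[str, ArgumentTarget]] = []
        for role, ref in args:
            if ref in mentions:
                targets.append((role, mentions[ref]))
            elif ref in raw:
                targets.append((role, resolve(ref)))
            else:
                raise StandoffParseError(
                    f"event {eid} argument {role}:{ref} is dangling"
                )
        visiting.discard(eid)
        ev = EventStructure(eid, etype, mentions[trig_id], targets)
        resolved[eid] = ev
        return ev

    for eid in order:
        resolve(eid)
    doc.events = [resolved[eid] for eid in order]

    doc.sentence_spans = (
        sentence_spans if sentence_spans is not None else split_sentences(text)
    )
    return doc


def write_a2(doc: AnnotatedDocument, include_entities: bool = False) -> str:
    """Serialise triggers and events back to ``.a2`` text.

    Event lines are emitted with sub-events before their parents so the
    output is parseable in a single forward pass.
    """
    out: List[str] = []
    if include_entities:
        for m in doc.entities:
            out.append(f"{m.id}\t{m.label} {m.start} {m.end}\t{m.surface}")
    for m in doc.triggers:
        out.append(f"{m.id}\t{m.label} {m.start} {m.end}\t{m.surface}")

    known = {m.id for m in doc.entities} | {m.id for m in doc.triggers}
    emitted: set = set()

    def emit(ev: EventStructure):
        if ev.id in emitted:
            return
        parts = [f"{ev.event_type}:{ev.trigger.id}"]
        if ev.trigger.id not in known:
            raise StandoffStructureError(
                f"event {ev.id} trigger {ev.trigger.id} not in document"
            )
        for role, t in ev.arguments:
            if isinstance(t, EventStructure):
                emit(t)
                parts.append(f"{role}:{t.id}")
            else:
                if t.id not in known:
                    raise StandoffStructureError(
                        f"event {ev.id} argument {t.id} not in document"
                    )
                parts.append(f"{role}:{t.id}")
        emitted.add(ev.id)
        out.append(f"{ev.id}\t" + " ".join(parts))

    for ev in doc.events:
        emit(ev)
    return "\n".join(out) + ("\n" if out else "")


def decompose_events(doc: AnnotatedDocument) -> List[RelationTriple]:
    """Break every event into its pairwise (trigger, role, argument) triples.

    Event arguments contribute the sub-event's *trigger* mention as the
    argument.  Duplicate triples (from overlapping events reusing an edge)
    are collapsed; output order is (trigger offset, role, argument offset).
    """
    seen = set()
    triples: List[RelationTriple] = []
    for ev in doc.events:
        for role, t in ev.arguments:
            arg = t if isinstance(t, Mention) else t.trigger
            key = (ev.trigger.id, role, arg.id)
            if key in seen:
                continue
            seen.add(key)
            triples.append(RelationTriple(ev.trigger, role, arg))
    triples.sort(key=RelationTriple.sort_key)
    return triples


@dataclass
class EventCategoryReport:
    """Per-event flat/nested/overlapping/inter-sentence flags."""

    flags: Dict[str, Dict[str, bool]]

    def __getitem__(self, eid: str) -> Dict[str, bool]:
        return self.flags[eid]

    def count(self, flag: str) -> int:
        return sum(1 for f in self.flags.values() if f[flag])


def categorize_events(
    doc: AnnotatedDocument, inter_sentence: bool = True
) -> EventCategoryReport:
    """Classify each gold event as flat/nested, overlapping, inter-sentence.

    Two events overlap when they share at least one common argument target
    (an entity mention or the same sub-event).  Flat and nested are
    complementary.
    """
    if inter_sentence and not doc.sentence_spans:
        raise ValueError(
            "sentence spans required for inter-sentence flags; "
            "populate doc.sentence_spans or pass inter_sentence=False"
        )
    arg_sets = {ev.id: set(ev.argument_keys()) for ev in doc.events}
    flags: Dict[str, Dict[str, bool]] = {}
    for ev in doc.events:
        nested = not ev.is_flat()
        overlapping = any(
            other.id != ev.id and arg_sets[ev.id] & arg_sets[other.id]
            for other in doc.events
        )
        inter = False
        if inter_sentence:
            ts = doc.sentence_index(ev.trigger.start)
            for _, t in ev.arguments:
                m = t if isinstance(t, Mention) else t.trigger
                if doc.sentence_index(m.start) != ts:
                    inter = True
                    break
        flags[ev.id] = {
            "is_flat": not nested,
            "is_nested": nested,
            "is_overlapping": overlapping,
            "is_inter_sentence": inter,
        }
    return EventCategoryReport(flags)


@dataclass
class CorpusStats:
    documents: int
    sentences: int
    events: int
    pct_flat: float
    pct_nested: float
    pct_overlapping: float
    pct_inter_sentence: float
    per_type_counts: Dict[str, int]
    per_type_arg_histogram: Dict[str, Dict[int, int]]
    per_type_category_counts: Dict[str, Dict[str, int]]
    pct_unknown_words: Optional[float]
    sentence_splitter: str = SENTENCE_SPLITTER_NAME

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["per_type_arg_histogram"] = {
            t: {str(k): v for k, v in h.items()}
            for t, h in self.per_type_arg_histogram.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        """Type x argument-count matrix, heatmap-ready."""
        max_args = max(
            (k for h in self.per_type_arg_histogram.values() for k in h),
            default=0,
        )
        cols = list(range(max_args + 1))
        lines = ["event_type\ttotal\t" + "\t".join(f"args={c}" for c in cols)]
        for t in sorted(self.per_type_counts):
            h = self.per_type_arg_histogram.get(t, {})
            row = [t, str(self.per_type_counts[t])]
            row += [str(h.get(c, 0)) for c in cols]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def _word_tokens(text: str) -> List[str]:
    return _TOKEN_RE.findall(text)


def corpus_stats(
    corpus: Iterable[AnnotatedDocument],
    reference_vocabulary: Optional[set] = None,
) -> CorpusStats:
    """Aggregate event-category and argument-count statistics over a corpus.

    ``reference_vocabulary`` (typically the training-set vocabulary) enables
    the unknown-word percentage; the value is tokenizer-dependent and is
    reported, not guaranteed.
    """
    docs = list(corpus)
    n_events = 0
    n_flat = n_nested = n_over = n_inter = 0
    per_type: Counter = Counter()
    histo: Dict[str, Counter] = {}
    cats: Dict[str, Counter] = {}
    n_sent = 0
    n_tok = n_unk = 0
    for doc in docs:
        n_sent += len(doc.sentence_spans)
        report = categorize_events(doc, inter_sentence=bool(doc.sentence_spans))
        for ev in doc.events:
            n_events += 1
            f = report[ev.id]
            n_flat += f["is_flat"]
            n_nested += f["is_nested"]
            n_over += f["is_overlapping"]
            n_inter += f["is_inter_sentence"]
            per_type[ev.event_type] += 1
            histo.setdefault(ev.event_type, Counter())[len(ev.arguments)] += 1
            c = cats.setdefault(
                ev.event_type, Counter({"flat": 0, "nested": 0, "overlapping": 0})
            )
            for name, key in (
                ("flat", "is_flat"),
                ("nested", "is_nested"),
                ("overlapping", "is_overlapping"),
            ):
                c[name] += f[key]
        if reference_vocabulary is not None:
            toks = _word_tokens(doc.text)
            n_tok += len(toks)
            n_unk += sum(1 for t in toks if t not in reference_vocabulary)

    pct = lambda k: (100.0 * k / n_events) if n_events else 0.0
    return CorpusStats(
        documents=len(docs),
        sentences=n_sent,
        events=n_events,
        pct_flat=pct(n_flat),
        pct_nested=pct(n_nested),
        pct_overlapping=pct(n_over),
        pct_inter_sentence=pct(n_inter),
        per_type_counts=dict(per_type),
        per_type_arg_histogram={t: dict(h) for t, h in histo.items()},
        per_type_category_counts={t: dict(c) for t, c in cats.items()},
        pct_unknown_words=(
            (100.0 * n_unk / n_tok) if reference_vocabulary is not None and n_tok else
            (0.0 if reference_vocabulary is not None else None)
        ),
    )


# ---------------------------------------------------------------------------
# corpus directories (one .txt/.a1/.a2 triple per document) and the
# predicted-relations sidecar (doc id, trigger id, role, argument id)


def read_corpus_dir(path) -> List[AnnotatedDocument]:
    """Read every ``.txt``/``.a1``/``.a2`` triple under a directory."""
    import os

    docs = []
    names = sorted(
        f[:-4] for f in os.listdir(path) if f.endswith(".txt")
    )
    if not names:
        raise FileNotFoundError(f"no .txt documents under {path!r}")
    for name in names:
        def load(ext):
            p = os.path.join(path, name + ext)
            if os.path.exists(p):
                with open(p) as fh:
                    return fh.read()
            return ""

        docs.append(
            read_document(load(".txt"), load(".a1"), load(".a2"), doc_id=name)
        )
    return docs


def write_corpus_dir(path, docs: Iterable[AnnotatedDocument]) -> None:
    import os

    os.makedirs(path, exist_ok=True)
    for doc in docs:
        with open(os.path.join(path, doc.doc_id + ".txt"), "w") as fh:
            fh.write(doc.text)
        with open(os.path.join(path, doc.doc_id + ".a1"), "w") as fh:
            for m in doc.entities:
                fh.write(f"{m.id}\t{m.label} {m.start} {m.end}\t{m.surface}\n")
        with open(os.path.join(path, doc.doc_id + ".a2"), "w") as fh:
            fh.write(write_a2(doc))


def write_relations_tsv(path, relations: Dict[str, List[RelationTriple]]) -> None:
    with open(path, "w") as fh:
        for doc_id in sorted(relations):
            for t in relations[doc_id]:
                fh.write(
                    f"{doc_id}\t{t.trigger.id}\t{t.role}\t{t.argument.id}\n"
                )


def read_relations_tsv(
    path, docs: Iterable[AnnotatedDocument]
) -> Dict[str, List[RelationTriple]]:
    """Resolve a relations sidecar against the corpus' mentions."""
    by_doc = {d.doc_id: d for d in docs}
    out: Dict[str, List[RelationTriple]] = {d: [] for d in by_doc}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            try:
                doc_id, trig_id, role, arg_id = ln.split("\t")
                doc = by_doc[doc_id]
                out[doc_id].append(
                    RelationTriple(doc.mention(trig_id), role, doc.mention(arg_id))
                )
            except (ValueError, KeyError) as exc:
                raise StandoffParseError(
                    f"bad relations line {lineno}: {ln!r} ({exc})"
                )
    return out
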