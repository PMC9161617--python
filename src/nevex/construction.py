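"""Candidate events construction over pairwise relations.

Four steps: (1) pairwise relation triples (from gold decomposition or an
external relation predictor), (2) per-trigger adjacency lists, (3) a DAG
over triggers/entities with a topological order and bottom-up level groups,
(4) event-structure templates — per event type, the set of valid
(role, argument-type) multisets observed in training gold — used to filter
candidate structures.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

from .standoff import AnnotatedDocument, Mention, RelationTriple

__all__ = [
    "RelationGraph",
    "TemplateSet",
    "CandidateMultiset",
    "build_adjacency",
    "build_graph",
    "extract_templates",
    "match_template",
]

log = logging.getLogger(__name__)

Multiset = Tuple[Tuple[str, str], ...]  # sorted (role, argument-type) pairs

Adjacency = Dict[str, List[Tuple[str, Mention]]]


def build_adjacency(triples: Iterable[RelationTriple]) -> "AdjacencyMap":
    """Group relations into an ordered per-trigger argument list.

    Arguments are ordered by (text offset, role name) so downstream
    processing is independent of input order.
    """
    by_trigger: Dict[str, List[Tuple[str, Mention]]] = defaultdict(list)
    mentions: Dict[str, Mention] = {}
    for t in sorted(set(triples), key=RelationTriple.sort_key):
        by_trigger[t.trigger.id].append((t.role, t.argument))
        mentions[t.trigger.id] = t.trigger
        mentions.setdefault(t.argument.id, t.argument)
    for tid in by_trigger:
        by_trigger[tid].sort(key=lambda ra: (ra[1].start, ra[0], ra[1].id))
    return AdjacencyMap(dict(by_trigger), mentions)


@dataclass
class AdjacencyMap:
    """Per-trigger ordered argument lists plus the mention table."""

    lists: Dict[str, List[Tuple[str, Mention]]]
    mentions: Dict[str, Mention]

    def __getitem__(self, trigger_id: str) -> List[Tuple[str, Mention]]:
        return self.lists[trigger_id]

    def __contains__(self, trigger_id: str) -> bool:
        return trigger_id in self.lists

    def __len__(self) -> int:
        return len(self.lists)

    def total_relations(self) -> int:
        return sum(len(v) for v in self.lists.values())


@dataclass
class RelationGraph:
    """DAG over mentions with a topological order and bottom-up levels.

    ``levels[0]`` holds triggers all of whose arguments are entities;
    ``levels[g]`` holds triggers whose deepest trigger-argument sits in
    level ``g - 1``.  Entities carry no level.  ``topo_order`` lists nodes
    arguments-first (bottom-up processing order).
    """

    nodes: Dict[str, Mention]
    edges: List[Tuple[str, str, str]]  # (trigger id, role, argument id)
    topo_order: List[str]
    levels: List[List[str]] = field(default_factory=list)
    removed_edges: List[Tuple[str, str, str]] = field(default_factory=list)

    def arguments_of(self, trigger_id: str) -> List[Tuple[str, Mention]]:
        out = [
            (role, self.nodes[a]) for (t, role, a) in self.edges if t == trigger_id
        ]
        out.sort(key=lambda ra: (ra[1].start, ra[0], ra[1].id))
        return out

    def trigger_level(self, trigger_id: str) -> Optional[int]:
        for g, group in enumerate(self.levels):
            if trigger_id in group:
                return g
        return None


def _edge_sort_key(nodes: Dict[str, Mention], e: Tuple[str, str, str]):
    t, role, a = e
    return (nodes[t].start, nodes[t].id, role, nodes[a].start, nodes[a].id)


def build_graph(adjacency: AdjacencyMap) -> RelationGraph:
    """Build the relation DAG with topological order and level groups.

    Predicted relations may contain cycles; each cycle is broken by
    removing its lexicographically last edge (by trigger offset, role,
    argument offset), logged as a warning.  Self-loops are dropped.
    """
    nodes = dict(adjacency.mentions)
    edges: List[Tuple[str, str, str]] = []
    removed: List[Tuple[str, str, str]] = []
    for tid, args in adjacency.lists.items():
        for role, arg in args:
            if arg.id == tid:
                log.warning("dropping self-loop relation on %s", tid)
                removed.append((tid, role, arg.id))
                continue
            edges.append((tid, role, arg.id))

    g = nx.MultiDiGraph()
    g.add_nodes_from(nodes)
    for t, role, a in edges:
        g.add_edge(t, a, role=role)

    # break cycles deterministically
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        cycle_edges = [
            (u, v, g.edges[u, v, k]["role"]) for u, v, k in cycle
        ]
        u, v, role = max(
            cycle_edges,
            key=lambda e: _edge_sort_key(nodes, (e[0], e[2], e[1])),
        )
        log.warning("breaking relation cycle by removing %s-%s->%s", u, role, v)
        removed.append((u, role, v))
        for k in list(g[u][v]):
            if g.edges[u, v, k]["role"] == role:
                g.remove_edge(u, v, key=k)
                break
        edges.remove((u, role, v))

    # bottom-up topological order: arguments before the triggers using them
    order = list(
        nx.lexicographical_topological_sort(
            g.reverse(copy=True), key=lambda n: (nodes[n].start, n)
        )
    )

    # level groups over triggers (nodes with outgoing edges)
    is_trigger = {t for t, _, _ in edges}
    level_of: Dict[str, int] = {}
    for n in order:
        if n not in is_trigger:
            continue
        trig_args = [a for (t, _, a) in edges if t == n and a in is_trigger]
        level_of[n] = 1 + max((level_of[a] for a in trig_args), default=-1)
    n_levels = 1 + max(level_of.values(), default=-1)
    levels = [[] for _ in range(n_levels)]
    for n, lv in level_of.items():
        levels[lv].append(n)
    for group in levels:
        group.sort(key=lambda n: (nodes[n].start, n))

    return RelationGraph(
        nodes=nodes,
        edges=sorted(edges, key=lambda e: _edge_sort_key(nodes, e)),
        topo_order=order,
        levels=levels,
        removed_edges=removed,
    )


@dataclass
class TemplateSet:
    """Per event type, the observed set of valid argument multisets."""

    by_type: Dict[str, set] = field(default_factory=dict)

    def add(self, event_type: str, multiset: Multiset) -> None:
        if not multiset:
            return
        self.by_type.setdefault(event_type, set()).add(tuple(sorted(multiset)))

    def templates_for(self, event_type: str) -> frozenset:
        return frozenset(self.by_type.get(event_type, ()))

    def max_arity(self, event_type: str) -> int:
        return max((len(m) for m in self.by_type.get(event_type, ())), default=0)

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_type.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                t: sorted([list(p) for p in m] for m in ms)
                for t, ms in self.by_type.items()
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TemplateSet":
        data = json.loads(text)
        ts = cls()
        for t, multisets in data.items():
            for m in multisets:
                ts.add(t, tuple((r, a) for r, a in m))
        return ts


@dataclass(frozen=True)
class CandidateMultiset:
    """A candidate structure's type plus its (role, argument-type) multiset."""

    event_type: str
    pairs: Multiset

    @classmethod
    def from_pairs(cls, event_type: str, pairs: Iterable[Tuple[str, str]]):
        return cls(event_type, tuple(sorted(pairs)))


def extract_templates(gold_corpus: Iterable[AnnotatedDocument]) -> TemplateSet:
    """Collect every gold event's (role, argument-type) multiset per type.

    The argument-type of an event argument is the sub-event's type.
    """
    ts = TemplateSet()
    for doc in gold_corpus:
        for ev in doc.events:
            ts.add(ev.event_type, ev.multiset())
    return ts


def match_template(candidate: CandidateMultiset, templates: TemplateSet) -> bool:
    """Exact, multiplicity-sensitive multiset membership in F_t.

    Unknown event types and empty candidates simply fail to match.
    """
    if not candidate.pairs:
        return False
    return tuple(sorted(candidate.pairs)) in templates.templates_for(
        candidate.event_type
    )
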