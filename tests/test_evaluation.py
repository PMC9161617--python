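"""Approximate span matching, recursive event matching, category scoring."""

import copy
import re

import numpy as np
import pytest

import nevex as nv
from nevex.evaluation import extend_span
from nevex.standoff import Mention


TEXT = "alpha beta gamma delta epsilon"


def m(mid, label, start, end):
    return Mention(mid, label, start, end, TEXT[start:end])


class TestMatchMention:
    def test_identical_mentions_match_in_both_modes(self):
        a = m("T1", "GGP", 6, 10)
        assert nv.match_mention(a, a, "exact")
        assert nv.match_mention(a, a, "approximate", TEXT)

    def test_one_word_extension_matches_approximately_only(self):
        gold = m("T1", "GGP", 11, 16)  # "gamma"
        pred = m("P1", "GGP", 6, 16)  # "beta gamma"
        assert not nv.match_mention(pred, gold, "exact")
        assert nv.match_mention(pred, gold, "approximate", TEXT)

    def test_two_word_extension_fails_approximately(self):
        gold = m("T1", "GGP", 11, 16)
        pred = m("P1", "GGP", 0, 16)  # two extra words to the left
        assert not nv.match_mention(pred, gold, "approximate", TEXT)

    def test_type_mismatch_never_matches(self):
        assert not nv.match_mention(
            m("P1", "Cancer", 6, 10), m("T1", "GGP", 6, 10), "approximate", TEXT
        )

    def test_random_perturbations_agree_with_independent_predicate(self):
        rng = np.random.default_rng(4)
        words = [(mo.start(), mo.end()) for mo in re.finditer(r"\S+", TEXT)]
        for _ in range(200):
            gi = int(rng.integers(0, len(words)))
            gold = m("T1", "GGP", *words[gi])
            ps = int(rng.integers(0, len(TEXT) - 1))
            pe = int(rng.integers(ps + 1, len(TEXT) + 1))
            pred = m("P1", "GGP", ps, pe)
            # independent restatement: allowed window is gold span plus at
            # most one whitespace-delimited word on each side
            lo = words[gi - 1][0] if gi > 0 else words[gi][0]
            hi = words[gi + 1][1] if gi + 1 < len(words) else words[gi][1]
            allowed = lo <= ps and pe <= hi
            assert nv.match_mention(pred, gold, "approximate", TEXT) == allowed

    def test_extend_span_at_text_boundaries(self):
        assert extend_span(TEXT, 0, 5) == (0, 10)
        assert extend_span(TEXT, 23, 30) == (17, 30)


def _tiny_doc():
    txt = "ggp1 expr1 indu1 ."
    a1 = "T1\tGGP 0 4\tggp1"
    a2 = (
        "TR1\tGene_expression 5 10\texpr1\n"
        "TR2\tPositive_regulation 11 16\tindu1\n"
        "E1\tGene_expression:TR1 Theme:T1\n"
        "E2\tPositive_regulation:TR2 Theme:E1\n"
    )
    return nv.read_document(txt, a1, a2, doc_id="tiny")


class TestMatchEvent:
    def test_event_matches_itself(self):
        doc = _tiny_doc()
        for ev in doc.events:
            assert nv.match_event(ev, ev, "approximate", doc.text)

    def test_corrupted_flat_level_breaks_nested_match(self, worked_example):
        doc = worked_example
        corrupt = copy.deepcopy(doc)
        e1 = corrupt.event("E1")
        other = Mention("TX", "Cancer", 0, 2, doc.text[0:2])
        e1.arguments = [("Theme", other)]
        assert not nv.match_event(
            corrupt.event("E2"), doc.event("E2"), "approximate", doc.text
        )

    def test_argument_pairing_is_role_preserving(self):
        doc = _tiny_doc()
        e1 = doc.event("E1")
        swapped = copy.deepcopy(e1)
        swapped.arguments = [("Cause", swapped.arguments[0][1])]
        assert not nv.match_event(swapped, e1, "approximate", doc.text)

    def test_random_argument_sets_agree_with_permutation_bruteforce(self):
        from itertools import permutations

        rng = np.random.default_rng(8)
        ents = [m(f"T{i}", "GGP", 6 * i, 6 * i + 5) for i in range(5)]
        trig = m("TR", "Binding", 0, 5)
        for _ in range(120):
            np_, ng = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p_args = [
                ("Theme", ents[rng.integers(0, len(ents))]) for _ in range(np_)
            ]
            g_args = [
                ("Theme", ents[rng.integers(0, len(ents))]) for _ in range(ng)
            ]
            pe = nv.EventStructure("P", "Binding", trig, list(p_args))
            ge = nv.EventStructure("G", "Binding", trig, list(g_args))
            got = nv.match_event(pe, ge, "exact")
            brute = len(p_args) == len(g_args) and any(
                all(
                    p_args[i][0] == perm[i][0]
                    and p_args[i][1].start == perm[i][1].start
                    and p_args[i][1].end == perm[i][1].end
                    for i in range(len(p_args))
                )
                for perm in permutations(g_args)
            )
            assert got == brute


class TestScore:
    def test_gold_scored_against_itself_is_all_ones(self, small_corpus):
        docs, _ = small_corpus
        report = nv.score(docs[:30], docs[:30])
        for cat in ("all", "nested", "overlapping", "flat"):
            assert report.precision(cat) == 1.0
            assert report.recall(cat) == 1.0
            assert report.f1(cat) == 1.0

    def test_removing_one_nested_event_changes_nested_recall_by_one_over_n(
        self, small_corpus
    ):
        docs, _ = small_corpus
        gold = [copy.deepcopy(d) for d in docs[:30]]
        pred = [copy.deepcopy(d) for d in docs[:30]]
        flags = {d.doc_id: nv.categorize_events(d) for d in gold}
        n_nested = sum(
            1 for d in gold for e in d.events if flags[d.doc_id][e.id]["is_nested"]
        )
        removed = False
        for d in pred:
            for e in list(d.events):
                if not e.is_flat() and not removed:
                    # only drop an event no other event references
                    referenced = any(
                        t is e for o in d.events for _, t in o.arguments
                    )
                    if not referenced:
                        d.events.remove(e)
                        removed = True
        assert removed
        report = nv.score(pred, gold)
        assert report.recall("nested") == pytest.approx(1 - 1 / n_nested)
        assert report.precision("nested") == 1.0

    def test_monotonicity_under_prediction_edits(self, small_corpus):
        docs, _ = small_corpus
        gold = docs[:15]
        pred = [copy.deepcopy(d) for d in gold]
        base = nv.score(pred, gold)
        # removing a predicted event never increases recall
        fewer = [copy.deepcopy(d) for d in gold]
        for d in fewer:
            if d.events:
                top = [
                    e for e in d.events
                    if not any(t is e for o in d.events for _, t in o.arguments)
                ]
                if top:
                    d.events.remove(top[0])
                break
        assert nv.score(fewer, gold).recall("all") <= base.recall("all")
        # adding a non-matching event never increases precision
        extra = [copy.deepcopy(d) for d in gold]
        d0 = extra[0]
        trig = d0.triggers[0]
        bogus = nv.EventStructure(
            "EX", trig.label, trig,
            [("Theme", d0.entities[0]), ("Theme", d0.entities[0])],
        )
        d0.events.append(bogus)
        assert nv.score(extra, gold).precision("all") <= base.precision("all")

    def test_nested_tp_implies_matching_subevents(self, worked_example):
        doc = worked_example
        report = nv.score([doc], [doc])
        # the two nested events match, and so does their shared flat sub-event
        assert report.cell("nested").tp_predicted == 2
        assert report.cell("flat").tp_predicted == 1

    def test_controlled_corruption_gives_matching_recall(self):
        cfg = nv.GeneratorConfig(seed=31, n_docs=200, nested_fraction=0.3,
                                 overlap_fraction=0.3)
        docs = nv.generate_corpus(cfg)
        rng = np.random.default_rng(2)
        c = 0.1
        pred = []
        dropped = total = 0
        for d in docs:
            p = copy.deepcopy(d)
            keep = []
            drop_ids = set()
            for e in p.events:
                total += 1
                referenced = any(t is e for o in p.events for _, t in o.arguments)
                if not referenced and rng.random() < c:
                    drop_ids.add(e.id)
                    dropped += 1
                else:
                    keep.append(e)
            p.events = keep
            pred.append(p)
        report = nv.score(pred, docs)
        assert report.recall("all") == pytest.approx(1 - dropped / total)
        assert abs(report.recall("all") - (1 - c)) < 0.05

    def test_duplicate_gold_document_ids_rejected(self, small_corpus):
        docs, _ = small_corpus
        with pytest.raises(ValueError):
            nv.score([docs[0]], [docs[0], docs[0]])

    def test_report_serialisations_are_consistent(self, small_corpus):
        import json

        docs, _ = small_corpus
        report = nv.score(docs[:5], docs[:5])
        data = json.loads(report.to_json())
        assert data["by_category"]["all"]["f1"] == 1.0
        assert "overall\tall" in report.to_tsv()
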