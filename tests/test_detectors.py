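"""SBNN beam search and EXNN enumeration/classification behaviour."""

import numpy as np
import pytest

import nevex as nv
from nevex.construction import CandidateMultiset, TemplateSet
from nevex.detection import (
    ADD,
    CONSTRUCT,
    IGNORE,
    AcceptAllScorer,
    CandidateArg,
    OracleScorer,
    RejectAllScorer,
    TriggerContext,
)
from nevex.exnn import enumerate_candidates
from nevex.sbnn import BeamState, SBNNConfig, expand_state, search_trigger
from nevex.standoff import Mention


def make_trigger(label="Binding", start=0):
    return TriggerContext(Mention("TRX", label, start, start + 4, "bind"))


def make_args(n, role="Theme", label="GGP"):
    return [
        CandidateArg(
            role,
            Mention(f"T{i}", label, 100 + 10 * i, 103 + 10 * i, "ggp"),
            label,
            ("TRX", role, f"T{i}"),
        )
        for i in range(n)
    ]


def permissive_templates(etype="Binding", max_arity=8, role="Theme", atype="GGP"):
    ts = TemplateSet()
    for size in range(1, max_arity + 1):
        ts.add(etype, ((role, atype),) * size)
    return ts


class TestExpandState:
    def test_three_successors_consume_the_head(self):
        state = BeamState(trigger=make_trigger(), buffer=tuple(make_args(2)))
        succ = expand_state(state, AcceptAllScorer())
        assert len(succ) == 3
        assert {s.action_history[-1] for s in succ} == {ADD, IGNORE, CONSTRUCT}
        assert all(s.position == 1 for s in succ)

    def test_construct_marks_emission_ignore_does_not(self):
        state = BeamState(trigger=make_trigger(), buffer=tuple(make_args(1)))
        by_action = {
            s.action_history[-1]: s for s in expand_state(state, AcceptAllScorer())
        }
        assert by_action[CONSTRUCT].emitted
        assert not by_action[IGNORE].emitted and not by_action[ADD].emitted

    def test_unpruned_expansion_yields_3_pow_n_leaves(self):
        n = 4
        states = [BeamState(trigger=make_trigger(), buffer=tuple(make_args(n)))]
        scorer = AcceptAllScorer()
        for _ in range(n):
            states = [s2 for s in states for s2 in expand_state(s, scorer)]
        assert len(states) == 3**n

    def test_empty_buffer_cannot_expand(self):
        state = BeamState(trigger=make_trigger(), buffer=())
        with pytest.raises(ValueError):
            expand_state(state, AcceptAllScorer())


class TestSearchTrigger:
    def test_accept_all_with_huge_beam_emits_every_template_subset(self):
        n = 5
        args = make_args(n)
        ts = permissive_templates()
        out = search_trigger(
            make_trigger(), args, ts, SBNNConfig(k=3**n, threshold=0.0),
            AcceptAllScorer(),
        )
        assert len(out) == 2**n - 1

    def test_zero_candidates_give_empty_result(self):
        out = search_trigger(
            make_trigger(), [], permissive_templates(), SBNNConfig(), AcceptAllScorer()
        )
        assert out == []

    def test_reject_all_emits_nothing(self):
        out = search_trigger(
            make_trigger(), make_args(3), permissive_templates(),
            SBNNConfig(k=100, threshold=0.5), RejectAllScorer(),
        )
        assert out == []

    def test_emissions_monotone_in_beam_width(self):
        args = make_args(5)
        ts = permissive_templates(max_arity=3)
        sizes = []
        emitted_sets = []
        for k in (1, 2, 4, 8, 64, 3**5):
            out = search_trigger(
                make_trigger(), args, ts, SBNNConfig(k=k, threshold=0.0),
                AcceptAllScorer(),
            )
            keys = {e.key() for e in out}
            sizes.append(len(keys))
            emitted_sets.append(keys)
        assert sizes == sorted(sizes)
        for small, big in zip(emitted_sets, emitted_sets[1:]):
            assert small <= big

    def test_beam_never_holds_more_than_k_states(self):
        k = 4

        class CountingScorer(AcceptAllScorer):
            def __init__(self):
                super().__init__()
                self.per_step = []

            def score_actions(self, ctx, items, head):
                self.per_step.append(len(items))
                return super().score_actions(ctx, items, head)

        scorer = CountingScorer()
        search_trigger(
            make_trigger(), make_args(6), permissive_templates(), SBNNConfig(k=k),
            scorer,
        )
        from collections import Counter

        per_depth = Counter(scorer.per_step)
        assert all(v <= k for d, v in per_depth.items() if d > 0)

    def test_oracle_on_worked_example_returns_both_overlapping_events(
        self, worked_example
    ):
        doc = worked_example
        ts = nv.extract_templates([doc])
        oracle = OracleScorer(doc.events)
        e1 = doc.event("E1")
        sub = nv.ScoredEvent(
            e1.trigger, e1.event_type,
            [
                (r, CandidateArg(r, t, t.label, (e1.trigger.id, r, t.id)))
                for r, t in e1.arguments
            ],
            1.0,
        )
        tr1 = doc.mention("TR1")
        cargs = [
            CandidateArg("Cause", doc.mention("T1"), "Gene-or-Gene-Product",
                         ("TR1", "Cause", "T1")),
            CandidateArg("Cause", doc.mention("T2"), "Gene-or-Gene-Product",
                         ("TR1", "Cause", "T2")),
            CandidateArg("Theme", doc.mention("TR2"), "Blood_vessel_development",
                         ("TR1", "Theme", "TR2"), sub),
        ]
        out = search_trigger(
            TriggerContext(tr1), cargs, ts, SBNNConfig(k=8), oracle
        )
        assert len(out) == 2  # E2 and E3 from the same trigger
        causes = {
            a.mention.id for e in out for role, a in e.arguments if role == "Cause"
        }
        assert causes == {"T1", "T2"}

    def test_threshold_zero_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(1, 7))
            roles = ["Theme", "Cause"]
            args = [
                CandidateArg(
                    roles[rng.integers(0, 2)],
                    Mention(f"T{i}", "GGP", 100 + 10 * i, 103 + 10 * i, "ggp"),
                    "GGP",
                    ("TRX", roles[0], f"T{i}"),
                )
                for i in range(n)
            ]
            args = [
                CandidateArg(a.role, a.mention, a.arg_type,
                             ("TRX", a.role, a.mention.id))
                for a in args
            ]
            ts = TemplateSet()
            for _ in range(int(rng.integers(1, 5))):
                size = int(rng.integers(1, 4))
                ts.add(
                    "Binding",
                    tuple(
                        (roles[rng.integers(0, 2)], "GGP") for _ in range(size)
                    ),
                )
            sb = search_trigger(
                make_trigger(), args, ts, SBNNConfig(k=3**8, threshold=0.0),
                AcceptAllScorer(),
            )
            ex = enumerate_candidates(make_trigger(), args, ts)
            sb_keys = {tuple(sorted((r, a.mention.id) for r, a in e.arguments))
                       for e in sb}
            ex_keys = {
                tuple(sorted((a.role, a.mention.id) for a in m.chosen()))
                for m in ex
            }
            assert sb_keys == ex_keys


class TestEnumerateCandidates:
    def test_zero_arguments_give_empty_list(self):
        assert enumerate_candidates(make_trigger(), [], permissive_templates()) == []

    def test_equals_template_filtered_powerset(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(1, 8))
            args = make_args(n)
            ts = permissive_templates(max_arity=int(rng.integers(1, 5)))
            got = enumerate_candidates(make_trigger(), args, ts)
            from itertools import combinations

            brute = [
                subset
                for size in range(1, n + 1)
                for subset in combinations(args, size)
                if nv.match_template(
                    CandidateMultiset.from_pairs(
                        "Binding", [(a.role, a.arg_type) for a in subset]
                    ),
                    ts,
                )
            ]
            assert len(got) == len(brute)
            assert len(got) <= 2**n - 1

    def test_argument_cap_skips_trigger_with_warning(self, caplog):
        args = make_args(5)
        with caplog.at_level("WARNING"):
            out = enumerate_candidates(
                make_trigger(), args, permissive_templates(), max_args=4
            )
        assert out == []
        assert "skipping" in caplog.text

    def test_two_groundings_of_one_relation_never_coselected(self):
        sub_trigger = Mention("TRS", "Gene_expression", 200, 204, "expr")
        preds = [
            nv.ScoredEvent(sub_trigger, "Gene_expression",
                           [("Theme", make_args(1)[0])], 1.0),
            nv.ScoredEvent(sub_trigger, "Gene_expression",
                           [("Theme", make_args(2)[1])], 1.0),
        ]
        cargs = [
            CandidateArg("Theme", sub_trigger, "Gene_expression",
                         ("TRX", "Theme", "TRS"), p)
            for p in preds
        ]
        ts = permissive_templates("Binding", 2, "Theme", "Gene_expression")
        out = enumerate_candidates(make_trigger(), cargs, ts)
        assert all(len(m.chosen()) == 1 for m in out)


class TestDetectTriggerEvents:
    def test_accept_all_returns_every_template_valid_subset(self):
        args = make_args(4)
        ts = permissive_templates(max_arity=2)
        out = nv.detect_trigger_events(
            make_trigger(), args, ts, 0.5, AcceptAllScorer()
        )
        assert len(out) == 4 + 6

    def test_reject_all_returns_nothing(self):
        out = nv.detect_trigger_events(
            make_trigger(), make_args(4), permissive_templates(), 0.5,
            RejectAllScorer(),
        )
        assert out == []


class TestEXNNClassifier:
    @pytest.fixture
    def scorer(self):
        from nevex.exnn import EXNNScorer
        from nevex.neural import EmbeddingConfig, NeuralCore, Vocabulary

        core = NeuralCore(
            EmbeddingConfig(seed=2),
            Vocabulary(["bind", "ggp"]),
            Vocabulary(["Binding", "GGP"]),
            Vocabulary(["Theme"]),
        )
        return core, EXNNScorer(core)

    def _marked(self, core, n=4, k_in=2, order=None):
        from nevex.exnn import MarkedCandidate

        vecs = core.encode_sentence(["bind"] + ["ggp"] * n)
        spans = [(i * 5, i * 5 + 4) for i in range(n + 1)]
        trig = TriggerContext(
            Mention("TRX", "Binding", 0, 4, "bind"),
            core.mention_representation(
                Mention("TRX", "Binding", 0, 4, "bind"), spans, vecs
            ),
        )
        args = []
        for i in range(n):
            m = Mention(f"T{i}", "GGP", (i + 1) * 5, (i + 1) * 5 + 4, "ggp")
            args.append(
                CandidateArg(
                    "Theme", m, "GGP", ("TRX", "Theme", m.id),
                    None, core.mention_representation(m, spans, vecs),
                )
            )
        idx = order if order is not None else list(range(n))
        rels = tuple(args[i] for i in idx)
        mask = tuple(i < k_in for i in idx)
        return MarkedCandidate(trig, rels, mask)

    def test_probability_in_unit_interval_and_deterministic(self, scorer):
        core, sc = scorer
        m = self._marked(core)
        p1 = nv.classify_candidate(m, sc)
        p2 = nv.classify_candidate(m, sc)
        assert 0.0 <= p1 <= 1.0 and p1 == p2

    def test_relation_order_permutation_invariance(self, scorer):
        core, sc = scorer
        rng = np.random.default_rng(0)
        base = nv.classify_candidate(self._marked(core), sc)
        for _ in range(20):
            order = list(rng.permutation(4))
            p = nv.classify_candidate(self._marked(core, order=order), sc)
            assert p == pytest.approx(base, abs=1e-9)

    def test_in_out_mask_changes_probability(self, scorer):
        core, sc = scorer
        p2 = nv.classify_candidate(self._marked(core, k_in=2), sc)
        p3 = nv.classify_candidate(self._marked(core, k_in=3), sc)
        assert p2 != p3

    def test_candidate_requires_at_least_one_in_relation(self, scorer):
        core, _ = scorer
        with pytest.raises(ValueError):
            self._marked(core, k_in=0)
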