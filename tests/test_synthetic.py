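"""Generator reproducibility, rate targeting, and relation-noise injection."""

import numpy as np
import pytest

import nevex as nv
from nevex.standoff import decompose_events


class TestGenerateCorpus:
    def test_same_seed_gives_byte_identical_standoff(self):
        cfg = dict(seed=13, n_docs=40, nested_fraction=0.3, overlap_fraction=0.5)
        a = nv.generate_corpus(nv.GeneratorConfig(**cfg))
        b = nv.generate_corpus(nv.GeneratorConfig(**cfg))
        for da, db in zip(a, b):
            assert da.text == db.text
            assert nv.write_a2(da) == nv.write_a2(db)

    def test_zero_nested_fraction_gives_all_flat_events(self):
        docs = nv.generate_corpus(
            nv.GeneratorConfig(seed=1, n_docs=50, nested_fraction=0.0)
        )
        assert all(e.is_flat() for d in docs for e in d.events)

    def test_every_category_is_exercised(self, small_corpus):
        docs, _ = small_corpus
        st = nv.corpus_stats(docs)
        assert st.pct_flat > 0 and st.pct_nested > 0 and st.pct_overlapping > 0

    def test_depth_two_overlap_reproduces_shared_subevent_topology(self):
        docs = nv.generate_corpus(
            nv.GeneratorConfig(seed=3, n_docs=150, nested_fraction=0.5,
                               overlap_fraction=0.9, max_depth=2)
        )
        found = False
        for d in docs:
            parents_of = {}
            for e in d.events:
                for _, t in e.arguments:
                    if not isinstance(t, nv.Mention):
                        parents_of.setdefault(t.id, []).append(e.id)
            if any(len(p) >= 2 for p in parents_of.values()):
                found = True
                break
        assert found, "no flat event shared by two nested parents was generated"

    def test_max_depth_respected(self):
        docs = nv.generate_corpus(
            nv.GeneratorConfig(seed=2, n_docs=100, nested_fraction=0.6,
                               max_depth=2, events_per_sentence=(3, 4))
        )

        def depth(ev):
            subs = [t for _, t in ev.arguments if not isinstance(t, nv.Mention)]
            return 1 + max((depth(s) for s in subs), default=0)

        assert max(depth(e) for d in docs for e in d.events) <= 2

    def test_nested_fraction_within_sampling_error_at_1000_events(self):
        cfg = nv.GeneratorConfig(seed=21, n_docs=400, nested_fraction=0.35)
        st = nv.corpus_stats(nv.generate_corpus(cfg))
        assert st.events >= 900
        assert abs(st.pct_nested - 35.0) <= 4.0

    @pytest.mark.parametrize(
        "kw, msg",
        [
            (dict(nested_fraction=1.5), "nested_fraction"),
            (dict(max_depth=0), "max_depth"),
            (dict(events_per_sentence=(1, 1), nested_fraction=0.3), "nested"),
            (dict(events_per_sentence=(1, 1), nested_fraction=0.0,
                  overlap_fraction=1.0), "overlap"),
            (dict(event_types={}), "template"),
        ],
    )
    def test_infeasible_configs_raise_named_errors(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            nv.GeneratorConfig(seed=0, n_docs=2, **kw).validate()

    def test_gold_events_pass_templates_extracted_from_same_corpus(
        self, small_corpus, small_templates
    ):
        docs, _ = small_corpus
        from nevex.construction import CandidateMultiset

        for d in docs:
            for e in d.events:
                assert nv.match_template(
                    CandidateMultiset(e.event_type, e.multiset()), small_templates
                )


class TestInjectRelationNoise:
    def test_zero_noise_is_identity(self, small_corpus):
        docs, cfg = small_corpus
        for d in docs[:10]:
            gold = decompose_events(d)
            out = nv.inject_relation_noise(gold, d, cfg)
            assert [(t.trigger.id, t.role, t.argument.id) for t in out] == [
                (t.trigger.id, t.role, t.argument.id) for t in gold
            ]

    def test_fn_rate_one_empties_the_relation_set(self, small_corpus):
        docs, cfg = small_corpus
        noisy_cfg = nv.GeneratorConfig(**{**cfg.__dict__, "fn_rate": 1.0,
                                          "fp_rate": 0.0})
        for d in docs[:10]:
            assert nv.inject_relation_noise(decompose_events(d), d, noisy_cfg) == []

    def test_fp_count_within_binomial_interval(self):
        cfg = nv.GeneratorConfig(seed=6, n_docs=500, fp_rate=0.2, fn_rate=0.0)
        docs = nv.generate_corpus(cfg)
        n_sent = sum(len(d.sentence_spans) for d in docs)
        rng = np.random.default_rng(99)
        added = 0
        for d in docs:
            gold = decompose_events(d)
            out = nv.inject_relation_noise(gold, d, cfg, rng)
            added += len(out) - len(gold)
        mean = 0.2 * n_sent
        sd = np.sqrt(n_sent * 0.2 * 0.8)
        assert abs(added - mean) < 4 * sd

    def test_false_positives_are_type_plausible_and_not_gold(self, small_corpus):
        docs, cfg = small_corpus
        noisy_cfg = nv.GeneratorConfig(**{**cfg.__dict__, "fp_rate": 1.0})
        ts = nv.extract_templates(docs)
        for d in docs[:20]:
            gold = decompose_events(d)
            gold_keys = {(t.trigger.id, t.role, t.argument.id) for t in gold}
            out = nv.inject_relation_noise(gold, d, noisy_cfg)
            for t in out:
                key = (t.trigger.id, t.role, t.argument.id)
                if key in gold_keys:
                    continue
                pairs = {
                    (role, atype)
                    for tpl in noisy_cfg.event_types[t.trigger.label]["templates"]
                    for role, atype in tpl
                }
                arg_type = (
                    t.argument.label
                    if t.argument.label not in noisy_cfg.event_types
                    else t.argument.label
                )
                assert (t.role, arg_type) in pairs

    def test_deterministic_given_seed(self, small_corpus):
        docs, cfg = small_corpus
        noisy = nv.GeneratorConfig(**{**cfg.__dict__, "fp_rate": 0.4,
                                      "fn_rate": 0.2})
        d = docs[0]
        a = nv.inject_relation_noise(decompose_events(d), d, noisy)
        b = nv.inject_relation_noise(decompose_events(d), d, noisy)
        assert [(t.trigger.id, t.role, t.argument.id) for t in a] == [
            (t.trigger.id, t.role, t.argument.id) for t in b
        ]


class TestScenarios:
    def test_zero_noise_scenarios_coincide(self, small_corpus):
        docs, cfg = small_corpus
        scen = nv.make_scenario_datasets(docs[:30], cfg, n_train=20)

        def keys(rel):
            return {
                doc: [(t.trigger.id, t.role, t.argument.id) for t in ts]
                for doc, ts in rel.items()
            }

        assert keys(scen["scenario1"].train_relations) == keys(
            scen["scenario2"].train_relations
        ) == keys(scen["scenario3"].train_relations)
        assert keys(scen["scenario1"].eval_relations) == keys(
            scen["scenario2"].eval_relations
        )

    def test_noisy_eval_recall_ceiling_below_one(self):
        cfg = nv.GeneratorConfig(seed=8, n_docs=120, fp_rate=0.3, fn_rate=0.3)
        docs = nv.generate_corpus(cfg)
        scen = nv.make_scenario_datasets(docs, cfg, n_train=100)
        eval_docs = docs[100:]
        ts = nv.extract_templates(docs[:100])
        constructible = total = 0
        for d in eval_docs:
            rels = {
                (t.trigger.id, t.role, t.argument.id)
                for t in scen["scenario2"].eval_relations[d.doc_id]
            }
            for e in d.events:
                total += 1
                need = {
                    (
                        e.trigger.id,
                        role,
                        t.id if isinstance(t, nv.Mention) else t.trigger.id,
                    )
                    for role, t in e.arguments
                }
                constructible += need <= rels
        assert constructible < total  # dropped relations cap recall below 1

    def test_scenario2_training_relations_are_gold_plus_fps(self, small_corpus):
        docs, cfg = small_corpus
        noisy = nv.GeneratorConfig(**{**cfg.__dict__, "fp_rate": 0.5,
                                      "fn_rate": 0.5})
        scen = nv.make_scenario_datasets(docs[:30], noisy, n_train=20)
        for d in docs[:20]:
            gold = {
                (t.trigger.id, t.role, t.argument.id)
                for t in decompose_events(d)
            }
            s2 = {
                (t.trigger.id, t.role, t.argument.id)
                for t in scen["scenario2"].train_relations[d.doc_id]
            }
            assert gold <= s2  # no false negatives in scenario-2 training
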