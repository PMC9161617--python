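# Methods

`nevex` detects biomedical *events* — a trigger span plus an unordered
multiset of role-labelled arguments — from pairwise trigger–argument
relations. Arguments may be entities or other events, so structures nest;
events sharing an argument overlap. This note documents the models, the
free parameters and their defaults, what the synthetic corpora do and do
not emulate, and the numerical choices that make runs reproducible.

## Data model and candidate construction

A document is a BioNLP-ST standoff triple (`.txt`, `.a1`, `.a2`) with
0-based half-open character offsets. Role enumeration suffixes
(`Theme2` → `Theme`) are always stripped; `Equiv` lines are recorded but
never expanded. An event's type equals its trigger's type label.

Candidate construction proceeds in four steps:

1. **Relation triples.** Gold events are decomposed into (trigger, role,
   argument) triples; an event argument contributes its sub-event's
   trigger. Duplicate triples from overlapping events collapse to one
   edge — relations form a graph, not a multiset.
2. **Adjacency lists.** Per-trigger argument lists, ordered by
   (text offset, role) so nothing depends on input order.
3. **Relation DAG.** Triggers and entities are nodes, relations directed
   edges. A topological order and bottom-up *levels* are derived: level 0
   holds triggers whose arguments are all entities; level *g* holds
   triggers whose deepest trigger-argument sits at level *g − 1*. Noisy
   predicted relations can contain cycles; each cycle is broken by
   deleting its lexicographically last edge (by trigger offset, role,
   argument offset), with a warning — the method itself assumes DAGs and
   is silent on cycles, so the tie-break is ours and purely for
   determinism. Self-loops are dropped, never fatal.
4. **Templates.** For every event type *t* observed in training gold, the
   set *F_t* of (role, argument-type) multisets; an event argument's type
   is the sub-event's event type (chosen because the corpus argument
   constraints are stated over event types). Matching is exact multiset
   equality — multiplicity-sensitive (`Theme×2 ≠ Theme×1`), no
   subsumption — the strictest reading that preserves the closure
   property (every gold event matches the templates of its own corpus).

## Representations

Sentences are encoded once each by a BiLSTM over randomly initialised
word embeddings (pretrained vectors are supported but off by default so
nothing is downloaded). A mention is the mean of its token context
vectors concatenated with a type embedding (mean pooling is
parameter-free; the method description does not fix a pooling). A
relation is the concatenation (trigger ⊕ role ⊕ argument). A predicted
event's composed representation has the same dimensionality as a mention
representation, so it substitutes directly as the argument representation
of upper levels.

Default dimensions (free hyperparameters; small on purpose so the test
corpora train in seconds): word 16, type/role/action/IN-OUT 8, LSTM
hidden 16, MLP hidden 32. All initialisation flows from one integer seed;
two runs with equal seed, data and configuration produce bitwise-equal
parameters and predictions.

## The two detectors

**EXNN (exhaustive).** For a trigger with relations *R*, every non-empty
subset up to the maximum template arity for the trigger's type is
enumerated (hard cap 10 relations per trigger; beyond it the trigger is
skipped with a warning). Each candidate is encoded by marking every
relation of the trigger with a trainable IN or OUT embedding, feeding all
marked relations as children of a single Child-Sum Tree-LSTM step whose
input is the trigger representation, and passing the output through an
MLP to 2 softmax logits (event / not event). Child-Sum aggregation makes
the score invariant to relation order, which the tests assert under
random permutations. The Tree-LSTM is one composition deep; nesting
composes through grounded sub-event representations, not deeper trees.

**SBNN (search-based).** Per trigger, beam search over the argument
buffer (sorted by argument offset, then role) applies ADD / IGNORE /
CONSTRUCT to the buffer head. What the network scores is the
partially-built structure: the sum of (relation ⊕ action-embedding)
vectors over consumed arguments, combined with the trigger
representation, through an MLP with a sigmoid head. One scorer invocation
evaluates all three successors of a state (they share the consumed
prefix); the CONSTRUCT score is the emitted structure's final
probability, to which the acceptance threshold applies. The beam keeps
the top-k states (k = 8 by default, the width reported to perform best),
drops states below the threshold, and collects emissions from **all**
retained beams across all time steps — this is what lets one trigger emit
several overlapping events. Emitted structures are additionally
template-checked; re-checking at emission is the conservative composition
of the two filters. CONSTRUCT does not terminate the search, so later,
larger structures can still be emitted. Tie-breaking at pruning is a
stable sort by (score descending, action history lexicographic), which
prefers ADD-dense histories and makes the search deterministic.

With an accept-everything scorer, k ≥ 3^n and threshold 0, the emitted
set equals EXNN's template-filtered powerset — the two detectors are
oracle-equivalent, and the test suite checks this on random instances.

## Bottom-up detection and grounding

Detection walks the levels upward. A relation whose argument is a trigger
is *grounded*: one candidate argument per previously predicted event of
that trigger (the Cartesian product over event arguments arises from
subset choice). Candidate arguments remember their source relation and a
structure never uses two groundings of one relation, which makes
relation-level grounding exactly equivalent to per-structure replication.
A relation whose event-argument has no predictions is dropped, so the
branch above a rejected trigger stops expanding while independent chains
continue — the stopping rule is read per branch, not document-global,
because a global stop would forfeit unrelated event chains and their
recall. Predicted events are deduplicated by structural equality
(trigger, type, grounded argument multiset). The trace records per-group
counts and the number of scorer invocations — action scorings for SBNN,
candidate classifications for EXNN — a hardware-independent cost metric
on which the beam-search detector undercuts the exhaustive one whenever
triggers average two or more arguments.

## Training

Both models train bottom-up with teacher forcing: event arguments are
grounded to gold sub-events, whose representations are composed by the
current model. EXNN sees every template-valid candidate subset, labelled
positive iff it equals a gold structure, with 2-class cross-entropy and a
positive-class weight (default #negatives/#positives) against the heavy
candidate imbalance. SBNN is trained transition-style on the states lying
on a gold action path (chosen = gold ∩ consumed prefix): the three
successors of each such state get binary cross-entropy against whether
they stay on a gold path, with CONSTRUCT positive exactly at a complete
gold structure; for triggers with no constructible gold only the
all-IGNORE spine is supervised with all-zero labels, so the beam learns
to die there cheaply. Optimisation is Adam at learning rate 0.01 with a
per-document step; training stops early once the mean loss drops below
0.02. When a predicted-relations sidecar is supplied for training, it is
merged with the gold-decomposed relations (true positives plus false
positives), mirroring how the pipeline regime is trained.

## Synthetic corpora

The generator emits seeded standoff corpora whose lexical cues are
predictive of structure: each (event type, template) pair owns trigger
lexemes, entities are typed tokens, and everything else is filler — token
soup, not natural language, which suffices because no component consumes
syntax. The default inventory has five event types; regulations nest
(depth cap 3 by default) and a Binding-like type takes 2–5 repeated
Themes, which exercises multiplicity-sensitive matching, creates
template-valid proper subsets as genuine negatives, and pushes the mean
argument count per event above 2. The realised nested fraction tracks its
target by a running quota (±4 points at ~1000 events in the tests);
overlap is implemented as argument reuse and its realised flagged
fraction exceeds the configured probability because overlap marks both
sharers. Infeasible configurations (nesting with single-event sentences,
overlap rate 1 without event pairs) fail validation with the violated
constraint named.

Relation noise emulates an upstream extractor: each gold triple is
dropped with probability `fn_rate` (default 0.3 in the scenario
experiments) and one type-plausible spurious triple per sentence is added
with probability `fp_rate` (default 0.5). The three pipeline regimes are:
scenario 1 gold/gold (upper bound); scenario 2 trains on gold + false
positives and evaluates on noisy relations; scenario 3 trains **and**
evaluates on noisy relations at the base rates scaled by 1.5
(`scenario3_noise_scale`) — reflecting that a relation extractor trained
on predicted inputs is itself degraded. Scaling only scenario 3 is what
gives the lower bound a structural, not sampling-luck, gap below the
pipeline regime. These noise levels were fixed to produce the
upper/pipeline/lower-bound spread the pipeline experiments exhibit
(roughly 1.0 / 0.5 / 0.3 F1 at desk scale).

What passing tests on these corpora do **not** show: robustness to real
biomedical lexical variety, discontinuous or overlapping mention spans,
inter-sentence events (excluded by design — detection is sentence-level),
or server-parity with the shared-task evaluation.

## Evaluation

Scoring separates the all / nested / overlapping / flat categories.
Events match recursively: equal types, triggers matched exactly or within
the gold span extended by one word per side (the published approximate
criterion), and a one-to-one role-preserving argument pairing whose
entity arguments match as mentions and event arguments match recursively
down to the flat level — so a nested true positive entails that its
sub-events match. Matching is greedy in document order with deterministic
tie-breaks; optimal bipartite matching is deliberately out of scope.
True positives are tallied on the predicted side for precision and on the
matched gold side for recall, since category flags can differ between the
two sides; an event both nested and overlapping counts in both
categories. F1 is 2PR/(P+R) with 0/0 → 0. Flat and nested percentages
are complementary by definition here; published corpus tables in this
area do not always sum to 100 because their denominators are unstated,
and this implementation makes no attempt to reverse-engineer them.

## Problem sizes

The default test and acceptance runs use 500 training and 100 evaluation
single-sentence documents (~1,200 events), 200-document corpora for gold
recovery, and 100 random triggers with ≤ 8 arguments for the
oracle-equivalence check. These sizes were chosen so the whole suite,
including six model trainings, completes in a few minutes on one CPU
while every category (flat, nested to depth 3, overlapping) stays
populated.

## Known limitations

- Discontinuous spans (`;`-separated offsets) are rejected at parse time.
- The unknown-word percentage depends on the tokenizer and is reported,
  not asserted.
- The beam's threshold filter means a badly calibrated scorer can kill a
  search early; training supervises on-path states specifically to keep
  gold paths above threshold.
- Checkpoints are JSON (parameters are small); no binary format.
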