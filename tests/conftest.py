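"""Shared fixtures: the worked-example document and synthetic corpora."""

from __future__ import annotations

import pytest

import nevex as nv

FIG_TEXT = (
    "We discuss the role of this transcription factor in influencing "
    "Bcl-2 / VEGF induction of tumor angiogenesis ."
)


def _span(word: str):
    i = FIG_TEXT.index(word)
    return i, i + len(word)


def worked_example_streams():
    """Standoff streams for the angiogenesis worked example.

    One flat Blood_vessel_development event (E1) under *angiogenesis*, and
    two Positive_regulation events (E2, E3) under *induction* that share E1
    as Theme but differ in their Cause (Bcl-2 vs VEGF) — so E2 and E3 are
    nested and overlapping.
    """
    a1 = []
    for tid, label, word in [
        ("T1", "Gene-or-Gene-Product", "Bcl-2"),
        ("T2", "Gene-or-Gene-Product", "VEGF"),
        ("T3", "Cancer", "tumor"),
    ]:
        s, e = _span(word)
        a1.append(f"{tid}\t{label} {s} {e}\t{word}")
    a2 = []
    for tid, label, word in [
        ("TR1", "Positive_regulation", "induction"),
        ("TR2", "Blood_vessel_development", "angiogenesis"),
    ]:
        s, e = _span(word)
        a2.append(f"{tid}\t{label} {s} {e}\t{word}")
    a2 += [
        "E1\tBlood_vessel_development:TR2 Theme:T3",
        "E2\tPositive_regulation:TR1 Theme:E1 Cause:T1",
        "E3\tPositive_regulation:TR1 Theme:E1 Cause:T2",
    ]
    return FIG_TEXT, "\n".join(a1) + "\n", "\n".join(a2) + "\n"


@pytest.fixture
def worked_example() -> nv.AnnotatedDocument:
    txt, a1, a2 = worked_example_streams()
    return nv.read_document(txt, a1, a2, doc_id="angio")


@pytest.fixture(scope="session")
def small_corpus():
    """200 clean synthetic documents with nesting and overlap."""
    cfg = nv.GeneratorConfig(
        seed=5, n_docs=200, nested_fraction=0.35, overlap_fraction=0.4
    )
    return nv.generate_corpus(cfg), cfg


@pytest.fixture(scope="session")
def small_templates(small_corpus):
    docs, _ = small_corpus
    return nv.extract_templates(docs)
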