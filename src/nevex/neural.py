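"""Shared representation machinery for the event detectors.

Sentences are encoded once per sentence with a bidirectional LSTM over
randomly initialised word embeddings (pretrained vectors are optional and
off by default).  A mention is represented by the mean of its token context
vectors concatenated with a mention-type embedding; a pairwise relation by
the concatenation (trigger representation, role embedding, argument
representation).  Event arguments substitute the composed representation of
the already-predicted sub-event, which the scorers produce with the same
dimensionality as a mention representation so nesting composes uniformly.

All randomness flows from the single seed in :class:`EmbeddingConfig`.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor, concat, matvec, row, stack_sum
from .standoff import Mention

__all__ = [
    "EmbeddingConfig",
    "Vocabulary",
    "NeuralCore",
    "AlignmentError",
    "tokenize_with_offsets",
]

log = logging.getLogger(__name__)

UNK = "<unk>"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize_with_offsets(text: str) -> List[Tuple[str, int, int]]:
    """Whitespace/punctuation tokenizer retaining character offsets."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class AlignmentError(ValueError):
    """A mention span does not align with any token."""


@dataclass
class EmbeddingConfig:
    """Dimensions of the representation spaces.

    The paper leaves the embedding sizes open; these defaults are small so
    models train in seconds on synthetic corpora while remaining expressive
    enough for the lexical cues the generator plants.
    """

    word_dim: int = 16
    type_dim: int = 8
    role_dim: int = 8
    action_dim: int = 8
    io_dim: int = 8
    hidden_size: int = 16
    mlp_hidden: int = 32
    seed: int = 0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if name != "seed" and v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")

    @property
    def context_dim(self) -> int:
        return 2 * self.hidden_size

    @property
    def mention_dim(self) -> int:
        return self.context_dim + self.type_dim

    @property
    def relation_dim(self) -> int:
        return 2 * self.mention_dim + self.role_dim


class Vocabulary:
    """Token/label to index mapping with a reserved unknown symbol."""

    def __init__(self, items: Sequence[str] = (), warn_unknown: bool = False):
        self.index: Dict[str, int] = {UNK: 0}
        for it in items:
            self.index.setdefault(it, len(self.index))
        self.warn_unknown = warn_unknown
        self._warned: set = set()

    @classmethod
    def fit(cls, tokens, max_size: Optional[int] = None, **kw) -> "Vocabulary":
        counts = Counter(tokens)
        ranked = [t for t, _ in counts.most_common()]
        if max_size is not None:
            ranked = ranked[: max_size - 1]  # one slot for UNK
        return cls(sorted(ranked), **kw)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, item: str) -> bool:
        return item in self.index

    def __getitem__(self, item: str) -> int:
        idx = self.index.get(item)
        if idx is None:
            if self.warn_unknown and item not in self._warned:
                log.warning("unknown label %r mapped to reserved unknown", item)
                self._warned.add(item)
            return 0
        return idx

    def to_dict(self) -> Dict[str, int]:
        return dict(self.index)

    @classmethod
    def from_dict(cls, d: Dict[str, int], **kw) -> "Vocabulary":
        v = cls(**kw)
        v.index = dict(d)
        return v


class _LSTMCell:
    def __init__(self, in_dim: int, hidden: int, rng, prefix: str, params: dict):
        scale = 1.0 / np.sqrt(in_dim + hidden)
        self.h = hidden
        self.W = Tensor(
            rng.uniform(-scale, scale, (4 * hidden, in_dim + hidden)),
            requires_grad=True,
        )
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        params[f"{prefix}.W"] = self.W
        params[f"{prefix}.b"] = self.b

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> Tuple[Tensor, Tensor]:
        z = matvec(self.W, concat([x, h])) + self.b
        hh = self.h
        i = z.slice(0, hh).sigmoid()
        f = z.slice(hh, 2 * hh).sigmoid()
        o = z.slice(2 * hh, 3 * hh).sigmoid()
        u = z.slice(3 * hh, 4 * hh).tanh()
        c2 = f * c + i * u
        h2 = o * c2.tanh()
        return h2, c2


class NeuralCore:
    """Sentence encoder plus mention/role/relation representation builder."""

    def __init__(
        self,
        config: EmbeddingConfig,
        vocab: Vocabulary,
        type_vocab: Vocabulary,
        role_vocab: Vocabulary,
    ):
        self.config = config
        self.vocab = vocab
        self.type_vocab = type_vocab
        self.role_vocab = role_vocab
        self.params: Dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)

        def emb(name, n, d):
            t = Tensor(rng.normal(0.0, 0.1, (n, d)), requires_grad=True)
            self.params[name] = t
            return t

        self.word_emb = emb("word_emb", len(vocab), config.word_dim)
        self.type_emb = emb("type_emb", len(type_vocab), config.type_dim)
        self.role_emb = emb("role_emb", len(role_vocab), config.role_dim)
        self.fwd = _LSTMCell(config.word_dim, config.hidden_size, rng, "fwd", self.params)
        self.bwd = _LSTMCell(config.word_dim, config.hidden_size, rng, "bwd", self.params)

    # -- encoding ---------------------------------------------------------

    def encode_sentence(self, tokens: Sequence[str]) -> List[Tensor]:
        """Contextualised vector (size 2·hidden) per token, BiLSTM shared
        across all event structures of the sentence."""
        if not tokens:
            raise ValueError("cannot encode an empty sentence")
        h = self.config.hidden_size
        xs = [row(self.word_emb, self.vocab[t]) for t in tokens]
        zero = Tensor(np.zeros(h))
        hs_f, hs_b = [], []
        hc = (zero, zero)
        for x in xs:
            hc = self.fwd.step(x, *hc)
            hs_f.append(hc[0])
        hc = (zero, zero)
        for x in reversed(xs):
            hc = self.bwd.step(x, *hc)
            hs_b.append(hc[0])
        hs_b.reverse()
        return [concat([f, b]) for f, b in zip(hs_f, hs_b)]

    def encode_text(self, text: str):
        """Tokenize a sentence and encode it; returns (spans, vectors)."""
        toks = tokenize_with_offsets(text)
        vecs = self.encode_sentence([t for t, _, _ in toks])
        return [(s, e) for _, s, e in toks], vecs

    # -- representations --------------------------------------------------

    def mention_representation(
        self,
        mention: Mention,
        token_spans: Sequence[Tuple[int, int]],
        context_vectors: Sequence[Tensor],
        sentence_offset: int = 0,
    ) -> Tensor:
        """Mean of the mention's token vectors ⊕ mention-type embedding."""
        idxs = [
            i
            for i, (s, e) in enumerate(token_spans)
            if mention.overlaps(s + sentence_offset, e + sentence_offset)
        ]
        if not idxs:
            raise AlignmentError(
                f"mention {mention.id} [{mention.start},{mention.end}) aligns "
                f"with no token (sentence offset {sentence_offset})"
            )
        pooled = stack_sum([context_vectors[i] for i in idxs]) * Tensor(
            1.0 / len(idxs)
        )
        return concat([pooled, row(self.type_emb, self.type_vocab[mention.label])])

    def role_embedding(self, role: str) -> Tensor:
        return row(self.role_emb, self.role_vocab[role])

    def relation_representation(
        self, trigger_repr: Tensor, role: str, argument_repr: Tensor
    ) -> Tensor:
        """Fixed-order concatenation (trigger, role, argument)."""
        expected = self.config.mention_dim
        for name, t in (("trigger", trigger_repr), ("argument", argument_repr)):
            if t.data.shape != (expected,):
                raise ValueError(
                    f"{name} representation has shape {t.data.shape}, "
                    f"expected ({expected},)"
                )
        return concat([trigger_repr, self.role_embedding(role), argument_repr])

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "vocab": self.vocab.to_dict(),
            "type_vocab": self.type_vocab.to_dict(),
            "role_vocab": self.role_vocab.to_dict(),
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }

    def load_state(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k].data = np.asarray(v, dtype=np.float64)

    @classmethod
    def from_state(cls, state: dict) -> "NeuralCore":
        core = cls(
            EmbeddingConfig(**state["config"]),
            Vocabulary.from_dict(state["vocab"]),
            Vocabulary.from_dict(state["type_vocab"]),
            Vocabulary.from_dict(state["role_vocab"], warn_unknown=True),
        )
        core.load_state(state)
        return core
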