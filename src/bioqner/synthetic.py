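"""Synthetic annotated corpora with the structure the recogniser assumes.

Generated sentences mix a context vocabulary with planted multiword entities:
each entity of type T opens with a T-specific prefix marker word, closes with
a T-specific suffix marker, and fills its interior with connectives or nouns
from a shared pool.  Several realistic difficulties are planted on purpose:

* one prefix and one suffix marker are shared between pairs of entity types
  (type ambiguity),
* part of the interior noun pool doubles as ordinary context vocabulary, and
  connectives also occur in plain context, so entity membership of those
  tokens is resolvable only from context,
* optional annotation noise drops or shifts gold spans by one token.

Noise is applied to the training split only; test references stay clean so
measured F reflects recognition quality rather than corrupted references.
Everything is a pure function of the configured seed.
"""

from __future__ import annotations

import random
import string
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

from .corpus_io import (
    DEFAULT_CONNECTIVES,
    EntitySpan,
    TaggedCorpus,
    iob_spans,
    spans_to_iob,
)

DEFAULT_TYPES = ("DNA", "RNA", "cell_line", "cell_type", "protein")


@dataclass
class SynthConfig:
    seed: int = 0
    n_sentences: int = 200
    entity_types: tuple[str, ...] = DEFAULT_TYPES
    vocab_size_context: int = 150
    #: marker words per role (prefix/suffix) per entity type
    n_feature_words: int = 3
    entity_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.40, 3: 0.25, 4: 0.10}
    )
    connective_rate: float = 0.3
    entities_per_sentence: dict[int, float] = field(
        default_factory=lambda: {0: 0.15, 1: 0.55, 2: 0.30}
    )
    label_noise_rate: float = 0.0
    #: interior noun pool size and the fraction of it shared with context vocabulary
    noun_pool_size: int = 8
    noun_context_overlap: float = 0.5
    #: probability that a plain context token is a connective word
    context_connective_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("connective_rate", "noun_context_overlap", "context_connective_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.label_noise_rate <= 0.3):
            raise ValueError("label_noise_rate must lie in [0, 0.3]")
        if min(self.n_sentences, self.vocab_size_context, self.n_feature_words,
               self.noun_pool_size) <= 0:
            raise ValueError("sizes must be positive")
        for dist_name in ("entity_length_distribution", "entities_per_sentence"):
            dist = getattr(self, dist_name)
            if abs(sum(dist.values()) - 1.0) > 1e-9 or min(dist.values()) < 0:
                raise ValueError(f"{dist_name} must be a probability distribution")


@dataclass
class Lexis:
    """The word stock a task is built from; related tasks share its shape."""

    context_vocab: list[str]
    prefix_markers: dict[str, list[str]]
    suffix_markers: dict[str, list[str]]
    noun_pool: list[str]
    connectives: list[str]

    def marker_words(self) -> dict[str, set[str]]:
        """Planted marker words by FPNS role (for recovery checks)."""
        return {
            "PF": {w for ws in self.prefix_markers.values() for w in ws},
            "SF": {w for ws in self.suffix_markers.values() for w in ws},
        }


def _make_word(rng: random.Random, used: set[str]) -> str:
    while True:
        w = "".join(rng.choice(string.ascii_lowercase) for _ in range(rng.randint(4, 8)))
        if w not in used:
            used.add(w)
            return w


def _make_marker(rng: random.Random, used: set[str]) -> str:
    """Acronym-with-digit marker word (e.g. ``QZV2``), the shape real
    biomedical feature words tend to have; the uppercase/digit characters keep
    marker affixes disjoint from the lowercase context vocabulary."""
    while True:
        w = "".join(
            rng.choice(string.ascii_uppercase) for _ in range(rng.randint(2, 4))
        ) + rng.choice(string.digits)
        if w not in used:
            used.add(w)
            return w


def _share_markers(markers: dict[str, list[str]], types: tuple[str, ...]) -> None:
    # plant ambiguity: pairs of types share their first marker word
    for i in range(0, len(types) - 1, 2):
        markers[types[i + 1]][0] = markers[types[i]][0]


def build_lexis(cfg: SynthConfig, rng: random.Random) -> Lexis:
    used: set[str] = set(DEFAULT_CONNECTIVES)
    context = [_make_word(rng, used) for _ in range(cfg.vocab_size_context)]
    pf = {t: [_make_marker(rng, used) for _ in range(cfg.n_feature_words)] for t in cfg.entity_types}
    sf = {t: [_make_marker(rng, used) for _ in range(cfg.n_feature_words)] for t in cfg.entity_types}
    # planted type ambiguity on prefixes only: real prefix feature words (e.g.
    # "IL-") recur across types, while suffix heads tend to indicate the type
    _share_markers(pf, cfg.entity_types)
    n_shared = round(cfg.noun_pool_size * cfg.noun_context_overlap)
    nouns = rng.sample(context, n_shared)
    nouns += [_make_marker(rng, used) for _ in range(cfg.noun_pool_size - n_shared)]
    return Lexis(context, pf, sf, nouns, sorted(DEFAULT_CONNECTIVES))


def _categorical(rng: random.Random, dist: dict) -> object:
    u = rng.random()
    acc = 0.0
    items = sorted(dist.items(), key=lambda kv: str(kv[0]))
    for k, p in items:
        acc += p
        if u < acc:
            return k
    return items[-1][0]


def _context_token(rng: random.Random, lexis: Lexis, cfg: SynthConfig) -> str:
    if rng.random() < cfg.context_connective_rate:
        return rng.choice(lexis.connectives)
    return rng.choice(lexis.context_vocab)


def _build_sentence(rng, lexis: Lexis, cfg: SynthConfig, marker_idx: Counter):
    n_ent = _categorical(rng, cfg.entities_per_sentence)
    tokens: list[str] = []
    spans: list[tuple[int, int, str]] = []

    def ctx_run() -> None:
        for _ in range(rng.randint(1, 3)):
            tokens.append(_context_token(rng, lexis, cfg))

    ctx_run()
    for _ in range(n_ent):
        etype = rng.choice(cfg.entity_types)
        length = _categorical(rng, cfg.entity_length_distribution)
        start = len(tokens)
        # round-robin marker usage keeps every marker word in play
        pf_list = lexis.prefix_markers[etype]
        tokens.append(pf_list[marker_idx[(etype, "PF")] % len(pf_list)])
        marker_idx[(etype, "PF")] += 1
        if length >= 2:
            for _ in range(length - 2):
                if rng.random() < cfg.connective_rate:
                    tokens.append(rng.choice(lexis.connectives))
                else:
                    tokens.append(rng.choice(lexis.noun_pool))
            sf_list = lexis.suffix_markers[etype]
            tokens.append(sf_list[marker_idx[(etype, "SF")] % len(sf_list)])
            marker_idx[(etype, "SF")] += 1
        spans.append((start, len(tokens), etype))
        ctx_run()
    return tokens, spans


def _corrupt_spans(rng, spans, sentence_len: int, noise: float):
    """Drop or shift each span by one token with probability ``noise``."""
    out = []
    for start, end, etype in spans:
        if noise > 0.0 and rng.random() < noise:
            if rng.random() < 0.5:
                continue  # dropped annotation
            d = rng.choice((-1, 1))
            ns, ne = start + d, end + d
            if ns < 0 or ne > sentence_len:
                continue
            out.append((ns, ne, etype))
        else:
            out.append((start, end, etype))
    # shifted spans may now collide; keep the earlier span of any overlap
    out.sort()
    kept = []
    for sp in out:
        if kept and sp[0] < kept[-1][1]:
            continue
        kept.append(sp)
    return kept


def _assemble(sentence_data, noise_rng: Optional[random.Random], noise: float) -> TaggedCorpus:
    texts = []
    spans: list[EntitySpan] = []
    for i, (tokens, raw_spans) in enumerate(sentence_data):
        texts.append(tokens)
        use = raw_spans
        if noise_rng is not None:
            use = _corrupt_spans(noise_rng, raw_spans, len(tokens), noise)
        for s, e, t in use:
            spans.append(EntitySpan(i, s, e, t))
    return spans_to_iob(texts, spans)


def generate_with_lexis(
    cfg: SynthConfig, lexis: Lexis, rng: random.Random
) -> tuple[TaggedCorpus, TaggedCorpus]:
    marker_idx: Counter = Counter()
    data = [_build_sentence(rng, lexis, cfg, marker_idx) for _ in range(cfg.n_sentences)]
    n_train = int(cfg.n_sentences * 0.7)
    if n_train == 0 or n_train == cfg.n_sentences:
        raise ValueError("n_sentences too small for a 70/30 split")
    train = _assemble(data[:n_train], rng, cfg.label_noise_rate)
    test = _assemble(data[n_train:], None, 0.0)
    for c in (train, test):
        c.entity_types = set(cfg.entity_types)
    return train, test


def generate(cfg: SynthConfig) -> tuple[TaggedCorpus, TaggedCorpus]:
    """Generate disjoint train/test corpora (70/30), gold in IOB2, from cfg.seed."""
    rng = random.Random(cfg.seed)
    lexis = build_lexis(cfg, rng)
    return generate_with_lexis(cfg, lexis, rng)


def related_lexis(lexis: Lexis, cfg: SynthConfig, rename_seed: int) -> Lexis:
    """A related task's word stock: about half of the marker words are renamed."""
    rng = random.Random(rename_seed)
    used = set(lexis.context_vocab) | set(lexis.noun_pool) | set(lexis.connectives)
    for ws in list(lexis.prefix_markers.values()) + list(lexis.suffix_markers.values()):
        used.update(ws)
    pf = {t: list(ws) for t, ws in lexis.prefix_markers.items()}
    sf = {t: list(ws) for t, ws in lexis.suffix_markers.items()}
    for markers in (pf, sf):
        for t in markers:
            for i in range(len(markers[t])):
                if i % 2 == 0:
                    markers[t][i] = _make_marker(rng, used)
        _share_markers(markers, cfg.entity_types)
    return Lexis(lexis.context_vocab, pf, sf, lexis.noun_pool, lexis.connectives)


def generate_pair(
    cfg: SynthConfig, target_seed: int
) -> tuple[
    tuple[TaggedCorpus, TaggedCorpus], tuple[TaggedCorpus, TaggedCorpus], Lexis, Lexis
]:
    """A source task and a related-but-different target task.

    The target renames about half of the marker words and draws fresh
    sentences from ``target_seed``; everything else is shared, so the tasks
    are related in exactly the way Q-value reuse assumes.
    """
    rng_src = random.Random(cfg.seed)
    src_lexis = build_lexis(cfg, rng_src)
    src = generate_with_lexis(cfg, src_lexis, rng_src)
    tgt_lexis = related_lexis(src_lexis, cfg, target_seed)
    tgt = generate_with_lexis(
        replace(cfg, seed=target_seed), tgt_lexis, random.Random(target_seed + 1)
    )
    return src, tgt, src_lexis, tgt_lexis


def describe(corpus: TaggedCorpus) -> dict:
    """Summary statistics: sentence/token/entity counts and mean entity length."""
    n_sent = len(corpus.sentences)
    n_tok = corpus.n_tokens()
    if n_sent == 0:
        return {
            "sentences": 0, "tokens": 0, "entities": 0,
            "per_type": {}, "mean_entity_length": 0.0,
        }
    spans = iob_spans(corpus) if corpus.label_scheme == "IOB2" else (corpus.spans or [])
    per_type = Counter(sp.entity_type for sp in spans)
    mean_len = (
        sum(sp.end - sp.start for sp in spans) / len(spans) if spans else 0.0
    )
    return {
        "sentences": n_sent,
        "tokens": n_tok,
        "entities": len(spans),
        "per_type": dict(sorted(per_type.items())),
        "mean_entity_length": mean_len,
    }
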