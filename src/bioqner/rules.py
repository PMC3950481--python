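"""Error-driven transformation-based learning of an ordered rule list.

Starting from an initial per-token tagging (the lexicons' argmax label), the
learner repeatedly instantiates candidate correction rules from template
contexts at mis-tagged positions, scores each candidate by net errors
repaired over the whole training corpus, accepts the best rule, applies it
and iterates until no candidate reaches the acceptance threshold.  Because
every accepted rule has an integer score >= threshold >= 1, the training
error count strictly decreases and the loop terminates within the initial
error count.

Rules carry a polarity (positive / negative / neuter, codes 0/1/2)
assigned from the information value of the rule's lexical anchor: anchors
below the corpus-mean information value yield positive (entity-assigning)
rules, anchors above it negative rules, and rules without a lexical anchor
are neuter.  Polarity is descriptive metadata; it does not change rule
semantics.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .corpus_io import (
    ENTITY_LABELS,
    CorpusError,
    Sentence,
    TaggedCorpus,
    Token,
    copy_corpus,
)
from .features import (
    LEFT_SENTINEL,
    RIGHT_SENTINEL,
    Feature,
    FeatureLexicons,
    extract_features,
)

POSITIVE = 0
NEGATIVE = 1
NEUTER = 2

#: context slots a rule condition may constrain
SLOTS = ("cur_word", "cur_suffix", "prev_label", "left_word", "right_word")

#: default rule templates: which slots each candidate rule constrains
DEFAULT_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("cur_word",),
    ("cur_suffix",),
    ("prev_label",),
    ("left_word",),
    ("right_word",),
    ("prev_label", "cur_word"),
    ("left_word", "cur_word"),
)

_SUFFIX_LEN = 3

_START_LABEL = "START"


@dataclass(frozen=True)
class Rule:
    """Contextual label rewrite old -> new under a slot-value condition."""

    condition: tuple[tuple[str, str], ...]
    old: str
    new: str
    polarity: int = field(default=NEUTER, compare=False)
    score: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.old == self.new:
            raise ValueError("a rule must change the label")
        for slot, _ in self.condition:
            if slot not in SLOTS:
                raise ValueError(f"unknown condition slot {slot!r}")


@dataclass
class RuleList:
    rules: list[Rule]

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def serialize_rule(rule: Rule) -> str:
    cond = "\t".join(f"{slot}={value}" for slot, value in rule.condition)
    return f"{rule.old}\t{rule.new}\t{rule.polarity}\t{rule.score}\t{cond}"


def parse_rule(line: str) -> Rule:
    parts = line.rstrip("\n").split("\t")
    old, new, polarity, score = parts[0], parts[1], int(parts[2]), int(parts[3])
    cond = tuple(tuple(p.split("=", 1)) for p in parts[4:])
    return Rule(cond, old, new, polarity, score)


def rules_to_text(rules: RuleList) -> str:
    return "".join(serialize_rule(r) + "\n" for r in rules)


def rules_from_text(text: str) -> RuleList:
    return RuleList([parse_rule(line) for line in text.splitlines() if line.strip()])


def _slot_values(sent: Sentence, preds: Sequence[str], j: int) -> dict[str, str]:
    text = sent.tokens[j].text
    return {
        "cur_word": text,
        "cur_suffix": text[-min(_SUFFIX_LEN, len(text)):],
        "prev_label": preds[j - 1] if j > 0 else _START_LABEL,
        "left_word": sent.tokens[j - 1].text if j > 0 else LEFT_SENTINEL,
        "right_word": sent.tokens[j + 1].text if j + 1 < len(sent) else RIGHT_SENTINEL,
    }


def _anchor_feature(condition: Iterable[tuple[str, str]]) -> Optional[Feature]:
    """Lexical feature anchoring a condition, for the polarity split."""
    kind_map = {
        "cur_word": "surface_word",
        "cur_suffix": "suffix_string",
        "left_word": "left_word",
        "right_word": "right_word",
    }
    for slot, value in condition:
        if slot in kind_map:
            return Feature(kind_map[slot], value)
    return None


def _polarity(condition, new_label: str, lexicons: Optional[FeatureLexicons]) -> int:
    anchor = _anchor_feature(condition)
    if anchor is None or lexicons is None:
        return NEUTER
    if lexicons.is_low_information(anchor):
        return POSITIVE
    return NEGATIVE


def _check_aligned(tagged: TaggedCorpus, gold: TaggedCorpus) -> None:
    if len(tagged.sentences) != len(gold.sentences):
        raise CorpusError("tagged and gold corpora have different sentence counts")
    for i, (a, b) in enumerate(zip(tagged.sentences, gold.sentences)):
        if a.texts() != b.texts():
            raise CorpusError(f"tokenization mismatch in sentence {i}")


def initial_tag(corpus: TaggedCorpus, lexicons: FeatureLexicons) -> TaggedCorpus:
    """Per-token argmax lexicon label (O without a vote), stored as pred labels."""
    out = copy_corpus(corpus)
    for sent in out.sentences:
        for j, tok in enumerate(sent.tokens):
            vote = lexicons.vote(extract_features(sent, j))
            tok.pred_label = vote if vote is not None else "O"
    return out


def _matches(rule: Rule, slots: dict[str, str]) -> bool:
    return all(slots[s] == v for s, v in rule.condition)


def generate_candidates(
    tagged: TaggedCorpus,
    gold: TaggedCorpus,
    templates: Sequence[tuple[str, ...]] = DEFAULT_TEMPLATES,
    lexicons: Optional[FeatureLexicons] = None,
) -> set[Rule]:
    """All distinct template instantiations at mis-tagged positions."""
    _check_aligned(tagged, gold)
    out: set[Rule] = set()
    for sent_t, sent_g in zip(tagged.sentences, gold.sentences):
        preds = [t.pred_label for t in sent_t.tokens]
        for j, (pt, gt) in enumerate(zip(sent_t.tokens, sent_g.tokens)):
            if pt.pred_label == gt.gold_label:
                continue
            slots = _slot_values(sent_t, preds, j)
            for tmpl in templates:
                cond = tuple((s, slots[s]) for s in tmpl)
                out.add(
                    Rule(
                        cond,
                        pt.pred_label,
                        gt.gold_label,
                        polarity=_polarity(cond, gt.gold_label, lexicons),
                    )
                )
    return out


def score_rule(rule: Rule, tagged: TaggedCorpus, gold: TaggedCorpus) -> int:
    """Net error change: (#errors fixed) - (#errors introduced) under simultaneous application."""
    _check_aligned(tagged, gold)
    fixed = 0
    introduced = 0
    for sent_t, sent_g in zip(tagged.sentences, gold.sentences):
        preds = [t.pred_label for t in sent_t.tokens]
        for j, (pt, gt) in enumerate(zip(sent_t.tokens, sent_g.tokens)):
            if pt.pred_label != rule.old:
                continue
            if not _matches(rule, _slot_values(sent_t, preds, j)):
                continue
            if gt.gold_label == rule.new:
                fixed += 1
            elif gt.gold_label == rule.old:
                introduced += 1
    return fixed - introduced


def apply_rules(rule_list, tagged: TaggedCorpus) -> TaggedCorpus:
    """Apply rules in list order; each rule is one simultaneous pass.

    Within one rule, conditions are evaluated against the pre-pass predicted
    labels, then all matching positions are rewritten at once, so scoring and
    application agree.
    """
    out = copy_corpus(tagged)
    rules = list(rule_list)
    for rule in rules:
        for sent in out.sentences:
            preds = [t.pred_label for t in sent.tokens]
            hits = [
                j
                for j in range(len(sent))
                if preds[j] == rule.old and _matches(rule, _slot_values(sent, preds, j))
            ]
            for j in hits:
                sent.tokens[j].pred_label = rule.new
    return out


def _iteration_buckets(tagged: TaggedCorpus, gold: TaggedCorpus, templates):
    """One corpus pass: per (template condition, old pred) gold-label counts.

    score(cond, old->new) = bucket[new] - bucket[old], exactly the
    simultaneous-application net error change computed by score_rule.
    """
    buckets: dict[tuple, Counter] = defaultdict(Counter)
    errors: list[tuple] = []
    for sent_t, sent_g in zip(tagged.sentences, gold.sentences):
        preds = [t.pred_label for t in sent_t.tokens]
        for j, (pt, gt) in enumerate(zip(sent_t.tokens, sent_g.tokens)):
            slots = _slot_values(sent_t, preds, j)
            for tmpl in templates:
                cond = tuple((s, slots[s]) for s in tmpl)
                buckets[(cond, pt.pred_label)][gt.gold_label] += 1
            if pt.pred_label != gt.gold_label:
                errors.append((j, pt.pred_label, gt.gold_label, slots))
    return buckets, errors


def learn_rules(
    corpus: TaggedCorpus,
    gold: TaggedCorpus,
    lexicons: FeatureLexicons,
    threshold: int = 2,
    templates: Sequence[tuple[str, ...]] = DEFAULT_TEMPLATES,
    max_rules: int = 1000,
) -> RuleList:
    """Greedy error-driven rule induction.

    ``corpus`` supplies predicted labels (tokens without predictions are
    initially tagged from the lexicons); ``gold`` supplies the reference.
    Stops when the best candidate's net score drops below ``threshold``
    (>= 1).  Ties between equally scoring candidates break to the
    lexicographically smallest serialized rule, so the result is
    deterministic.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1 on the integer score scale")
    _check_aligned(corpus, gold)
    tagged = copy_corpus(corpus)
    if any(t.pred_label is None for s in tagged.sentences for t in s.tokens):
        tagged = initial_tag(tagged, lexicons)

    accepted: list[Rule] = []
    while len(accepted) < max_rules:
        buckets, errors = _iteration_buckets(tagged, gold, templates)
        if not errors:
            break
        best_rule: Optional[Rule] = None
        best_key: Optional[tuple] = None
        seen: set[tuple] = set()
        for _, old, new_lab, slots in errors:
            for tmpl in templates:
                cond = tuple((s, slots[s]) for s in tmpl)
                ident = (cond, old, new_lab)
                if ident in seen:
                    continue
                seen.add(ident)
                counter = buckets[(cond, old)]
                score = counter.get(new_lab, 0) - counter.get(old, 0)
                if score < threshold:
                    continue
                rule = Rule(cond, old, new_lab, score=score)
                key = (-score, serialize_rule(rule))
                if best_key is None or key < best_key:
                    best_rule, best_key = rule, key
        if best_rule is None:
            break
        best_rule = replace(
            best_rule, polarity=_polarity(best_rule.condition, best_rule.new, lexicons)
        )
        accepted.append(best_rule)
        tagged = apply_rules([best_rule], tagged)
    return RuleList(accepted)
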