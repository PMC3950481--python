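"""Feature extraction, feature-quality scoring and lexicon induction.

Each token yields a deterministic list of features: its surface form,
character prefixes/suffixes of length 1-4, orthographic flags (digit, hyphen,
uppercase — emitted only when present) and the neighbouring surface words.

Two scores drive the recogniser:

* ``quality(f, t)`` — the F score of the one-feature decision rule "assign
  label t to every token exhibiting f", computed over a gold FPNS corpus.
  It is the association score stored in the induced lexicons and the reward
  of a correct tagging move.
* ``information_value(f)`` — add-one-smoothed mutual information (bits)
  between the feature's indicator and the gold label variable.  Features
  below the corpus mean are "low information value", a split that governs
  rule polarity in the rule learner.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .corpus_io import FPNS, FPNS_LABELS, CorpusError, Sentence, TaggedCorpus

LEFT_SENTINEL = "<s>"
RIGHT_SENTINEL = "</s>"

_STRING_KINDS = frozenset(
    {"surface_word", "prefix_string", "suffix_string", "left_word", "right_word"}
)
_FLAG_KINDS = frozenset({"contains_digit", "contains_hyphen", "contains_uppercase"})


@dataclass(frozen=True)
class Feature:
    kind: str
    value: str

    def __post_init__(self) -> None:
        if self.kind in _STRING_KINDS and not self.value:
            raise ValueError(f"{self.kind} feature needs a non-empty value")


def extract_features(sentence: Sentence, position: int) -> list[Feature]:
    """Deterministic feature list for one token position."""
    if not (0 <= position < len(sentence)):
        raise IndexError(f"position {position} out of range for sentence of length {len(sentence)}")
    text = sentence.tokens[position].text
    feats = [Feature("surface_word", text)]
    for k in range(1, min(4, len(text)) + 1):
        feats.append(Feature("prefix_string", text[:k]))
    for k in range(1, min(4, len(text)) + 1):
        feats.append(Feature("suffix_string", text[-k:]))
    if any(c.isdigit() for c in text):
        feats.append(Feature("contains_digit", "true"))
    if "-" in text:
        feats.append(Feature("contains_hyphen", "true"))
    if any(c.isupper() for c in text):
        feats.append(Feature("contains_uppercase", "true"))
    left = sentence.tokens[position - 1].text if position > 0 else LEFT_SENTINEL
    right = sentence.tokens[position + 1].text if position + 1 < len(sentence) else RIGHT_SENTINEL
    feats.append(Feature("left_word", left))
    feats.append(Feature("right_word", right))
    return feats


def _f_score(n_ft: int, n_f: int, n_t: int) -> float:
    if n_f == 0 or n_t == 0 or n_ft == 0:
        return 0.0
    p = n_ft / n_f
    r = n_ft / n_t
    return 2 * p * r / (p + r)


def _count_features(corpus: TaggedCorpus):
    """One pass over the corpus: per-feature totals and per-(feature,label) counts."""
    feat_total: Counter = Counter()
    feat_label: dict[Feature, Counter] = defaultdict(Counter)
    label_total: Counter = Counter()
    for sent in corpus.sentences:
        for j in range(len(sent)):
            lab = sent.tokens[j].gold_label
            label_total[lab] += 1
            for f in extract_features(sent, j):
                feat_total[f] += 1
                feat_label[f][lab] += 1
    return feat_total, feat_label, label_total


def quality(f: Feature, t: str, corpus: TaggedCorpus) -> float:
    """F score of the rule "label t whenever feature f is present" (0 if degenerate)."""
    n_f = 0
    n_t = 0
    n_ft = 0
    for sent in corpus.sentences:
        for j in range(len(sent)):
            has_f = f in extract_features(sent, j)
            is_t = sent.tokens[j].gold_label == t
            n_f += has_f
            n_t += is_t
            n_ft += has_f and is_t
    return _f_score(n_ft, n_f, n_t)


def _mutual_information(
    counts_with: Counter, label_total: Counter, n_tokens: int, labels: Sequence[str]
) -> float:
    """Smoothed MI (bits) between a binary feature indicator and the label variable."""
    cells = 2 * len(labels)
    denom = n_tokens + cells
    mi = 0.0
    # marginals are taken from the smoothed joint so MI is guaranteed >= 0
    p_a = {}
    joint = {}
    for a in (0, 1):
        row = 0.0
        for lab in labels:
            n = counts_with[lab] if a == 1 else label_total[lab] - counts_with[lab]
            p = (n + 1) / denom
            joint[(a, lab)] = p
            row += p
        p_a[a] = row
    for lab in labels:
        p_l = joint[(0, lab)] + joint[(1, lab)]
        for a in (0, 1):
            p = joint[(a, lab)]
            mi += p * math.log2(p / (p_a[a] * p_l))
    return max(mi, 0.0)


def information_value(f: Feature, corpus: TaggedCorpus) -> float:
    """Add-one-smoothed mutual information (bits) between f's indicator and the gold label."""
    if not corpus.sentences:
        raise CorpusError("empty corpus")
    labels = list(FPNS_LABELS) if corpus.label_scheme == FPNS else sorted(
        {t.gold_label for _, _, t in corpus.iter_tokens()}
    )
    counts_with: Counter = Counter()
    label_total: Counter = Counter()
    n_with = 0
    n_tokens = 0
    for sent in corpus.sentences:
        for j in range(len(sent)):
            lab = sent.tokens[j].gold_label
            label_total[lab] += 1
            n_tokens += 1
            if f in extract_features(sent, j):
                counts_with[lab] += 1
                n_with += 1
    return _mutual_information(counts_with, label_total, n_tokens, labels)


@dataclass
class FeatureLexicons:
    """Per-label feature lexicons plus per-feature information values.

    ``by_label[t][f]`` is the association score (the quality F) of feature
    ``f`` for label ``t``; ``labels`` fixes the tie-break order for votes.
    """

    labels: tuple[str, ...]
    by_label: dict[str, dict[Feature, float]]
    information_values: dict[Feature, float]
    mean_information_value: float

    def vote(self, feats: Iterable[Feature]) -> Optional[str]:
        """Label whose lexicon gives the largest summed association, or None.

        Ties (within float equality) go to the label earliest in ``labels``.
        """
        best: Optional[str] = None
        best_sum = 0.0
        flist = list(feats)
        for lab in self.labels:
            lex = self.by_label.get(lab)
            if not lex:
                continue
            s = 0.0
            for f in flist:
                s += lex.get(f, 0.0)
            if s > best_sum:
                best, best_sum = lab, s
        return best

    def is_low_information(self, f: Feature) -> bool:
        return self.information_values.get(f, 0.0) < self.mean_information_value


def induce_lexicons(
    corpus: TaggedCorpus,
    min_quality: float = 0.1,
    min_count: int = 2,
) -> FeatureLexicons:
    """Induce per-FPNS-label feature lexicons from a gold FPNS corpus.

    A feature enters label t's lexicon when it occurs at least ``min_count``
    times and its quality for t is at least ``min_quality``.  Scores depend
    only on corpus counts, so induction is invariant to sentence order and to
    duplicating the whole corpus.
    """
    if corpus.label_scheme != FPNS:
        raise CorpusError("lexicon induction requires a gold FPNS corpus")
    if not corpus.sentences:
        raise CorpusError("empty corpus")
    feat_total, feat_label, label_total = _count_features(corpus)
    n_tokens = sum(label_total.values())
    labels = tuple(FPNS_LABELS)

    by_label: dict[str, dict[Feature, float]] = {lab: {} for lab in labels}
    info: dict[Feature, float] = {}
    for f, n_f in feat_total.items():
        if n_f < min_count:
            continue
        per_label = feat_label[f]
        info[f] = _mutual_information(per_label, label_total, n_tokens, labels)
        for lab in labels:
            q = _f_score(per_label.get(lab, 0), n_f, label_total.get(lab, 0))
            if q >= min_quality:
                by_label[lab][f] = q
    mean_iv = sum(info.values()) / len(info) if info else 0.0
    return FeatureLexicons(labels, by_label, info, mean_iv)


def induce_type_lexicons(
    corpus: TaggedCorpus, min_quality: float = 0.1, min_count: int = 2
) -> dict[str, dict[Feature, float]]:
    """Per-entity-type lexicons from IOB2 gold: quality of "token lies in a type-T span"."""
    if corpus.label_scheme != "IOB2":
        raise CorpusError("type lexicons are induced from an IOB2 corpus")
    feat_total: Counter = Counter()
    feat_type: dict[Feature, Counter] = defaultdict(Counter)
    type_total: Counter = Counter()
    for sent in corpus.sentences:
        for j in range(len(sent)):
            lab = sent.tokens[j].gold_label
            etype = lab[2:] if lab != "O" else None
            if etype is not None:
                type_total[etype] += 1
            for f in extract_features(sent, j):
                feat_total[f] += 1
                if etype is not None:
                    feat_type[f][etype] += 1
    out: dict[str, dict[Feature, float]] = {t: {} for t in type_total}
    for f, n_f in feat_total.items():
        if n_f < min_count:
            continue
        for t, n_ft in feat_type[f].items():
            q = _f_score(n_ft, n_f, type_total[t])
            if q >= min_quality:
                out[t][f] = q
    return out


def assign_span_type(
    sentence: Sentence,
    span: tuple[int, int],
    type_lexicons: dict[str, dict[Feature, float]],
    default: Optional[str] = None,
) -> str:
    """Type a decoded span by the largest summed association; ties alphabetical."""
    types = sorted(type_lexicons)
    if not types:
        raise ValueError("no entity types available")
    feats = [f for j in range(span[0], span[1]) for f in extract_features(sentence, j)]
    best = default if default is not None else types[0]
    best_sum = 0.0
    for t in types:
        lex = type_lexicons[t]
        s = sum(lex.get(f, 0.0) for f in feats)
        if s > best_sum:
            best, best_sum = t, s
    return best


# ---------------------------------------------------------------------------
# plain-text serialization: one record per line, tab-separated
#   LEX   <label> <kind> <value> <score>
#   INFO  <kind> <value> <score>
#   MEAN  <score>

def lexicons_to_text(lex: FeatureLexicons) -> str:
    lines = ["LABELS\t" + "\t".join(lex.labels)]
    for lab in lex.labels:
        for f, score in sorted(lex.by_label.get(lab, {}).items(), key=lambda kv: (kv[0].kind, kv[0].value)):
            lines.append(f"LEX\t{lab}\t{f.kind}\t{f.value}\t{score!r}")
    for f, score in sorted(lex.information_values.items(), key=lambda kv: (kv[0].kind, kv[0].value)):
        lines.append(f"INFO\t{f.kind}\t{f.value}\t{score!r}")
    lines.append(f"MEAN\t{lex.mean_information_value!r}")
    return "\n".join(lines) + "\n"


def lexicons_from_text(text: str) -> FeatureLexicons:
    labels: tuple[str, ...] = tuple(FPNS_LABELS)
    by_label: dict[str, dict[Feature, float]] = {}
    info: dict[Feature, float] = {}
    mean_iv = 0.0
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag == "LABELS":
            labels = tuple(parts[1:])
        elif tag == "LEX":
            _, lab, kind, value, score = parts
            by_label.setdefault(lab, {})[Feature(kind, value)] = float(score)
        elif tag == "INFO":
            _, kind, value, score = parts
            info[Feature(kind, value)] = float(score)
        elif tag == "MEAN":
            mean_iv = float(parts[1])
        else:
            raise ValueError(f"unknown lexicon record {tag!r}")
    for lab in labels:
        by_label.setdefault(lab, {})
    return FeatureLexicons(labels, by_label, info, mean_iv)
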