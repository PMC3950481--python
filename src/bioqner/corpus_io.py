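"""Token-annotated corpora: CoNLL I/O and IOB2 <-> FPNS label-scheme conversion.

A corpus is a list of sentences of whitespace-free tokens, each carrying a gold
label and optionally a predicted label.  Two label schemes are supported:

* ``IOB2`` — span annotation with ``B-<type>`` / ``I-<type>`` / ``O`` labels,
  the interchange form for typed entity mentions.
* ``FPNS`` — the seven-state decomposition of an entity mention and its
  context: prefix feature word (PF), intermediate feature word (IF), suffix
  feature word (SF), conjunctive word (J), left/right boundary word (LB/RB)
  and other word (O).  FPNS labels are typeless; entity types are carried
  out-of-band as a parallel span list so the conversion is invertible.

The on-disk format is two-column CoNLL: ``token<TAB>label`` lines with one
blank line between sentences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

FPNS_LABELS: tuple[str, ...] = ("PF", "IF", "SF", "J", "LB", "RB", "O")
#: numeric state codes, in mnemonic order (PF=0 ... O=6)
FPNS_VALUES: dict[str, int] = {lab: i for i, lab in enumerate(FPNS_LABELS)}
#: labels that lie inside an entity mention
ENTITY_LABELS: frozenset[str] = frozenset({"PF", "IF", "SF", "J"})
#: default connective words recognised as J inside a multiword entity
DEFAULT_CONNECTIVES: frozenset[str] = frozenset({"of", "and", "or", "-", "/", "for", "in"})

# conflict resolution when one token is eligible for several FPNS roles:
# entity-internal labels always beat boundary labels, and a token that is both
# RB of one entity and LB of the next becomes LB.
_FPNS_PRIORITY: dict[str, int] = {"PF": 0, "SF": 1, "IF": 2, "J": 3, "LB": 4, "RB": 5, "O": 6}

IOB2 = "IOB2"
FPNS = "FPNS"


class CorpusError(ValueError):
    """Malformed corpus content (bad line, bad label sequence, empty input)."""


class SchemeError(CorpusError):
    """Label scheme mismatch or mixture."""


@dataclass
class Token:
    text: str
    gold_label: str
    pred_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.text or any(c.isspace() for c in self.text):
            raise CorpusError(f"token text must be non-empty and whitespace-free: {self.text!r}")


@dataclass
class Sentence:
    tokens: list[Token]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise CorpusError("a sentence must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]

    def gold_labels(self) -> list[str]:
        return [t.gold_label for t in self.tokens]

    def pred_labels(self) -> list[Optional[str]]:
        return [t.pred_label for t in self.tokens]


@dataclass(frozen=True)
class EntitySpan:
    """Half-open token span [start, end) of one entity in one sentence."""

    sentence_index: int
    start: int
    end: int
    entity_type: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid span coordinates [{self.start}, {self.end})")


@dataclass
class TaggedCorpus:
    sentences: list[Sentence]
    label_scheme: str
    entity_types: set[str] = field(default_factory=set)
    #: entity spans with types, parallel to the FPNS labels (None for IOB2,
    #: where spans are recoverable from the labels themselves)
    spans: Optional[list[EntitySpan]] = None

    def __post_init__(self) -> None:
        if self.label_scheme not in (IOB2, FPNS):
            raise SchemeError(f"unknown label scheme {self.label_scheme!r}")

    def __len__(self) -> int:
        return len(self.sentences)

    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def iter_tokens(self) -> Iterator[tuple[int, int, Token]]:
        for i, sent in enumerate(self.sentences):
            for j, tok in enumerate(sent.tokens):
                yield i, j, tok

    def validate(self) -> None:
        """Raise if any label violates the declared scheme."""
        if self.label_scheme == FPNS:
            for i, j, tok in self.iter_tokens():
                if tok.gold_label not in FPNS_VALUES:
                    raise SchemeError(
                        f"sentence {i} token {j}: {tok.gold_label!r} is not an FPNS label"
                    )
        else:
            for i, sent in enumerate(self.sentences):
                _check_iob2(sent.gold_labels(), i)


def _check_iob2(labels: Sequence[str], sentence_index: int) -> None:
    prev = "O"
    for j, lab in enumerate(labels):
        if lab == "O":
            prev = lab
            continue
        if len(lab) < 3 or lab[1] != "-" or lab[0] not in "BI":
            raise SchemeError(f"sentence {sentence_index} token {j}: bad IOB2 label {lab!r}")
        if lab[0] == "I":
            if prev == "O" or prev[2:] != lab[2:]:
                raise SchemeError(
                    f"sentence {sentence_index} token {j}: {lab!r} continues no open entity"
                )
        prev = lab


def _detect_scheme(labels: Iterable[str]) -> str:
    has_iob = False
    has_fpns = False
    for lab in labels:
        if lab.startswith(("B-", "I-")):
            has_iob = True
        elif lab in FPNS_VALUES and lab != "O":
            has_fpns = True
        elif lab != "O":
            raise SchemeError(f"label {lab!r} belongs to no supported scheme")
    if has_iob and has_fpns:
        raise SchemeError("corpus mixes IOB2 and FPNS labels")
    return FPNS if has_fpns else IOB2


def read_conll(source) -> TaggedCorpus:
    """Read a two-column ``token<TAB>label`` corpus.

    ``source`` may be a text stream, a path, or a string containing the text
    itself when it contains newlines.  The label scheme is auto-detected.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()

    sentences: list[Sentence] = []
    tokens: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        if line.strip() == "":
            if tokens:
                sentences.append(Sentence([Token(t, l) for t, l in tokens]))
                tokens = []
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise CorpusError(f"line {lineno}: expected 2 tab-separated columns, got {len(cols)}")
        tokens.append((cols[0], cols[1]))
    if tokens:
        sentences.append(Sentence([Token(t, l) for t, l in tokens]))
    if not sentences:
        raise CorpusError("empty corpus: no sentences found")

    scheme = _detect_scheme(
        lab for sent in sentences for lab in sent.gold_labels()
    )
    types = set()
    if scheme == IOB2:
        for sent in sentences:
            for lab in sent.gold_labels():
                if lab != "O":
                    types.add(lab[2:])
    corpus = TaggedCorpus(sentences, scheme, types)
    corpus.validate()
    return corpus


def write_conll(corpus: TaggedCorpus, dest=None) -> Optional[str]:
    """Write the exact dialect :func:`read_conll` accepts.

    ``dest`` may be a text stream or a path; with ``dest=None`` the text is
    returned.  ``read(write(c)) == c`` and ``write(read(s)) == s``.
    """
    if not corpus.sentences:
        raise CorpusError("refusing to write a corpus with no sentences")
    buf = io.StringIO()
    for sent in corpus.sentences:
        for tok in sent.tokens:
            buf.write(f"{tok.text}\t{tok.gold_label}\n")
        buf.write("\n")
    text = buf.getvalue()
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
        return None
    try:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    except OSError as exc:
        raise CorpusError(f"cannot write corpus to {dest}: {exc}") from exc
    return None


def iob_spans(corpus: TaggedCorpus) -> list[EntitySpan]:
    """Extract typed entity spans from an IOB2 corpus."""
    if corpus.label_scheme != IOB2:
        raise SchemeError("iob_spans requires an IOB2 corpus")
    spans: list[EntitySpan] = []
    for i, sent in enumerate(corpus.sentences):
        start = None
        etype = None
        labels = sent.gold_labels()
        for j, lab in enumerate(labels):
            if lab.startswith("B-"):
                if start is not None:
                    spans.append(EntitySpan(i, start, j, etype))
                start, etype = j, lab[2:]
            elif lab == "O":
                if start is not None:
                    spans.append(EntitySpan(i, start, j, etype))
                    start, etype = None, None
        if start is not None:
            spans.append(EntitySpan(i, start, len(labels), etype))
    return spans


def spans_to_iob(token_texts: list[list[str]], spans: Iterable[EntitySpan]) -> TaggedCorpus:
    """Build an IOB2 corpus from sentence token texts and typed spans."""
    labels = [["O"] * len(texts) for texts in token_texts]
    types: set[str] = set()
    for sp in spans:
        if sp.end > len(labels[sp.sentence_index]):
            raise CorpusError(f"span {sp} exceeds sentence length")
        labels[sp.sentence_index][sp.start] = f"B-{sp.entity_type}"
        for j in range(sp.start + 1, sp.end):
            labels[sp.sentence_index][j] = f"I-{sp.entity_type}"
        types.add(sp.entity_type)
    sentences = [
        Sentence([Token(t, l) for t, l in zip(texts, labs)])
        for texts, labs in zip(token_texts, labels)
    ]
    return TaggedCorpus(sentences, IOB2, types)


def iob_to_fpns(
    corpus: TaggedCorpus, connectives: frozenset[str] = DEFAULT_CONNECTIVES
) -> TaggedCorpus:
    """Convert gold IOB2 annotation to the seven-state FPNS scheme.

    Within each entity the first token becomes PF, the last SF and interior
    tokens J (when the surface form is a connective) or IF; a single-token
    entity is PF alone.  The token immediately left of an entity becomes LB,
    the one immediately right RB.  Conflicts are resolved by the priority
    PF > SF > IF > J > LB > RB > O.  Entity types are preserved on the
    returned corpus's ``spans`` list.
    """
    if corpus.label_scheme != IOB2:
        raise SchemeError("iob_to_fpns requires an IOB2 corpus")
    spans = iob_spans(corpus)
    by_sentence: dict[int, list[EntitySpan]] = {}
    for sp in spans:
        by_sentence.setdefault(sp.sentence_index, []).append(sp)

    sentences: list[Sentence] = []
    for i, sent in enumerate(corpus.sentences):
        n = len(sent)
        labels = ["O"] * n

        def place(j: int, lab: str) -> None:
            if _FPNS_PRIORITY[lab] < _FPNS_PRIORITY[labels[j]]:
                labels[j] = lab

        for sp in by_sentence.get(i, []):
            if sp.end - sp.start == 1:
                place(sp.start, "PF")
            else:
                place(sp.start, "PF")
                place(sp.end - 1, "SF")
                for j in range(sp.start + 1, sp.end - 1):
                    place(j, "J" if sent.tokens[j].text in connectives else "IF")
        # boundary labels second: priority makes entity labels win, and LB
        # (placed after RB here via priority ranks) wins over RB
        for sp in by_sentence.get(i, []):
            if sp.end < n:
                place(sp.end, "RB")
            if sp.start > 0:
                place(sp.start - 1, "LB")
        sentences.append(
            Sentence([Token(t.text, lab) for t, lab in zip(sent.tokens, labels)])
        )
    return TaggedCorpus(sentences, FPNS, set(corpus.entity_types), spans=spans)


def fpns_to_spans(labels: Sequence[str]) -> list[tuple[int, int]]:
    """Decode maximal runs of entity-internal FPNS labels into [start, end) spans.

    Adjacent entities with no separating token merge into one run; this is a
    documented lossy case of the FPNS scheme.
    """
    for lab in labels:
        if lab not in FPNS_VALUES:
            raise SchemeError(f"{lab!r} is not an FPNS label")
    spans: list[tuple[int, int]] = []
    start = None
    for j, lab in enumerate(labels):
        if lab in ENTITY_LABELS:
            if start is None:
                start = j
        else:
            if start is not None:
                spans.append((start, j))
                start = None
    if start is not None:
        spans.append((start, len(labels)))
    return spans


def copy_corpus(corpus: TaggedCorpus) -> TaggedCorpus:
    """Deep-enough copy: tokens are re-created, spans list is shared-immutable."""
    return TaggedCorpus(
        [Sentence([replace(t) for t in s.tokens]) for s in corpus.sentences],
        corpus.label_scheme,
        set(corpus.entity_types),
        list(corpus.spans) if corpus.spans is not None else None,
    )
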