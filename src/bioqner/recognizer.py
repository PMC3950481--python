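"""End-to-end recognisers: baseline, Q-learning, and Q-learning with transfer.

All three share the same front end (feature-lexicon induction on the FPNS
conversion of the training corpus) and back end (transformation-based
correction rules, span decoding, span typing).  They differ in how token
labels are proposed:

* ``baseline``        — the per-token lexicon argmax label,
* ``qlearn``          — greedy decoding from a learned Q table,
* ``qlearn_transfer`` — greedy decoding from the sum of a frozen source
  table (through an inter-task mapping) and a learned correction table.

Correction rules are learned on each recogniser's own training output, so
they repair that recogniser's systematic mistakes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Callable, Optional

from . import corpus_io, evaluation, features, qlearn, rules, transfer
from .corpus_io import EntitySpan, Sentence, TaggedCorpus, Token
from .features import FeatureLexicons
from .qlearn import LearnerConfig, QTable
from .rules import RuleList
from .transfer import TaskMapping

MODES = ("baseline", "qlearn", "qlearn_transfer")


@dataclass
class ModelBundle:
    mode: str
    lexicons: FeatureLexicons
    type_lexicons: dict[str, dict[features.Feature, float]]
    rule_list: RuleList
    qtable: Optional[QTable] = None
    q_source: Optional[QTable] = None
    mapping: Optional[TaskMapping] = None
    learner_config: Optional[LearnerConfig] = None

    def q_lookup(self) -> Optional[Callable[[qlearn.StateKey, int], float]]:
        if self.mode == "baseline":
            return None
        if self.mode == "qlearn":
            return self.qtable.get
        return lambda x, u: transfer.combined_q(self.q_source, self.qtable, self.mapping, x, u)


def train_recognizer(
    train_iob: TaggedCorpus,
    mode: str = "qlearn",
    learner_config: Optional[LearnerConfig] = None,
    source: Optional[ModelBundle] = None,
    rule_threshold: int = 2,
    min_quality: float = 0.1,
    min_count: int = 2,
) -> tuple[ModelBundle, list[float]]:
    """Fit one of the three recognisers on an IOB2 training corpus.

    Returns the model bundle and the Q learning curve (empty for baseline).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "qlearn_transfer" and source is None:
        raise ValueError("qlearn_transfer requires a source model bundle")
    cfg = learner_config or LearnerConfig()

    fpns_train = corpus_io.iob_to_fpns(train_iob)
    lexicons = features.induce_lexicons(fpns_train, min_quality=min_quality, min_count=min_count)
    type_lexicons = features.induce_type_lexicons(train_iob, min_quality=min_quality, min_count=min_count)

    curve: list[float] = []
    qtable: Optional[QTable] = None
    q_source: Optional[QTable] = None
    mapping: Optional[TaskMapping] = None

    if mode == "baseline":
        tagged = rules.initial_tag(fpns_train, lexicons)
    else:
        if mode == "qlearn":
            qtable, curve = qlearn.train(fpns_train, lexicons, cfg)
            lookup = qtable.get
        else:
            q_source = source.qtable if source.qtable is not None else QTable()
            mapping = transfer.build_mapping(source.lexicons, lexicons)
            qtable, curve = transfer.transfer_train(fpns_train, lexicons, q_source, mapping, cfg)
            qt, qs, mp = qtable, q_source, mapping
            lookup = lambda x, u: transfer.combined_q(qs, qt, mp, x, u)
        tagged = corpus_io.copy_corpus(fpns_train)
        prepped = qlearn.prepare(tagged, lexicons)
        for sent, p in zip(tagged.sentences, prepped):
            labels = qlearn.greedy_labels(p, lookup)
            for tok, lab in zip(sent.tokens, labels):
                tok.pred_label = lab

    rule_list = rules.learn_rules(tagged, fpns_train, lexicons, threshold=rule_threshold)
    bundle = ModelBundle(
        mode, lexicons, type_lexicons, rule_list, qtable, q_source, mapping, cfg
    )
    return bundle, curve


def predict(bundle: ModelBundle, corpus: TaggedCorpus) -> TaggedCorpus:
    """Tag a corpus: propose FPNS labels, apply rules, decode and type spans.

    The returned IOB2 corpus carries the predictions in its label column.
    """
    lookup = bundle.q_lookup()
    texts: list[list[str]] = []
    spans: list[EntitySpan] = []
    for i, sent in enumerate(corpus.sentences):
        p = qlearn.prepare(
            TaggedCorpus([Sentence([Token(t.text, "O") for t in sent.tokens])], "FPNS"),
            bundle.lexicons,
        )[0]
        if lookup is None:
            labels = list(p.initial)
        else:
            labels = qlearn.greedy_labels(p, lookup)
        if len(bundle.rule_list):
            work = TaggedCorpus(
                [Sentence([Token(t, "O", pred_label=l) for t, l in zip(p.texts, labels)])],
                "FPNS",
            )
            work = rules.apply_rules(bundle.rule_list, work)
            labels = [t.pred_label for t in work.sentences[0].tokens]
        texts.append(p.texts)
        for s, e in corpus_io.fpns_to_spans(labels):
            etype = features.assign_span_type(sent, (s, e), bundle.type_lexicons)
            spans.append(EntitySpan(i, s, e, etype))
    return corpus_io.spans_to_iob(texts, spans)


def evaluate(bundle: ModelBundle, test_iob: TaggedCorpus) -> evaluation.MetricReport:
    """Entity-level metrics of the bundle's predictions against IOB2 gold."""
    return evaluation.report(predict(bundle, test_iob), test_iob)


# ---------------------------------------------------------------------------
# bundle persistence: a directory of plain-text artefacts

_META = "meta.json"
_LEX = "lexicons.txt"
_TYPES = "type_lexicons.txt"
_RULES = "rules.txt"
_QTABLE = "qtable.txt"
_QSOURCE = "qsource.txt"
_MAPPING = "mapping.txt"


def _type_lex_to_text(tl: dict[str, dict[features.Feature, float]]) -> str:
    lines = []
    for t in sorted(tl):
        for f, score in sorted(tl[t].items(), key=lambda kv: (kv[0].kind, kv[0].value)):
            lines.append(f"{t}\t{f.kind}\t{f.value}\t{score!r}")
    return "\n".join(lines) + ("\n" if lines else "")


def _type_lex_from_text(text: str) -> dict[str, dict[features.Feature, float]]:
    out: dict[str, dict[features.Feature, float]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        t, kind, value, score = line.split("\t")
        out.setdefault(t, {})[features.Feature(kind, value)] = float(score)
    return out


def save_bundle(bundle: ModelBundle, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {
        "mode": bundle.mode,
        "learner_config": (
            vars(bundle.learner_config) if bundle.learner_config is not None else None
        ),
        "entity_types": sorted(bundle.type_lexicons),
    }
    with open(os.path.join(path, _META), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    _write(path, _LEX, features.lexicons_to_text(bundle.lexicons))
    _write(path, _TYPES, _type_lex_to_text(bundle.type_lexicons))
    _write(path, _RULES, rules.rules_to_text(bundle.rule_list))
    if bundle.qtable is not None:
        _write(path, _QTABLE, bundle.qtable.to_text())
    if bundle.q_source is not None:
        _write(path, _QSOURCE, bundle.q_source.to_text())
    if bundle.mapping is not None:
        _write(path, _MAPPING, bundle.mapping.to_text())


def _write(path: str, name: str, text: str) -> None:
    with open(os.path.join(path, name), "w", encoding="utf-8") as fh:
        fh.write(text)


def _read(path: str, name: str) -> Optional[str]:
    p = os.path.join(path, name)
    if not os.path.exists(p):
        return None
    with open(p, encoding="utf-8") as fh:
        return fh.read()


def load_bundle(path: str) -> ModelBundle:
    with open(os.path.join(path, _META), encoding="utf-8") as fh:
        meta = json.load(fh)
    lex = features.lexicons_from_text(_read(path, _LEX))
    type_lex = _type_lex_from_text(_read(path, _TYPES) or "")
    rl = rules.rules_from_text(_read(path, _RULES) or "")
    qt = _read(path, _QTABLE)
    qs = _read(path, _QSOURCE)
    mp = _read(path, _MAPPING)
    cfg = meta.get("learner_config")
    return ModelBundle(
        meta["mode"],
        lex,
        type_lex,
        rl,
        QTable.from_text(qt) if qt is not None else None,
        QTable.from_text(qs) if qs is not None else None,
        TaskMapping.from_text(mp) if mp is not None else None,
        LearnerConfig(**cfg) if cfg else None,
    )
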