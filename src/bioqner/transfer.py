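"""Q-value reuse: transfer of a learned action-value table between tasks.

The source table, learned on one corpus, is frozen and consulted through an
inter-task mapping (f_x on states, f_u on actions); a target table is learned
on the new corpus to correct the source values.  The effective value is the
exact sum

    Q(x, u) = Q_source(f_x(x), f_u(u)) + Q_target(x, u)

with no interpolation weight.  When both tasks use the FPNS label alphabet
the state mapping is the identity; otherwise each target label component maps
to the source label whose lexicon shares the largest Jaccard overlap of
feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .corpus_io import CorpusError, TaggedCorpus
from .features import FeatureLexicons
from .qlearn import (
    ACTIONS,
    END,
    NONE_CLASS,
    START,
    LearnerConfig,
    QTable,
    RewardModel,
    StateKey,
    prepare,
    training_loop,
)

_PASSTHROUGH = frozenset({NONE_CLASS, START, END})


@dataclass
class TaskMapping:
    """Total state/action maps from target alphabets into source alphabets."""

    label_map: dict[str, str]
    action_map: dict[int, int] = field(default_factory=lambda: {a: a for a in ACTIONS})

    def map_label(self, lab: str) -> str:
        if lab in _PASSTHROUGH:
            return lab
        return self.label_map.get(lab, lab)

    def map_state(self, x: StateKey) -> StateKey:
        return StateKey(self.map_label(x.cur), self.map_label(x.prev), self.map_label(x.nxt))

    def map_action(self, u: int) -> int:
        return self.action_map.get(u, u)

    def to_text(self) -> str:
        lines = [f"STATE\t{t}\t{s}" for t, s in sorted(self.label_map.items())]
        lines += [f"ACTION\t{t}\t{s}" for t, s in sorted(self.action_map.items())]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TaskMapping":
        label_map: dict[str, str] = {}
        action_map: dict[int, int] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            kind, t, s = line.split("\t")
            if kind == "STATE":
                label_map[t] = s
            elif kind == "ACTION":
                action_map[int(t)] = int(s)
            else:
                raise ValueError(f"unknown mapping record {kind!r}")
        return cls(label_map, action_map or {a: a for a in ACTIONS})


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def build_mapping(
    source_lexicons: FeatureLexicons, target_lexicons: FeatureLexicons
) -> TaskMapping:
    """Deterministic inter-task mapping from induced lexicons.

    Shared label alphabet => identity.  Otherwise each target label maps to
    the source label with maximal Jaccard overlap of lexicon feature sets;
    ties (including all-empty overlap) fall back to source alphabet order.
    """
    if not source_lexicons.by_label or not target_lexicons.by_label:
        raise ValueError("both lexicon sets must be induced before mapping")
    if tuple(source_lexicons.labels) == tuple(target_lexicons.labels):
        return TaskMapping({lab: lab for lab in target_lexicons.labels})
    label_map: dict[str, str] = {}
    for i, t_lab in enumerate(target_lexicons.labels):
        t_feats = set(target_lexicons.by_label.get(t_lab, {}))
        best = source_lexicons.labels[min(i, len(source_lexicons.labels) - 1)]
        best_j = -1.0
        for s_lab in source_lexicons.labels:
            j = _jaccard(t_feats, set(source_lexicons.by_label.get(s_lab, {})))
            if j > best_j:
                best, best_j = s_lab, j
        if best_j <= 0.0:
            # no overlap anywhere: positional fallback in source alphabet order
            best = source_lexicons.labels[min(i, len(source_lexicons.labels) - 1)]
        label_map[t_lab] = best
    return TaskMapping(label_map)


def combined_q(
    q_source: QTable, q_target: QTable, m: TaskMapping, x: StateKey, u: int
) -> float:
    """Exact Q-value-reuse sum; missing entries read as 0."""
    return q_source.get(m.map_state(x), m.map_action(u)) + q_target.get(x, u)


def transfer_train(
    target_corpus: TaggedCorpus,
    lexicons: FeatureLexicons,
    q_source: QTable,
    m: TaskMapping,
    cfg: LearnerConfig,
    callback: Optional[Callable[[int], None]] = None,
) -> tuple[QTable, list[float]]:
    """Train a correction table on the target task.

    The loop is identical to :func:`bioqner.qlearn.train` except that action
    selection and the TD target use the combined value, while updates are
    applied to the target table only; ``q_source`` is never modified.
    """
    if target_corpus.label_scheme != "FPNS":
        raise CorpusError("training requires a gold FPNS corpus")
    prepped = prepare(target_corpus, lexicons)
    rm = RewardModel(lexicons)
    q_target = QTable()

    def lookup(x: StateKey, u: int) -> float:
        return q_source.get(m.map_state(x), m.map_action(u)) + q_target.get(x, u)

    curve = training_loop(prepped, cfg, rm, q_target, lookup, callback)
    return q_target, curve
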