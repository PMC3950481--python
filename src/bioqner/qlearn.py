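"""Tabular Q-learning over tagging states.

The tagging task is a finite MDP <X, U, R>: one episode per sentence, one
time step per token.  The state abstracts a token position as the triple
(lexicon vote for the current token, previously assigned FPNS label, lexicon
vote for the next token); surface words are deliberately excluded from the
key so the table stays small and transferable across corpora.

Three actions are available at every step:

* ``POSITIVE`` (0) — accept the lexicons' argmax FPNS label (O without a vote),
* ``NEGATIVE`` (1) — reject entity membership: emit O, or RB/LB when adjacent
  to an open entity or an upcoming vote,
* ``NEUTER``   (2) — keep the initial tagger's label for the token.

A correct move is rewarded with the quality of the token's dominant feature
for the gold label (floored at 0.1 for featureless tokens); an incorrect move
earns 0.  Values are learned with the standard off-policy update

    Q(x,u) <- Q(x,u) + alpha * [r + gamma * max_u' Q(x',u') - Q(x,u)]
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .corpus_io import ENTITY_LABELS, CorpusError, Sentence, TaggedCorpus
from .features import Feature, FeatureLexicons, extract_features

NONE_CLASS = "NONE"
START = "START"
END = "END"
#: terminal-state sentinel for q_update
TERMINAL = None


class Action:
    """The three rule-polarity action codes."""

    POSITIVE = 0
    NEGATIVE = 1
    NEUTER = 2


ACTIONS: tuple[int, int, int] = (Action.POSITIVE, Action.NEGATIVE, Action.NEUTER)


@dataclass(frozen=True)
class StateKey:
    """Discretized tagging state (current vote, previous assignment, next vote)."""

    cur: str
    prev: str
    nxt: str


class QTable:
    """Finite map (StateKey, action) -> value; unseen pairs read as 0."""

    def __init__(self) -> None:
        self.values: dict[tuple[StateKey, int], float] = {}

    def get(self, x: StateKey, u: int) -> float:
        return self.values.get((x, u), 0.0)

    def set(self, x: StateKey, u: int, v: float) -> None:
        self.values[(x, u)] = v

    def copy(self) -> "QTable":
        q = QTable()
        q.values = dict(self.values)
        return q

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, QTable) and self.values == other.values

    def to_text(self) -> str:
        """Plain-text records ``cur TAB prev TAB nxt TAB action TAB value``.

        Values are written with ``repr`` so the round-trip is bit-exact.
        """
        lines = []
        for (x, u), v in sorted(
            self.values.items(), key=lambda kv: (kv[0][0].cur, kv[0][0].prev, kv[0][0].nxt, kv[0][1])
        ):
            lines.append(f"{x.cur}\t{x.prev}\t{x.nxt}\t{u}\t{v!r}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_text(cls, text: str) -> "QTable":
        q = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            cur, prev, nxt, u, v = line.split("\t")
            q.set(StateKey(cur, prev, nxt), int(u), float(v))
        return q


@dataclass
class LearnerConfig:
    """Q-learning hyper-parameters.

    ``alpha`` may be 0, which freezes the table (useful as a degenerate
    check); ``epsilon`` decays multiplicatively per episode.
    """

    alpha: float = 0.1
    gamma: float = 0.9
    epsilon: float = 0.1
    epsilon_decay: float = 0.995
    episodes: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if not (0.0 < self.epsilon_decay <= 1.0):
            raise ValueError("epsilon_decay must lie in (0, 1]")
        if self.episodes <= 0:
            raise ValueError("episodes must be positive")


@dataclass
class RewardModel:
    """Quality lookup backing the reward: dominant-feature quality per label."""

    lexicons: FeatureLexicons
    floor: float = 0.1

    def dominant_quality(self, feats: Iterable[Feature], label: str) -> float:
        lex = self.lexicons.by_label.get(label)
        if lex is None:
            raise ValueError(f"unknown label {label!r}")
        best = 0.0
        for f in feats:
            v = lex.get(f, 0.0)
            if v > best:
                best = v
        return best


def reward(
    x: StateKey,
    u: int,
    gold_label: str,
    proposed_label: str,
    rm: RewardModel,
    feats: Sequence[Feature] = (),
) -> float:
    """Quality of the move: dominant-feature quality when correct, else 0."""
    if gold_label not in rm.lexicons.by_label:
        raise ValueError(f"unknown gold label {gold_label!r}")
    if proposed_label != gold_label:
        return 0.0
    return max(rm.dominant_quality(feats, gold_label), rm.floor)


def q_update(
    q: QTable,
    x: StateKey,
    u: int,
    r: float,
    x_next: Optional[StateKey],
    cfg: LearnerConfig,
) -> float:
    """One off-policy TD update; returns the new Q(x, u).

    ``x_next=TERMINAL`` (None) drops the bootstrap term.
    """
    import math

    if not math.isfinite(r):
        raise ValueError("reward must be finite")
    boot = 0.0 if x_next is None else max(q.get(x_next, a) for a in ACTIONS)
    new = q.get(x, u) + cfg.alpha * (r + cfg.gamma * boot - q.get(x, u))
    q.set(x, u, new)
    return new


def _select(q_lookup: Callable[[StateKey, int], float], x: StateKey, eps: float, rng: random.Random) -> int:
    if eps > 0.0 and rng.random() < eps:
        return rng.randrange(3)
    best, best_v = ACTIONS[0], q_lookup(x, ACTIONS[0])
    for a in ACTIONS[1:]:
        v = q_lookup(x, a)
        if v > best_v:
            best, best_v = a, v
    return best


def select_action(q: QTable, x: StateKey, cfg: LearnerConfig, rng: random.Random) -> int:
    """Epsilon-greedy action choice; greedy ties break to the lowest action code."""
    return _select(q.get, x, cfg.epsilon, rng)


def action_label(
    u: int,
    vote: Optional[str],
    initial: str,
    prev_assigned: str,
    next_vote: Optional[str],
) -> str:
    """Concrete FPNS label proposed by an action."""
    if u == Action.POSITIVE:
        return vote if vote is not None else "O"
    if u == Action.NEGATIVE:
        if prev_assigned in ENTITY_LABELS:
            return "RB"
        if next_vote in ENTITY_LABELS:
            return "LB"
        return "O"
    return initial


@dataclass
class PreppedSentence:
    """Per-sentence cache: features, lexicon votes and gold labels."""

    texts: list[str]
    gold: list[str]
    feats: list[list[Feature]]
    votes: list[Optional[str]]
    initial: list[str]


def prepare(corpus: TaggedCorpus, lexicons: FeatureLexicons, initial_labels=None) -> list[PreppedSentence]:
    prepped = []
    for i, sent in enumerate(corpus.sentences):
        feats = [extract_features(sent, j) for j in range(len(sent))]
        votes = [lexicons.vote(fs) for fs in feats]
        init = (
            list(initial_labels[i])
            if initial_labels is not None
            else [v if v is not None else "O" for v in votes]
        )
        prepped.append(PreppedSentence(sent.texts(), sent.gold_labels(), feats, votes, init))
    return prepped


def _state(p: PreppedSentence, k: int, prev: str) -> StateKey:
    cur = p.votes[k] if p.votes[k] is not None else NONE_CLASS
    if k + 1 < len(p.gold):
        nxt = p.votes[k + 1] if p.votes[k + 1] is not None else NONE_CLASS
    else:
        nxt = END
    return StateKey(cur, prev, nxt)


def _run_episode(
    p: PreppedSentence,
    cfg: LearnerConfig,
    q: QTable,
    q_lookup: Callable[[StateKey, int], float],
    rm: RewardModel,
    rng: random.Random,
    eps: float,
) -> float:
    prev = START
    total = 0.0
    n = len(p.gold)
    for k in range(n):
        x = _state(p, k, prev)
        u = _select(q_lookup, x, eps, rng)
        next_vote = p.votes[k + 1] if k + 1 < n else None
        proposed = action_label(u, p.votes[k], p.initial[k], prev, next_vote)
        r = reward(x, u, p.gold[k], proposed, rm, p.feats[k])
        if k + 1 < n:
            x2_cur = p.votes[k + 1] if p.votes[k + 1] is not None else NONE_CLASS
            x2_nxt = (p.votes[k + 2] if p.votes[k + 2] is not None else NONE_CLASS) if k + 2 < n else END
            x2 = StateKey(x2_cur, proposed, x2_nxt)
            boot = max(q_lookup(x2, a) for a in ACTIONS)
        else:
            boot = 0.0
        q.set(x, u, q.get(x, u) + cfg.alpha * (r + cfg.gamma * boot - q_lookup(x, u)))
        prev = proposed
        total += r
    return total


def training_loop(
    prepped: list[PreppedSentence],
    cfg: LearnerConfig,
    rm: RewardModel,
    q: QTable,
    q_lookup: Callable[[StateKey, int], float],
    callback: Optional[Callable[[int], None]] = None,
) -> list[float]:
    """Shared episode loop; ``q_lookup`` abstracts plain vs combined values."""
    if not prepped:
        raise CorpusError("empty corpus")
    rng = random.Random(cfg.seed)
    eps = cfg.epsilon
    order = list(range(len(prepped)))
    curve: list[float] = []
    ep = 0
    while ep < cfg.episodes:
        rng.shuffle(order)
        for idx in order:
            if ep >= cfg.episodes:
                break
            curve.append(_run_episode(prepped[idx], cfg, q, q_lookup, rm, rng, eps))
            eps *= cfg.epsilon_decay
            ep += 1
            if callback is not None:
                callback(ep)
    return curve


def train(
    corpus: TaggedCorpus,
    lexicons: FeatureLexicons,
    cfg: LearnerConfig,
    callback: Optional[Callable[[int], None]] = None,
) -> tuple[QTable, list[float]]:
    """Train a fresh table on a gold FPNS corpus; reproducible from cfg.seed.

    Returns the table and the per-episode summed reward (learning curve).
    """
    if corpus.label_scheme != "FPNS":
        raise CorpusError("training requires a gold FPNS corpus")
    prepped = prepare(corpus, lexicons)
    rm = RewardModel(lexicons)
    q = QTable()
    curve = training_loop(prepped, cfg, rm, q, q.get, callback)
    return q, curve


def greedy_labels(
    p: PreppedSentence, q_lookup: Callable[[StateKey, int], float]
) -> list[str]:
    """Greedy left-to-right decode of one prepared sentence."""
    prev = START
    out: list[str] = []
    n = len(p.texts)
    for k in range(n):
        x = _state(p, k, prev)
        best, best_v = ACTIONS[0], q_lookup(x, ACTIONS[0])
        for a in ACTIONS[1:]:
            v = q_lookup(x, a)
            if v > best_v:
                best, best_v = a, v
        next_vote = p.votes[k + 1] if k + 1 < n else None
        lab = action_label(best, p.votes[k], p.initial[k], prev, next_vote)
        out.append(lab)
        prev = lab
    return out


def tag(sentence: Sentence, q: QTable, lexicons: FeatureLexicons) -> list[str]:
    """Deterministic greedy FPNS labels for one sentence."""
    feats = [extract_features(sentence, j) for j in range(len(sentence))]
    votes = [lexicons.vote(fs) for fs in feats]
    p = PreppedSentence(
        sentence.texts(),
        ["O"] * len(sentence),
        feats,
        votes,
        [v if v is not None else "O" for v in votes],
    )
    return greedy_labels(p, q.get)
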