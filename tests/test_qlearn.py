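"""Tabular Q-learning: update rule, action selection, reward, training, decoding."""

import itertools
import math
import random

import pytest

from bioqner import corpus_io, qlearn
from bioqner.corpus_io import Sentence, Token
from bioqner.features import Feature, FeatureLexicons, induce_lexicons
from bioqner.qlearn import (
    ACTIONS,
    Action,
    LearnerConfig,
    QTable,
    RewardModel,
    StateKey,
    q_update,
    reward,
    select_action,
    tag,
    train,
)

from conftest import make_corpus


def _cfg(**kw):
    base = dict(alpha=0.5, gamma=0.9, epsilon=0.0, epsilon_decay=1.0, episodes=1, seed=0)
    base.update(kw)
    return LearnerConfig(**base)


class TestQUpdate:
    def test_single_update_from_zero_table(self):
        q = QTable()
        x, x2 = StateKey("PF", "START", "O"), StateKey("O", "PF", "END")
        new = q_update(q, x, 0, 1.0, x2, _cfg(alpha=0.5, gamma=0.9))
        assert new == pytest.approx(0.5)
        assert q.get(x, 0) == pytest.approx(0.5)

    def test_zero_step_size_leaves_value_unchanged(self):
        q = QTable()
        x = StateKey("PF", "START", "O")
        q.set(x, 1, 0.7)
        assert q_update(q, x, 1, 5.0, None, _cfg(alpha=0.0)) == 0.7

    def test_terminal_state_drops_bootstrap(self):
        q = QTable()
        x = StateKey("PF", "START", "END")
        assert q_update(q, x, 0, 1.0, None, _cfg(alpha=1.0, gamma=0.9)) == 1.0

    def test_only_the_updated_entry_changes(self):
        q = QTable()
        x, y = StateKey("PF", "START", "O"), StateKey("IF", "PF", "O")
        q.set(y, 2, 0.3)
        q_update(q, x, 0, 1.0, y, _cfg())
        assert q.get(y, 2) == 0.3 and len(q) == 2

    def test_non_finite_reward_rejected(self):
        with pytest.raises(ValueError):
            q_update(QTable(), StateKey("O", "START", "END"), 0, float("nan"), None, _cfg())


def _chain_mdp():
    """Deterministic 4-state chain: action 0 advances (reward by state),
    action 1 stays (reward 0.1), action 2 resets to s0 (reward 0)."""
    states = [StateKey(f"s{i}", "-", "-") for i in range(4)]
    advance_reward = [0.2, 0.4, 0.6, 1.0]

    def step(i, a):
        if a == 0:
            if i == 3:
                return None, 1.0  # terminal
            return i + 1, advance_reward[i]
        if a == 1:
            return i, 0.1
        return 0, 0.0

    return states, step


def _value_iteration(step, n_states, gamma, tol=1e-12):
    """Independent oracle: dense value iteration over the explicit model."""
    q = [[0.0] * 3 for _ in range(n_states)]
    while True:
        delta = 0.0
        new = [[0.0] * 3 for _ in range(n_states)]
        for i in range(n_states):
            for a in range(3):
                nxt, r = step(i, a)
                boot = 0.0 if nxt is None else max(q[nxt])
                new[i][a] = r + gamma * boot
                delta = max(delta, abs(new[i][a] - q[i][a]))
        q = new
        if delta < tol:
            return q


class TestChainMdpConvergence:
    def test_q_update_sweeps_reach_the_value_iteration_fixed_point(self):
        states, step = _chain_mdp()
        gamma = 0.9
        oracle = _value_iteration(step, 4, gamma)
        q = QTable()
        cfg = _cfg(alpha=0.5, gamma=gamma)
        for _ in range(2000):
            delta = 0.0
            for i, a in itertools.product(range(4), range(3)):
                nxt, r = step(i, a)
                before = q.get(states[i], a)
                q_update(q, states[i], a, r, None if nxt is None else states[nxt], cfg)
                delta = max(delta, abs(q.get(states[i], a) - before))
            if delta < 1e-12:
                break
        for i, a in itertools.product(range(4), range(3)):
            assert q.get(states[i], a) == pytest.approx(oracle[i][a], abs=1e-6)
        for i in range(4):
            greedy = max(range(3), key=lambda a: q.get(states[i], a))
            assert greedy == max(range(3), key=lambda a: oracle[i][a])


class TestSelectAction:
    def test_all_equal_ties_break_to_action_zero(self):
        rng = random.Random(0)
        x = StateKey("O", "START", "END")
        assert select_action(QTable(), x, _cfg(epsilon=0.0), rng) == Action.POSITIVE

    def test_greedy_picks_the_argmax(self):
        q = QTable()
        x = StateKey("O", "START", "END")
        q.set(x, 1, 0.9)
        assert select_action(q, x, _cfg(epsilon=0.0), random.Random(0)) == Action.NEGATIVE

    def test_full_exploration_is_near_uniform(self):
        rng = random.Random(1)
        x = StateKey("O", "START", "END")
        counts = [0, 0, 0]
        n = 3000
        for _ in range(n):
            counts[select_action(QTable(), x, _cfg(epsilon=1.0), rng)] += 1
        sigma = math.sqrt(n * (1 / 3) * (2 / 3))
        for c in counts:
            assert abs(c - n / 3) < 5 * sigma


def _toy_lexicons():
    by_label = {lab: {} for lab in corpus_io.FPNS_LABELS}
    by_label["PF"][Feature("surface_word", "MK1")] = 0.8
    by_label["O"][Feature("surface_word", "ctx")] = 0.3
    return FeatureLexicons(tuple(corpus_io.FPNS_LABELS), by_label, {}, 0.0)


class TestReward:
    def test_correct_move_earns_dominant_feature_quality(self):
        rm = RewardModel(_toy_lexicons())
        x = StateKey("PF", "START", "END")
        feats = [Feature("surface_word", "MK1")]
        assert reward(x, 0, "PF", "PF", rm, feats) == pytest.approx(0.8)

    def test_featureless_correct_move_earns_the_floor(self):
        rm = RewardModel(_toy_lexicons())
        x = StateKey("NONE", "START", "END")
        assert reward(x, 1, "O", "O", rm, []) == pytest.approx(0.1)

    def test_incorrect_move_earns_nothing(self):
        rm = RewardModel(_toy_lexicons())
        x = StateKey("PF", "START", "END")
        assert reward(x, 0, "O", "PF", rm, []) == 0.0

    def test_unknown_label_rejected(self):
        rm = RewardModel(_toy_lexicons())
        with pytest.raises(ValueError):
            reward(StateKey("O", "START", "END"), 0, "??", "??", rm, [])

    def test_discounted_episode_return_is_geometrically_bounded(
        self, clean_task, clean_lexicons
    ):
        """Rewards live in [0, 1], so any discounted return is < 1/(1-gamma)."""
        train_iob, _, _ = clean_task
        fpns = corpus_io.iob_to_fpns(train_iob)
        rm = RewardModel(clean_lexicons)
        rng = random.Random(5)
        gamma = 0.9
        prepped = qlearn.prepare(fpns, clean_lexicons)
        for p in prepped[:50]:
            ret = 0.0
            prev = "START"
            for k in range(len(p.gold)):
                u = rng.randrange(3)
                proposed = qlearn.action_label(
                    u, p.votes[k], p.initial[k], prev,
                    p.votes[k + 1] if k + 1 < len(p.gold) else None,
                )
                r = reward(
                    StateKey("O", prev, "O"), u, p.gold[k], proposed, rm, p.feats[k]
                )
                assert 0.0 <= r <= 1.0
                ret += (gamma ** k) * r
                prev = proposed
            assert ret < 1.0 / (1.0 - gamma)


class TestTraining:
    def test_identical_seeds_give_identical_tables(self, clean_task, clean_lexicons):
        train_iob, _, _ = clean_task
        fpns = corpus_io.iob_to_fpns(train_iob)
        cfg = LearnerConfig(seed=11, episodes=150)
        q1, c1 = train(fpns, clean_lexicons, cfg)
        q2, c2 = train(fpns, clean_lexicons, cfg)
        assert q1 == q2 and c1 == c2

    def test_stored_values_respect_the_reward_bound(self, clean_task, clean_lexicons):
        train_iob, _, _ = clean_task
        fpns = corpus_io.iob_to_fpns(train_iob)
        cfg = LearnerConfig(seed=2, episodes=400, epsilon=1.0, epsilon_decay=1.0)
        q, _ = train(fpns, clean_lexicons, cfg)
        bound = 1.0 / (1.0 - cfg.gamma) + 1e-9
        assert all(0.0 <= v <= bound for v in q.values.values())

    def test_one_sentence_with_perfect_lexicon_is_reproduced(self):
        corpus = make_corpus(
            [(["MK1", "ctx"], ["PF", "RB"])], scheme="FPNS"
        )
        by_label = {lab: {} for lab in corpus_io.FPNS_LABELS}
        by_label["PF"][Feature("surface_word", "MK1")] = 0.9
        by_label["RB"][Feature("surface_word", "ctx")] = 0.9
        lex = FeatureLexicons(tuple(corpus_io.FPNS_LABELS), by_label, {}, 0.0)
        q, _ = train(corpus, lex, LearnerConfig(seed=0, episodes=300, epsilon=0.3))
        assert tag(corpus.sentences[0], q, lex) == ["PF", "RB"]

    def test_learning_curve_moving_average_trend_is_upward(self, clean_task, clean_lexicons):
        train_iob, _, _ = clean_task
        fpns = corpus_io.iob_to_fpns(train_iob)
        cfg = LearnerConfig(seed=3, episodes=800, epsilon=1.0, epsilon_decay=0.995)
        _, curve = train(fpns, clean_lexicons, cfg)
        w = 50
        first = sum(curve[:w]) / w
        last = sum(curve[-w:]) / w
        assert last >= first

    def test_empty_corpus_rejected(self, clean_lexicons):
        empty = corpus_io.TaggedCorpus([], "FPNS")
        with pytest.raises(corpus_io.CorpusError):
            train(empty, clean_lexicons, LearnerConfig())


class TestTagging:
    def test_empty_table_falls_back_to_lexicon_votes(self):
        lex = _toy_lexicons()
        sent = Sentence([Token("MK1", "O"), Token("zzz", "O")])
        assert tag(sent, QTable(), lex) == ["PF", "O"]

    def test_tag_is_deterministic(self, clean_task, clean_lexicons):
        train_iob, test_iob, _ = clean_task
        fpns = corpus_io.iob_to_fpns(train_iob)
        q, _ = train(fpns, clean_lexicons, LearnerConfig(seed=1, episodes=100))
        sent = test_iob.sentences[0]
        assert tag(sent, q, clean_lexicons) == tag(sent, q, clean_lexicons)


class TestQTableSerialization:
    def test_round_trip_is_bit_exact(self):
        q = QTable()
        q.set(StateKey("PF", "START", "O"), 0, 0.1 + 0.2)  # 0.30000000000000004
        q.set(StateKey("NONE", "IF", "END"), 2, 1.0 / 3.0)
        q.set(StateKey("O", "O", "O"), 1, 5e-324)
        back = QTable.from_text(q.to_text())
        assert back == q
        assert back.to_text() == q.to_text()
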