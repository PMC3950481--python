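"""Transformation-based rule learning: candidates, scoring, greedy loop, application."""

import pytest

from bioqner import corpus_io
from bioqner.corpus_io import FPNS_LABELS, CorpusError, TaggedCorpus
from bioqner.features import Feature, FeatureLexicons
from bioqner.rules import (
    DEFAULT_TEMPLATES,
    Rule,
    RuleList,
    apply_rules,
    generate_candidates,
    initial_tag,
    learn_rules,
    parse_rule,
    rules_from_text,
    rules_to_text,
    score_rule,
    serialize_rule,
)

from conftest import make_corpus


def _with_preds(pairs, scheme="FPNS"):
    """[(texts, gold, pred)] -> corpus with pred labels set."""
    corpus = make_corpus([(t, g) for t, g, _ in pairs], scheme=scheme)
    for sent, (_, _, preds) in zip(corpus.sentences, pairs):
        for tok, p in zip(sent.tokens, preds):
            tok.pred_label = p
    return corpus


def _toy_lexicons():
    by_label = {lab: {} for lab in FPNS_LABELS}
    by_label["PF"][Feature("surface_word", "MK1")] = 0.8
    return FeatureLexicons(tuple(FPNS_LABELS), by_label, {}, 0.0)


class TestInitialTag:
    def test_single_vote_wins(self):
        corpus = make_corpus([(["MK1"], ["PF"])], scheme="FPNS")
        tagged = initial_tag(corpus, _toy_lexicons())
        assert tagged.sentences[0].tokens[0].pred_label == "PF"

    def test_featureless_token_defaults_to_o(self):
        corpus = make_corpus([(["zzz"], ["O"])], scheme="FPNS")
        tagged = initial_tag(corpus, _toy_lexicons())
        assert tagged.sentences[0].tokens[0].pred_label == "O"

    def test_per_token_independence(self):
        c1 = make_corpus([(["MK1", "zzz"], ["PF", "O"])], scheme="FPNS")
        c2 = make_corpus([(["zzz", "MK1"], ["O", "PF"])], scheme="FPNS")
        lex = _toy_lexicons()
        t1 = initial_tag(c1, lex).sentences[0].pred_labels()
        t2 = initial_tag(c2, lex).sentences[0].pred_labels()
        assert t1 == ["PF", "O"] and t2 == ["O", "PF"]


class TestGenerateCandidates:
    def test_no_errors_no_candidates(self):
        gold = make_corpus([(["a"], ["O"])], scheme="FPNS")
        tagged = _with_preds([(["a"], ["O"], ["O"])])
        assert generate_candidates(tagged, gold) == set()

    def test_one_error_bounded_by_template_count(self):
        gold = make_corpus([(["a"], ["PF"])], scheme="FPNS")
        tagged = _with_preds([(["a"], ["PF"], ["O"])])
        templates = DEFAULT_TEMPLATES[:3]
        cands = generate_candidates(tagged, gold, templates)
        assert 1 <= len(cands) <= 3
        assert all(r.old == "O" and r.new == "PF" for r in cands)

    def test_matches_exhaustive_error_template_enumeration(self):
        gold = make_corpus(
            [(["a", "b", "c"], ["PF", "IF", "SF"])], scheme="FPNS"
        )
        tagged = _with_preds([(["a", "b", "c"], ["PF", "IF", "SF"], ["PF", "O", "O"])])
        got = generate_candidates(tagged, gold)
        expected = set()
        sent = tagged.sentences[0]
        preds = ["PF", "O", "O"]
        from bioqner.rules import _slot_values
        for j, (pred, gold_lab) in enumerate(zip(preds, ["PF", "IF", "SF"])):
            if pred == gold_lab:
                continue
            slots = _slot_values(sent, preds, j)
            for tmpl in DEFAULT_TEMPLATES:
                expected.add(Rule(tuple((s, slots[s]) for s in tmpl), pred, gold_lab))
        assert got == expected

    def test_misaligned_corpora_rejected(self):
        gold = make_corpus([(["a", "b"], ["O", "O"])], scheme="FPNS")
        tagged = _with_preds([(["a"], ["O"], ["O"])])
        with pytest.raises(CorpusError):
            generate_candidates(tagged, gold)


class TestScoreRule:
    def _fixture(self):
        # rule "word=w: O -> PF" fixes 3 (gold PF, pred O) and breaks 1 (gold O, pred O)
        gold = make_corpus(
            [(["w"], ["PF"]), (["w"], ["PF"]), (["w"], ["PF"]), (["w"], ["O"])],
            scheme="FPNS",
        )
        tagged = _with_preds([
            (["w"], ["PF"], ["O"]), (["w"], ["PF"], ["O"]),
            (["w"], ["PF"], ["O"]), (["w"], ["O"], ["O"]),
        ])
        rule = Rule((("cur_word", "w"),), "O", "PF")
        return rule, tagged, gold

    def test_net_error_change(self):
        rule, tagged, gold = self._fixture()
        assert score_rule(rule, tagged, gold) == 2

    def test_rule_matching_nothing_scores_zero(self):
        _, tagged, gold = self._fixture()
        rule = Rule((("cur_word", "absent"),), "O", "PF")
        assert score_rule(rule, tagged, gold) == 0

    def test_score_equals_apply_and_count_oracle(self):
        rule, tagged, gold = self._fixture()
        def errors(c):
            return sum(
                t.pred_label != g.tokens[j].gold_label
                for s, g in zip(c.sentences, gold.sentences)
                for j, t in enumerate(s.tokens)
            )
        before = errors(tagged)
        after = errors(apply_rules([rule], tagged))
        assert score_rule(rule, tagged, gold) == before - after


class TestLearnRules:
    def test_perfect_initial_tagging_learns_nothing(self):
        gold = make_corpus([(["MK1"], ["PF"])], scheme="FPNS")
        assert len(learn_rules(gold, gold, _toy_lexicons(), threshold=1)) == 0

    def test_planted_systematic_error_is_recovered_first(self):
        # the lexicon mislabels "amb" as PF everywhere; gold says it is O
        by_label = {lab: {} for lab in FPNS_LABELS}
        by_label["PF"][Feature("surface_word", "amb")] = 0.5
        lex = FeatureLexicons(tuple(FPNS_LABELS), by_label, {}, 0.0)
        gold = make_corpus(
            [(["amb", "x"], ["O", "O"])] * 5, scheme="FPNS"
        )
        rules = learn_rules(gold, gold, lex, threshold=2)
        assert len(rules) >= 1
        first = rules.rules[0]
        assert first.old == "PF" and first.new == "O"
        assert ("cur_word", "amb") in first.condition or ("cur_suffix", "amb") in first.condition

    def test_training_error_strictly_decreases_and_loop_terminates(self, clean_task, clean_lexicons):
        train_iob, _, _ = clean_task
        gold = corpus_io.iob_to_fpns(train_iob)
        tagged = initial_tag(gold, clean_lexicons)
        def errors(c):
            return sum(
                t.pred_label != g.tokens[j].gold_label
                for s, g in zip(c.sentences, gold.sentences)
                for j, t in enumerate(s.tokens)
            )
        initial_errors = errors(tagged)
        rules = learn_rules(tagged, gold, clean_lexicons, threshold=1)
        assert len(rules) <= initial_errors
        counts = [initial_errors]
        current = tagged
        for rule in rules:
            current = apply_rules([rule], current)
            counts.append(errors(current))
        assert all(b < a for a, b in zip(counts, counts[1:]))

    def test_threshold_below_one_rejected(self, clean_lexicons):
        gold = make_corpus([(["a"], ["O"])], scheme="FPNS")
        with pytest.raises(ValueError):
            learn_rules(gold, gold, clean_lexicons, threshold=0)

    def test_byte_identical_rule_lists_across_runs(self, clean_task, clean_lexicons):
        train_iob, _, _ = clean_task
        gold = corpus_io.iob_to_fpns(train_iob)
        r1 = learn_rules(gold, gold, clean_lexicons)
        r2 = learn_rules(gold, gold, clean_lexicons)
        assert rules_to_text(r1) == rules_to_text(r2)


class TestApplyRules:
    def test_empty_list_is_identity(self):
        tagged = _with_preds([(["a", "b"], ["O", "O"], ["PF", "O"])])
        out = apply_rules([], tagged)
        assert [t.pred_label for t in out.sentences[0].tokens] == ["PF", "O"]

    def test_second_rule_fires_on_context_created_by_first(self):
        tagged = _with_preds([(["m", "n"], ["PF", "SF"], ["O", "O"])])
        r1 = Rule((("cur_word", "m"),), "O", "PF")
        r2 = Rule((("prev_label", "PF"),), "O", "SF")
        # r2 alone matches nothing: no PF context exists yet
        alone = apply_rules([r2], tagged)
        assert [t.pred_label for t in alone.sentences[0].tokens] == ["O", "O"]
        both = apply_rules([r1, r2], tagged)
        assert [t.pred_label for t in both.sentences[0].tokens] == ["PF", "SF"]

    def test_rule_destroying_its_own_condition_is_idempotent(self):
        tagged = _with_preds([(["a", "b", "c"], ["O", "O", "O"], ["PF", "PF", "PF"])])
        rule = Rule((("prev_label", "PF"),), "PF", "O")
        once = apply_rules([rule], tagged)
        twice = apply_rules([rule], once)
        assert [t.pred_label for t in once.sentences[0].tokens] == ["PF", "O", "O"]
        assert [t.pred_label for t in twice.sentences[0].tokens] == [
            t.pred_label for t in once.sentences[0].tokens
        ]

    def test_simultaneous_application_uses_pre_pass_context(self):
        # both positions 1 and 2 see pre-pass prev=PF only at position 1
        tagged = _with_preds([(["a", "b", "c"], ["O", "O", "O"], ["PF", "PF", "PF"])])
        rule = Rule((("prev_label", "PF"),), "PF", "O")
        out = apply_rules([rule], tagged)
        # position 2's pre-pass prev is PF, so it also rewrites; position 0 keeps PF
        assert [t.pred_label for t in out.sentences[0].tokens] == ["PF", "O", "O"]


class TestRuleSerialization:
    def test_parse_serialize_identity(self):
        rule = Rule(
            (("prev_label", "PF"), ("cur_word", "IL-2")), "O", "IF",
            polarity=1, score=7,
        )
        line = serialize_rule(rule)
        back = parse_rule(line)
        assert back == rule and back.polarity == 1 and back.score == 7
        assert serialize_rule(back) == line

    def test_rule_list_round_trip(self):
        rules = RuleList([
            Rule((("cur_word", "a"),), "O", "PF"),
            Rule((("left_word", "<s>"),), "PF", "O", polarity=0, score=3),
        ])
        assert rules_to_text(rules_from_text(rules_to_text(rules))) == rules_to_text(rules)

    def test_rule_must_change_the_label(self):
        with pytest.raises(ValueError):
            Rule((("cur_word", "a"),), "O", "O")
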