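"""Error-driven learning of an ordered correction-rule list.

Tags a synthetic corpus with the lexicon argmax, learns transformation rules
against the gold labels, and shows how the training error falls as each
accepted rule is applied.
"""

from bioqner import corpus_io, features, rules
from bioqner.synthetic import SynthConfig, generate

train, _ = generate(SynthConfig(seed=0, n_sentences=200, label_noise_rate=0.0))
gold = corpus_io.iob_to_fpns(train)
lex = features.induce_lexicons(gold)

tagged = rules.initial_tag(gold, lex)

def errors(c):
    return sum(
        t.pred_label != g.tokens[j].gold_label
        for s, g in zip(c.sentences, gold.sentences)
        for j, t in enumerate(s.tokens)
    )

print(f"initial tagging errors: {errors(tagged)} of {gold.n_tokens()} tokens")
learned = rules.learn_rules(tagged, gold, lex, threshold=2)
print(f"accepted rules: {len(learned)}")
for rule in list(learned)[:5]:
    print("  ", rules.serialize_rule(rule))
# Each line is: old-label, new-label, polarity (0 positive / 1 negative /
# 2 neuter, from the information value of the rule's lexical anchor), the
# net number of training errors the rule repaired, and its context condition.

current = tagged
for i, rule in enumerate(learned, start=1):
    current = rules.apply_rules([rule], current)
print(f"errors after all rules: {errors(current)}")
# The error count decreases strictly with every accepted rule; the loop
# stops when no candidate repairs at least `threshold` net errors.
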