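# bioqner

Recognition of *unregistered* (out-of-vocabulary) biomedical terms in
tokenized text: gene, protein, DNA, RNA and cell-line/cell-type mentions
that no dictionary covers.  Such mentions are typically multiword phrases
built from characteristic prefix and suffix feature words with connectives
and modifier nouns in between, and their boundaries depend on context —
which makes recognising them a sequential decision problem rather than a
lookup.

The package is aimed at text-mining practitioners and at anyone studying
reinforcement-learning formulations of sequence labeling.  It provides a
library API, narrative scripts under `examples/`, and a thin `bioqner`
command-line tool.

## The method

Tagging is cast as a finite Markov decision process ⟨X, U, R⟩ over the
seven-state **FPNS** decomposition of a mention and its context — prefix
feature word (PF=0), intermediate feature word (IF=1), suffix feature word
(SF=2), conjunctive word (J=3), left/right boundary word (LB=4, RB=5) and
other word (O=6).  Per-label **feature lexicons** are induced from annotated
data: a feature *f* (surface form, character affixes, orthographic flags,
neighbour words) is scored for label *t* by the F score of the one-feature
rule "tag *t* wherever *f* occurs",

    Quality(f, t) = F(precision(f → t), recall(f → t)),

and each token receives the argmax lexicon *vote*.  The tagger's state at
token *k* is the triple (vote for token *k*, previously assigned label, vote
for token *k+1*); its three actions mirror the rule polarities —
**0** accept the vote (positive), **1** reject entity membership (negative),
**2** keep the initial label (neuter).  A correct move is rewarded with the
Quality of the token's dominant feature; values are learned tabularly with

    Q(x_k, u_k) ← Q(x_k, u_k) + α [ r_{k+1} + γ max_u Q(x_{k+1}, u) − Q(x_k, u_k) ],

and decoding is greedy.  Knowledge transfers between corpora by **Q-value
reuse**: a frozen source table is consulted through an inter-task mapping
(f_x, f_u) and corrected by a target table,

    Q(x, u) = Q_source(f_x(x), f_u(u)) + Q_target(x, u).

A transformation-based learner then repairs systematic residual errors: it
generates candidate context rules at mis-tagged positions from templates,
accepts the rule with the highest net error reduction, applies it, and
iterates until no candidate clears an integer threshold — yielding an
ordered rule list with guaranteed termination.  Entity-level precision,
recall and F (exact boundaries and type) evaluate everything.

Because the public benchmark corpora cannot ship with the package, a
generator of synthetic annotated corpora with the same structure — typed
multiword entities with planted marker words, connectives, shared nouns and
optional annotation noise — makes every stage testable end to end.

## Worked example

```python
from bioqner import recognizer
from bioqner.experiments import experiment_learner
from bioqner.synthetic import SynthConfig, generate

train, test = generate(SynthConfig(seed=0, n_sentences=300))
bundle, curve = recognizer.train_recognizer(
    train, "qlearn", experiment_learner(seed=0, episodes=2000))
print(recognizer.evaluate(bundle, test).to_table())
```

prints

```
type       P       R       F       correct  predicted  gold
DNA        0.7200  0.9000  0.8000  18       25         20
RNA        0.7826  0.8182  0.8000  18       23         22
cell_line  0.7931  0.8519  0.8214  23       29         27
cell_type  0.8947  0.8500  0.8718  17       19         20
protein    1.0000  1.0000  1.0000  20       20         20
overall    0.8276  0.8807  0.8533  96       116        109
```

Each row gives exact-match precision, recall and F for one entity type on
the held-out 30 % split; `overall` is the micro average.  The same pipeline
trained on 500 clean sentences reaches overall F ≈ 0.90.  The scripts in
`examples/` walk through each capability — corpus conversion, lexicon
induction, Q-learning, rule learning, transfer, and the three-recogniser
benchmark — and the `bioqner synth / train / eval` commands expose the same
pipeline from the shell.

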