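# Methods

This note documents the models implemented in `bioqner`, the parameter
choices that matter, what the synthetic corpus generator does and does not
emulate, and the design decisions taken where the problem left the design
open.

## Label scheme and conversion

Entity mentions are handled in two schemes.  IOB2 (`B-type` / `I-type` /
`O`) is the interchange form and carries entity types.  Internally the
recogniser works over the seven-state FPNS decomposition — PF (0), IF (1),
SF (2), J (3), LB (4), RB (5), O (6) — in which the first token of a
mention is a prefix feature word, the last a suffix feature word, interior
tokens are conjunctive words (when the surface form is in a configurable
connective list, default `of, and, or, -, /, for, in`) or intermediate
feature words, and the tokens flanking a mention are left/right boundary
words.  Conversion from gold spans is positional and deterministic;
conflicts (adjacent mentions) resolve by the priority
PF > SF > IF > J > LB > RB > O, with LB beating RB when a token separates
two mentions.  FPNS is typeless and cannot represent the boundary between
abutting mentions: decoding takes maximal runs of entity-internal labels,
so abutting mentions merge.  The synthetic generator always separates
mentions by at least one context token, which makes the span → FPNS → span
round trip exact; entity types travel out-of-band as a span list.

## Features, quality, information value

Each token yields: its surface form, character prefixes and suffixes of
length 1–4, orthographic flags (contains digit / hyphen / uppercase,
emitted only when true), and the neighbouring surface words (with sentence
sentinels).  Emitting flags only when true is deliberate: a false-valued
flag is a near-universal feature whose association with the majority label
would swamp every vote.

`Quality(f, t)` is the corpus-level F score of the single-feature decision
rule "assign t wherever f occurs"; degenerate denominators give 0.  It is
used three ways: as the induction threshold (a feature enters label t's
lexicon when Quality ≥ `min_quality`, default 0.1, and the feature occurs
≥ `min_count` = 2 times), as the association weight behind lexicon votes
(argmax over labels of summed association; ties break in FPNS order), and
as the reward of a correct tagging move (the token's dominant-feature
quality, floored at 0.1 so featureless correct moves still pay).  Because
quality is computed from corpus counts only, induction is invariant to
sentence order and to duplicating the corpus.

The *information value* of a feature is the add-one-smoothed mutual
information (bits) between the feature's indicator and the gold label
variable, with marginals taken from the smoothed joint so the value is
never negative.  Features below the corpus mean are "low information
value"; the split only classifies correction rules (below).

A consequence of quality-as-F worth knowing: high-coverage labels (O) can
essentially never earn lexicon entries, because any single feature's recall
against them is tiny.  Votes therefore overcommit toward entity labels, and
it is the Q controller's job — via its negative action — to reject the
false ones from context.

## The tagging MDP

One sentence is one episode; one token is one time step; the state is the
triple (lexicon vote for the current token or NONE, previously assigned
FPNS label or START, lexicon vote for the next token or END).  Surface
words are deliberately absent from the key: the table stays small (a few
hundred entries) and, because the components are label classes rather than
vocabulary, the same key space is shared by related corpora — which is what
makes Q-value reuse work through an identity mapping.

Actions ground the three rule polarities: 0 accepts the lexicon argmax (O
without a vote), 1 rejects entity membership (emitting RB after an open
entity, LB before an upcoming entity vote, otherwise O), 2 keeps the
initial tagger's label.  With the default initial tagger (the lexicon
argmax itself) actions 0 and 2 coincide; action 2 becomes distinct when an
external initial labeling is supplied.  The update is standard off-policy
temporal-difference control with step size α = 0.1 and discount γ = 0.9;
rewards lie in [0, 1], so stored values stay within [0, 1/(1−γ)].
Decoding is greedy with the previously assigned label fed forward.

Exploration: the `LearnerConfig` defaults are ε = 0.1 with per-episode
decay 0.995.  The benchmark studies instead anneal from ε = 1.0 with decay
0.9995 (`experiments.experiment_learner`), for two measured reasons.
First, the accept/reject value gap in the critical states is small (a
quality-scaled reward against the 0.1 floor), so rejection actions must be
sampled many times before their values separate; a fast-decaying ε leaves
them permanently at zero and the greedy policy stuck on accept.  Second, the state
abstraction aliases some positions (a false entity vote directly after a
one-token mention looks like a mention interior), and under near-greedy
behaviour the visitation distribution concentrates and distorts the fixed
point; persistent exploration measurably improves the final policy for
cold and warm training alike.  At decay 0.9995 the schedule needs ~4000
episodes to anneal to ε ≈ 0.14, which is the budget the clean-data study
uses; the benchmark's data-poor target uses 1500 episodes deliberately
(below).

## Q-value reuse

The inter-task mapping maps each target label component to the source label
whose lexicon has maximal Jaccard overlap of feature sets (ties and the
all-disjoint case fall back to source alphabet order); with a shared FPNS
alphabet this is the identity.  The action map is the identity.  The
combined value is the exact unweighted sum Q_source∘mapping + Q_target.
During transfer training, action selection and the entire TD error use the
combined value while updates apply to the target table only, so the target
table learns the *correction* q* − Q_source and the source table is never
modified.  With a zero source table, transfer training is bit-identical to
plain training under the same seed.

Two properties follow and shape the experiments.  Transfer is a *speed*
mechanism: the warm curve starts near the source policy's quality.  And at
full target convergence it has no final-accuracy edge by construction,
since the correction can express q* − Q_source entirely; a final-F
advantage appears only when target training is data- or budget-limited.

## Transformation-based correction rules

Starting from the recogniser's own training output (lexicon argmax for the
baseline, greedy Q decode otherwise), the learner instantiates candidate
rules at every mis-tagged position from seven templates — current word,
current 3-character suffix, previous predicted label, left word, right
word, and the pairs (previous label, word) and (left word, word) — each
rewriting the predicted label to gold under that context condition.  A
rule's score is the net training-error change under simultaneous
application (conditions evaluated against pre-pass labels, all matches
rewritten at once, so scoring and application agree).  The greedy loop
accepts the best rule (ties: lexicographically smallest serialization),
applies it, and stops when the best score falls below the threshold
(default 2 net corrections; integer scores ≥ 1 guarantee strictly
decreasing error and termination within the initial error count).  Rule
polarity — positive / negative / neuter, codes 0/1/2 — is assigned from
the information value of the rule's lexical anchor (low-information
anchors give positive rules, high-information negative, anchorless rules
neuter) and is descriptive metadata only.

The error-count objective was chosen over an F-delta objective for its
integrality, which is what makes the termination argument exact.

## Evaluation

Entity-level precision, recall and F with exact boundary and exact type
matching; degenerate denominators map to 0.  Per-type rows plus a
micro-averaged overall row whose counts are the sums of the per-type
counts.  Span typing (the FPNS layer is typeless) assigns each decoded span
the entity type with maximal summed association over the span tokens'
features, using per-type lexicons induced from the IOB2 training corpus;
ties break alphabetically.

## The synthetic corpus generator

Sentences mix a context vocabulary (default 150 random lowercase words)
with planted entities: each mention of type T opens with one of T's three
prefix marker words and, when longer than one token, closes with one of
T's three suffix markers; interiors draw connectives (rate 0.3) or nouns
from a shared pool of eight.  Marker usage is round-robin so every marker
stays in play.  Mention lengths follow a categorical distribution over
{1, 2, 3, 4} (default 0.25/0.40/0.25/0.10), sentences carry 0–2 mentions
(0.15/0.55/0.30), and the 70/30 train/test split is by sentence.  All
draws derive from the single seed.

Three difficulties are planted deliberately, because they are what the
method's components exist to solve:

* **Type ambiguity** — pairs of types share their first *prefix* marker,
  so one-token mentions of those types cannot be typed from the marker
  alone.  Sharing is restricted to prefixes (real prefix feature words
  recur across categories; suffix heads tend to indicate the category):
  sharing suffixes as well would make both markers of many mentions
  uninformative and put a structural ceiling on typed F.
* **Entity-membership ambiguity** — half the noun pool doubles as context
  vocabulary, and connectives also appear as plain context (rate 0.1), so
  those tokens' votes are wrong outside mentions and only context can
  reject them.
* **Annotation noise** — with probability `label_noise_rate` a gold span is
  dropped or shifted by one token.  Noise applies to the *training* split
  only; test references stay clean so that measured F reflects recognition
  quality rather than corrupted references.

Marker words and the dedicated (non-shared) nouns are acronym-with-digit
tokens (e.g. `QZV2`), the morphology real biomedical feature words tend to
have.  This keeps their character affixes disjoint from the lowercase
context vocabulary; with uniformly random lowercase words everywhere, 1–2
character affix collisions flood the lexicons with weak false entity
predictors that no sequential context can undo (there is no O counterweight
— see above), which is a generator artefact rather than a property of the
domain.

What the generator does **not** emulate: real lexical diversity and Zipfian
frequencies, nested or discontinuous mentions, tokenization noise,
morphology beyond the planted shapes, and any semantic relation between
context and entity type.  Passing results therefore show that each
component does its job under the structural assumptions the method makes —
not that the pipeline reaches comparable scores on curated corpora.

## Study conditions

* **Clean-data recovery** (`experiments.clean_recovery`): seed-fixed task,
  500 training sentences, no noise.  Lexicon induction recovers 100 % of
  planted markers; the full Q pipeline reaches entity-level F ≈ 0.90 at
  seed 0 (seed spread roughly 0.87–0.91).
* **Three-recogniser benchmark** (`experiments.benchmark`): rich source
  (500 clean sentences, 2000 episodes) and data-poor target (200 training
  sentences, 1500 episodes) with half the marker words renamed.  Because
  single-run mode differences are a few F points — the same order as
  training-seed noise — the benchmark is a panel: five task pairs, two
  training repetitions per stochastic recogniser, per-mode mean F.  Under
  these conditions the means order baseline < Q-learning < Q-learning with
  transfer (at seed 0: 0.75 / 0.79 / 0.82).
* **Transfer speed-up** (`experiments.transfer_comparison`): ten paired
  tasks; cold vs warm learning curves with held-out *untyped* span F (the
  Q layer's own quantity; typing and rules are downstream) measured every
  50 episodes, episode 0 included.  Warm starts near the source policy
  (span F ≈ 0.74–0.88 at episode 0 vs ≈ 0.34–0.55 cold) and dominates the
  area under the curve in every pair; runs that never reach span F 0.8
  within the budget score as twice the budget.

## Numerical and degenerate-input choices

Greedy ties break to the lowest action code; vote ties to the earliest
FPNS label; span-type ties alphabetically; rule-score ties to the smallest
serialized rule.  Q tables, lexicons, mappings and rule lists serialize to
plain text with `repr`-round-trip floats, so persistence is bit-exact.
Empty corpora, unknown labels, misaligned corpora, malformed CoNLL lines
and scheme mixtures raise typed errors early.  `LearnerConfig` accepts
α = 0 (freezes the table) as a degenerate but well-defined configuration.

## Known limitations

The FPNS scheme cannot separate abutting mentions.  The state abstraction
aliases false votes adjacent to short mentions with true mention interiors;
this bounds the decoder below perfection on ambiguous data regardless of
training budget.  Typing one-token mentions whose (shared) prefix marker is
ambiguous is information-theoretically a coin flip in the generator's
design.  Tabular learning requires the small shared state space the
abstraction provides; richer keys would need function approximation, which
is out of scope.
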