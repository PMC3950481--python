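"""Reading annotated corpora and converting between IOB2 and FPNS labels.

Builds a two-sentence corpus in the two-column CoNLL dialect, converts the
span annotation to the seven-state FPNS scheme (prefix/intermediate/suffix
feature word, conjunctive word, left/right boundary, other), and decodes the
FPNS labels back into entity spans.
"""

from bioqner import corpus_io

TEXT = (
    "the\tO\n"
    "IL-2\tB-protein\n"
    "receptor\tI-protein\n"
    "binds\tO\n"
    "\n"
    "AKT1\tB-DNA\n"
    "of\tI-DNA\n"
    "mouse\tI-DNA\n"
    "\n"
)

corpus = corpus_io.read_conll(TEXT)
print(f"{len(corpus.sentences)} sentences, scheme {corpus.label_scheme}, "
      f"types {sorted(corpus.entity_types)}")

fpns = corpus_io.iob_to_fpns(corpus)
for sent in fpns.sentences:
    print("  ", list(zip(sent.texts(), sent.gold_labels())))
# The first token of each entity becomes PF, the last SF, connectives inside
# become J; the tokens flanking an entity become LB and RB.

for i, sent in enumerate(fpns.sentences):
    spans = corpus_io.fpns_to_spans(sent.gold_labels())
    print(f"sentence {i}: decoded entity spans {spans}")
# Maximal runs of entity-internal labels decode back to the annotated spans;
# the typed span list on fpns.spans keeps the conversion invertible.
print("typed spans:", fpns.spans)
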