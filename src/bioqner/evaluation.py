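"""Entity-level precision, recall and F with exact span and type matching.

A predicted span counts as correct only when its start, end and entity type
all equal a gold span's; partial overlap earns no credit.  Degenerate
denominators map to 0 by convention.  The overall row is the micro average:
its counts are the sums of the per-type counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_io import CorpusError, EntitySpan, TaggedCorpus, iob_spans


@dataclass(frozen=True)
class MatchCounts:
    correctly_identified: int
    total_identified: int
    total_gold: int

    def __post_init__(self) -> None:
        if min(self.correctly_identified, self.total_identified, self.total_gold) < 0:
            raise ValueError("counts must be non-negative")
        if self.correctly_identified > min(self.total_identified, self.total_gold):
            raise ValueError("correct count exceeds a denominator")


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f: float
    counts: MatchCounts


@dataclass
class MetricReport:
    per_type: dict[str, Metrics]
    overall: Metrics

    def to_table(self) -> str:
        rows = [("type", "P", "R", "F", "correct", "predicted", "gold")]
        for t in sorted(self.per_type):
            m = self.per_type[t]
            rows.append(
                (t, f"{m.precision:.4f}", f"{m.recall:.4f}", f"{m.f:.4f}",
                 str(m.counts.correctly_identified), str(m.counts.total_identified),
                 str(m.counts.total_gold))
            )
        m = self.overall
        rows.append(
            ("overall", f"{m.precision:.4f}", f"{m.recall:.4f}", f"{m.f:.4f}",
             str(m.counts.correctly_identified), str(m.counts.total_identified),
             str(m.counts.total_gold))
        )
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
        )

    def to_tsv(self) -> str:
        lines = ["type\tprecision\trecall\tf\tcorrect\tpredicted\tgold"]
        for t in sorted(self.per_type) + ["overall"]:
            m = self.overall if t == "overall" else self.per_type[t]
            lines.append(
                f"{t}\t{m.precision!r}\t{m.recall!r}\t{m.f!r}"
                f"\t{m.counts.correctly_identified}\t{m.counts.total_identified}"
                f"\t{m.counts.total_gold}"
            )
        return "\n".join(lines) + "\n"


def _check_no_overlap(spans: Iterable[EntitySpan]) -> None:
    by_sent: dict[int, list[EntitySpan]] = {}
    for sp in spans:
        by_sent.setdefault(sp.sentence_index, []).append(sp)
    for i, group in by_sent.items():
        group = sorted(group, key=lambda s: (s.start, s.end))
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise CorpusError(f"overlapping predicted spans in sentence {i}: {a} / {b}")


def count_matches(
    pred_spans: Sequence[EntitySpan], gold_spans: Sequence[EntitySpan]
) -> MatchCounts:
    """Exact (sentence, start, end, type) matching; each gold matches at most one prediction."""
    _check_no_overlap(pred_spans)
    gold_set = set(gold_spans)
    correct = sum(1 for sp in set(pred_spans) if sp in gold_set)
    return MatchCounts(correct, len(pred_spans), len(gold_spans))


def precision_recall_f(c: MatchCounts) -> tuple[float, float, float]:
    """P, R and their harmonic mean; degenerate denominators give 0."""
    p = c.correctly_identified / c.total_identified if c.total_identified else 0.0
    r = c.correctly_identified / c.total_gold if c.total_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _metrics(c: MatchCounts) -> Metrics:
    p, r, f = precision_recall_f(c)
    return Metrics(p, r, f, c)


def report(pred_corpus: TaggedCorpus, gold_corpus: TaggedCorpus) -> MetricReport:
    """Per-type and micro-averaged metrics for two IOB2 corpora over the same tokens."""
    if len(pred_corpus.sentences) != len(gold_corpus.sentences):
        raise CorpusError("corpora have different sentence counts")
    for i, (a, b) in enumerate(zip(pred_corpus.sentences, gold_corpus.sentences)):
        ta, tb = a.texts(), b.texts()
        if ta != tb:
            j = next(k for k in range(min(len(ta), len(tb)) + 1)
                     if k >= len(ta) or k >= len(tb) or ta[k] != tb[k])
            raise CorpusError(f"tokenization mismatch at sentence {i}, token {j}")
    pred = iob_spans(pred_corpus)
    gold = iob_spans(gold_corpus)
    types = sorted({sp.entity_type for sp in pred} | {sp.entity_type for sp in gold})
    per_type: dict[str, Metrics] = {}
    tot_c = tot_p = tot_g = 0
    for t in types:
        c = count_matches(
            [sp for sp in pred if sp.entity_type == t],
            [sp for sp in gold if sp.entity_type == t],
        )
        per_type[t] = _metrics(c)
        tot_c += c.correctly_identified
        tot_p += c.total_identified
        tot_g += c.total_gold
    overall = _metrics(MatchCounts(tot_c, tot_p, tot_g))
    return MetricReport(per_type, overall)
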