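"""TREC-style retrieval metrics over graded relevance judgments.

Implements P@N, nDCG@N, MAP and Bpref against qrels graded {0, 1, 2}.
Rankings are evaluated in list order.  Conventions follow trec_eval, the
standard tooling for these metrics:

* P@N and MAP binarize relevance at grade ≥ 1; P@N divides by N even when
  fewer documents were retrieved.
* DCG uses linear gain with the classic discount — the grade at rank 1
  undiscounted, rank i ≥ 2 discounted by log2(i); nDCG divides by the
  ideal DCG over the topic's judged grades (topics with IDCG 0 score 0).
* Bpref counts, for each relevant retrieved document r, the judged
  non-relevant documents ranked above it, capped at and divided by
  min(R, N) where R is the number of judged relevant and N the number of
  judged non-relevant documents; unjudged documents are invisible.  The
  textbook form that divides by R without capping can go negative when
  judged non-relevant outnumber relevant; it is available via
  ``literal=True`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .corpus import Qrels, RankedList

__all__ = [
    "MetricReport",
    "precision_at",
    "ndcg_at",
    "average_precision",
    "mean_average_precision",
    "bpref",
    "evaluate_run",
]


def _grades_in_order(ranked: RankedList, qrels: Qrels) -> list[int]:
    """Judged grade per retrieved doc, unjudged treated as grade 0."""
    return [
        qrels.grade(ranked.topic_id, d) or 0 for d in ranked.doc_ids()
    ]


def precision_at(ranked: RankedList, qrels: Qrels, n: int) -> float:
    """Fraction of the top-N positions holding a relevant (grade ≥ 1) doc."""
    if n < 1:
        raise ValueError("N must be >= 1")
    grades = _grades_in_order(ranked, qrels)[:n]
    return sum(1 for g in grades if g >= 1) / n


def ndcg_at(ranked: RankedList, qrels: Qrels, n: int) -> float:
    """Normalized discounted cumulative gain over the top N."""
    if n < 1:
        raise ValueError("N must be >= 1")
    grades = _grades_in_order(ranked, qrels)[:n]
    dcg = _dcg(grades)
    ideal = sorted(
        qrels.judged_docs(ranked.topic_id).values(), reverse=True
    )[:n]
    idcg = _dcg(ideal)
    return dcg / idcg if idcg > 0 else 0.0


def _dcg(grades: Sequence[int]) -> float:
    return sum(
        g if i == 1 else g / math.log2(i)
        for i, g in enumerate(grades, start=1)
    )


def average_precision(ranked: RankedList, qrels: Qrels) -> float:
    """Discrete AP: mean precision at each relevant retrieved rank,
    divided by the total number of judged relevant documents."""
    judged = qrels.judged_docs(ranked.topic_id)
    n_rel = sum(1 for g in judged.values() if g >= 1)
    if n_rel == 0:
        return 0.0
    hits = 0
    total = 0.0
    for rank, doc_id in enumerate(ranked.doc_ids(), start=1):
        if judged.get(doc_id, 0) >= 1:
            hits += 1
            total += hits / rank
    return total / n_rel


def mean_average_precision(
    run: Sequence[RankedList], qrels: Qrels
) -> float:
    """AP averaged over topics; topics with no judged relevant count as 0."""
    if not run:
        raise ValueError("empty run")
    return sum(average_precision(r, qrels) for r in run) / len(run)


def bpref(ranked: RankedList, qrels: Qrels, literal: bool = False) -> float:
    """Binary preference: how rarely judged non-relevant docs outrank
    relevant ones.  ``literal=True`` divides by R without capping."""
    judged = qrels.judged_docs(ranked.topic_id)
    n_rel = sum(1 for g in judged.values() if g >= 1)
    n_nonrel = sum(1 for g in judged.values() if g == 0)
    if n_rel == 0:
        return 0.0
    denom = n_rel if literal else min(n_rel, n_nonrel)
    nonrel_above = 0
    total = 0.0
    for doc_id in ranked.doc_ids():
        grade = judged.get(doc_id)
        if grade is None:
            continue
        if grade >= 1:
            if denom > 0:
                capped = nonrel_above if literal else min(nonrel_above, denom)
                total += 1.0 - capped / denom
            else:
                # no judged non-relevant at all: nothing can outrank r
                total += 1.0
        else:
            nonrel_above += 1
    return total / n_rel


@dataclass
class MetricReport:
    """Per-topic and mean values for the standard metric panel."""

    per_topic: dict[str, dict[str, float]]
    means: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        names = next(iter(self.per_topic.values())).keys()
        self.means = {
            name: sum(t[name] for t in self.per_topic.values())
            / len(self.per_topic)
            for name in names
        }

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.per_topic).T.sort_index()
        frame.loc["mean"] = pd.Series(self.means)
        return frame


def evaluate_run(run: Sequence[RankedList], qrels: Qrels) -> MetricReport:
    """Compute P@5, P@10, nDCG@10, MAP and Bpref for every topic."""
    if not run:
        raise ValueError("empty run")
    per_topic = {
        r.topic_id: {
            "P@5": precision_at(r, qrels, 5),
            "P@10": precision_at(r, qrels, 10),
            "nDCG@10": ndcg_at(r, qrels, 10),
            "AP": average_precision(r, qrels),
            "Bpref": bpref(r, qrels),
        }
        for r in run
    }
    return MetricReport(per_topic=per_topic)
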