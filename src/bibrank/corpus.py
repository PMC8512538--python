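"""Corpus domain types and readers/writers.

A corpus is a collection of :class:`Document` records (one scientific paper
each: title, abstract, optional full-text paragraphs, and the citation keys of
its bibliography), serialized as JSON Lines.  Queries are :class:`Topic`
records; relevance judgments are :class:`Qrels` in the 4-column TREC layout;
ranked output is written in the 6-column TREC run format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Document",
    "Topic",
    "Qrels",
    "RankedList",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "read_topics",
    "write_topics",
    "read_qrels",
    "write_qrels",
    "read_run",
    "write_run",
]

VALID_GRADES = frozenset({0, 1, 2})


class CorpusError(ValueError):
    """Raised for malformed or inconsistent corpus/qrels/run inputs."""


def _normalize_key(key: str) -> str:
    return key.strip().casefold()


@dataclass(frozen=True)
class Document:
    """One corpus record: a paper with metadata, body, and bibliography.

    ``references`` holds opaque citation keys shared across citing documents;
    they are normalized (trimmed, case-folded) and de-duplicated on
    construction so that exact string equality identifies a cited work.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    paragraphs: tuple[str, ...] = ()
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        object.__setattr__(self, "paragraphs", tuple(self.paragraphs))
        seen: dict[str, None] = {}
        for ref in self.references:
            key = _normalize_key(ref)
            if key and key not in seen:
                seen[key] = None
        object.__setattr__(self, "references", tuple(seen))

    @property
    def text(self) -> str:
        """Title and abstract joined — the indexed representation."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class Topic:
    """A query topic with three verbosity levels (name/question/narrative)."""

    topic_id: str
    name: str = ""
    question: str = ""
    narrative: str = ""

    def __post_init__(self) -> None:
        if not (self.name or self.question or self.narrative):
            raise CorpusError(
                f"topic {self.topic_id!r}: all three text fields are empty"
            )

    def query_text(self, field_name: str = "question") -> str:
        """Return the query string for one verbosity level.

        Defaults to the human-formulated question; falls back to whichever
        field is non-empty when the requested one is blank.
        """
        if field_name not in ("name", "question", "narrative"):
            raise ValueError(f"unknown topic field {field_name!r}")
        value = getattr(self, field_name)
        if value:
            return value
        return self.name or self.question or self.narrative


class Qrels:
    """Graded relevance judgments: (topic_id, doc_id) -> grade in {0, 1, 2}.

    Grade 0 is judged non-relevant, 1 partially relevant, 2 relevant;
    pairs absent from the mapping are unjudged.
    """

    def __init__(self, judgments: Mapping[tuple[str, str], int] | None = None):
        self._judgments: dict[tuple[str, str], int] = {}
        if judgments:
            for (topic_id, doc_id), grade in judgments.items():
                self.add(topic_id, doc_id, grade)

    def add(self, topic_id: str, doc_id: str, grade: int) -> None:
        if grade not in VALID_GRADES:
            raise CorpusError(
                f"relevance grade must be in {{0,1,2}}, got {grade} "
                f"for ({topic_id}, {doc_id})"
            )
        self._judgments[(topic_id, doc_id)] = grade

    def grade(self, topic_id: str, doc_id: str) -> int | None:
        """Judged grade, or None when the pair is unjudged."""
        return self._judgments.get((topic_id, doc_id))

    def topic_ids(self) -> list[str]:
        return sorted({t for t, _ in self._judgments})

    def judged_docs(self, topic_id: str) -> dict[str, int]:
        """doc_id -> grade for every judged doc of one topic."""
        return {
            d: g for (t, d), g in self._judgments.items() if t == topic_id
        }

    def __len__(self) -> int:
        return len(self._judgments)

    def __iter__(self):
        return iter(self._judgments.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Qrels):
            return NotImplemented
        return self._judgments == other._judgments


@dataclass
class RankedList:
    """Per-topic ordered retrieval output: (doc_id, score) pairs.

    Scores are non-increasing down the list and doc_ids are unique.
    """

    topic_id: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [(d, float(s)) for d, s in self.entries]
        ids = [d for d, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise CorpusError(
                f"topic {self.topic_id}: duplicate doc_ids in ranked list"
            )
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise CorpusError(
                f"topic {self.topic_id}: scores must be non-increasing"
            )

    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# JSON Lines corpus / topics I/O


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSON Lines corpus; one document per line.

    Duplicate ``doc_id`` values and malformed lines are rejected with the
    offending id / line number named in the error.  Missing optional fields
    default to empty.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON: {exc}") from exc
            if "doc_id" not in record:
                raise CorpusError(f"line {lineno}: missing doc_id")
            doc = Document(
                doc_id=str(record["doc_id"]),
                title=record.get("title", "") or "",
                abstract=record.get("abstract", "") or "",
                paragraphs=tuple(record.get("paragraphs") or ()),
                references=tuple(record.get("references") or ()),
            )
            if doc.doc_id in seen:
                raise CorpusError(
                    f"line {lineno}: duplicate doc_id {doc.doc_id!r}"
                )
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "paragraphs": list(doc.paragraphs),
                        "references": list(doc.references),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_topics(path: str | Path) -> list[Topic]:
    topics: list[Topic] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON: {exc}") from exc
            topics.append(
                Topic(
                    topic_id=str(record["topic_id"]),
                    name=record.get("name", "") or "",
                    question=record.get("question", "") or "",
                    narrative=record.get("narrative", "") or "",
                )
            )
    return topics


def write_topics(topics: Iterable[Topic], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in topics:
            fh.write(
                json.dumps(
                    {
                        "topic_id": t.topic_id,
                        "name": t.name,
                        "question": t.question,
                        "narrative": t.narrative,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TREC qrels / run I/O


def read_qrels(path: str | Path) -> Qrels:
    """Read 4-column TREC qrels: topic, iteration, doc, grade."""
    qrels = Qrels()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise CorpusError(
                    f"line {lineno}: expected 4 columns, got {len(parts)}"
                )
            topic_id, _iteration, doc_id, grade_str = parts
            try:
                grade = int(grade_str)
            except ValueError as exc:
                raise CorpusError(
                    f"line {lineno}: non-integer grade {grade_str!r}"
                ) from exc
            qrels.add(topic_id, doc_id, grade)
    return qrels


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (topic_id, doc_id), grade in sorted(qrels):
            fh.write(f"{topic_id} 0 {doc_id} {grade}\n")


def write_run(
    lists: Sequence[RankedList], tag: str, path: str | Path
) -> None:
    """Write ranked lists in the 6-column TREC run format.

    One line per entry: ``topic Q0 doc rank score tag`` with 1-based ranks
    following list order.
    """
    if not lists:
        raise CorpusError("cannot write an empty run")
    with open(path, "w", encoding="utf-8") as fh:
        for ranked in lists:
            for rank, (doc_id, score) in enumerate(ranked.entries, start=1):
                fh.write(
                    f"{ranked.topic_id} Q0 {doc_id} {rank} {score:.6f} {tag}\n"
                )


def read_run(path: str | Path) -> list[RankedList]:
    """Read a TREC run file back into per-topic RankedLists (file order)."""
    by_topic: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise CorpusError(
                    f"line {lineno}: expected 6 columns, got {len(parts)}"
                )
            topic_id, _q0, doc_id, _rank, score, _tag = parts
            if topic_id not in by_topic:
                by_topic[topic_id] = []
                order.append(topic_id)
            by_topic[topic_id].append((doc_id, float(score)))
    return [RankedList(topic_id=t, entries=by_topic[t]) for t in order]
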