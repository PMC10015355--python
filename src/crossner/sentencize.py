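"""Sentence segmentation with annotation carry-over.

Documents are partitioned into sentence spans that tile the full text, so
concatenating the sentence texts reconstructs the document exactly.
Annotations are re-based to sentence-relative offsets; a proposed boundary
that would cut through an annotation is dissolved by merging the two
sentences, so splitting never drops or truncates an annotation.

The default splitter is rule-based (sentence-final punctuation followed by
whitespace, plus newline breaks); any strategy returning covering boundary
offsets can be plugged in.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .standoff_io import Annotation, Document

logger = logging.getLogger(__name__)

_BOUNDARY = re.compile(r"[.!?]+[\"')\]]*\s+|\n+")


class SplitError(ValueError):
    """Splitter strategy returned boundaries that do not cover the text."""


@dataclass
class Sentence:
    """One sentence with sentence-relative annotations.

    ``char_offset_in_doc + relative offset`` recovers the document offset.
    """

    doc_id: str
    sent_index: int
    text: str
    char_offset_in_doc: int
    annotations: list[Annotation] = field(default_factory=list)


def rule_based_boundaries(text: str) -> list[int]:
    """Candidate sentence end offsets: after final punctuation + whitespace
    and after newline runs. Always includes ``len(text)``."""
    ends = sorted({m.end() for m in _BOUNDARY.finditer(text)} | {len(text)})
    return [e for e in ends if e > 0]


def split_document(doc: Document, splitter=rule_based_boundaries) -> list[Sentence]:
    """Split a document into sentences and localize its annotations.

    The splitter returns sentence-end offsets; spans between consecutive
    ends tile the text. Boundaries falling strictly inside an annotation are
    removed (merging the adjacent sentences) so every annotation lands whole
    in exactly one sentence.
    """
    if not doc.text:
        return []
    ends = sorted(set(splitter(doc.text)))
    if not ends or ends[-1] != len(doc.text):
        raise SplitError(
            f"{doc.doc_id}: splitter boundaries do not cover the text "
            f"(last end {ends[-1] if ends else None}, length {len(doc.text)})"
        )
    # dissolve boundaries that would cut an annotation in two
    kept = [
        e
        for e in ends
        if e == len(doc.text)
        or not any(a.start < e < a.end for a in doc.annotations)
    ]
    sentences: list[Sentence] = []
    start = 0
    for idx, end in enumerate(kept):
        sent_anns = [
            Annotation(a.start - start, a.end - start, a.label, a.surface)
            for a in doc.annotations
            if start <= a.start and a.end <= end
        ]
        sentences.append(
            Sentence(doc.doc_id, idx, doc.text[start:end], start, sent_anns)
        )
        start = end
    total = sum(len(s.annotations) for s in sentences)
    if total != len(doc.annotations):  # pragma: no cover - guarded by merge rule
        raise SplitError(
            f"{doc.doc_id}: annotation count changed during split "
            f"({len(doc.annotations)} -> {total})"
        )
    return sentences


def drop_unannotated(sentences: list[Sentence]) -> list[Sentence]:
    """Keep only sentences carrying at least one annotation (order preserved);
    the dropped count is logged."""
    kept = [s for s in sentences if s.annotations]
    dropped = len(sentences) - len(kept)
    if dropped:
        logger.info("dropped %d unannotated sentences of %d", dropped, len(sentences))
    return kept
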