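"""Corpus format I/O: brat/n2c2 standoff, CoNLL-IOB2 and JSONL span datasets.

Character offsets are 0-based half-open and count Unicode code points
everywhere. Standoff text-bound lines look like::

    T1<TAB>Drug 0 7<TAB>aspirin

Discontinuous spans (``start end;start end``) are split into contiguous
fragments, each inheriting the label. Relation (``R``) and attribute (``A``)
lines are ignored with a logged count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: Closed tag vocabulary of the medication-extraction annotation scheme.
LABELS = (
    "Drug",
    "Route",
    "Reason",
    "Strength",
    "Frequency",
    "Duration",
    "Form",
    "Dosage",
    "ADE",
)


class StandoffParseError(ValueError):
    """A malformed standoff / CoNLL / JSONL record; message names the line."""


class SpanValidationError(ValueError):
    """A span that does not fit its owning text."""


@dataclass(frozen=True)
class Annotation:
    """A labelled, contiguous character span.

    ``start``/``end`` are 0-based, half-open code-point offsets into the
    owning text; ``surface`` is the text slice at ``[start, end)``.
    """

    start: int
    end: int
    label: str
    surface: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SpanValidationError(
                f"invalid span ({self.start}, {self.end}): need 0 <= start < end"
            )

    def validate(self, text: str) -> None:
        if self.end > len(text):
            raise SpanValidationError(
                f"span ({self.start}, {self.end}) exceeds text of length {len(text)}"
            )
        if self.label not in LABELS:
            raise SpanValidationError(f"unknown label {self.label!r}")
        slice_ = text[self.start : self.end]
        if self.surface and self.surface != slice_:
            raise SpanValidationError(
                f"surface {self.surface!r} != text slice {slice_!r} at "
                f"({self.start}, {self.end})"
            )


@dataclass
class Document:
    """Full document text with its annotations, sorted by start offset."""

    doc_id: str
    text: str
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.annotations = sorted(self.annotations, key=lambda a: (a.start, a.end))
        for ann in self.annotations:
            if ann.end > len(self.text):
                raise SpanValidationError(
                    f"{self.doc_id}: annotation ({ann.start}, {ann.end}) exceeds "
                    f"text length {len(self.text)}"
                )


def read_standoff(txt_content: str, ann_content: str, doc_id: str = "doc") -> Document:
    """Parse a brat/n2c2 ``.txt``/``.ann`` pair into a :class:`Document`.

    Each contiguous fragment of a (possibly discontinuous) T-line becomes one
    :class:`Annotation`. The surface string is recomputed from the text; a
    mismatch with the surface stored in the file is logged and the recomputed
    slice wins. R- and A-lines are skipped with a logged count.
    """
    annotations: list[Annotation] = []
    skipped = 0
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        if line[0] in ("R", "A", "#", "E", "M", "N"):
            skipped += 1
            continue
        if line[0] != "T":
            raise StandoffParseError(f"line {lineno}: unrecognized record {line!r}")
        parts = line.split("\t")
        if len(parts) < 2:
            raise StandoffParseError(f"line {lineno}: expected tab-separated fields")
        type_span = parts[1]
        file_surface = parts[2] if len(parts) > 2 else ""
        try:
            label, span_part = type_span.split(" ", 1)
        except ValueError:
            raise StandoffParseError(
                f"line {lineno}: cannot split label from spans in {type_span!r}"
            ) from None
        if label not in LABELS:
            raise StandoffParseError(f"line {lineno}: unknown label {label!r}")
        fragments = []
        for frag in span_part.split(";"):
            bits = frag.split()
            if len(bits) != 2:
                raise StandoffParseError(
                    f"line {lineno}: malformed span fragment {frag!r}"
                )
            try:
                start, end = int(bits[0]), int(bits[1])
            except ValueError:
                raise StandoffParseError(
                    f"line {lineno}: non-integer offsets in {frag!r}"
                ) from None
            if not (0 <= start < end <= len(txt_content)):
                raise SpanValidationError(
                    f"line {lineno}: span ({start}, {end}) outside text of "
                    f"length {len(txt_content)}"
                )
            fragments.append((start, end))
        recomputed = " ".join(txt_content[s:e] for s, e in fragments)
        if file_surface and file_surface != recomputed:
            logger.warning(
                "line %d: stored surface %r != text slice %r; using slice",
                lineno,
                file_surface,
                recomputed,
            )
        for start, end in fragments:
            annotations.append(
                Annotation(start, end, label, txt_content[start:end])
            )
    if skipped:
        logger.info("skipped %d non-T standoff lines", skipped)
    return Document(doc_id=doc_id, text=txt_content, annotations=annotations)


def write_standoff(doc: Document) -> tuple[str, str]:
    """Serialize a document back to a ``(.txt, .ann)`` content pair."""
    lines = [
        f"T{i}\t{a.label} {a.start} {a.end}\t{doc.text[a.start:a.end]}"
        for i, a in enumerate(doc.annotations, start=1)
    ]
    return doc.text, "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# IOB2 span <-> tag conversion (shared by CoNLL I/O, projection and the tagger)

def spans_to_iob(
    token_spans: list[tuple[int, int]], annotations: list[Annotation]
) -> list[str]:
    """Encode annotations as IOB2 tags over tokens given by character spans.

    Every annotation must start at a token start and end at a token end;
    otherwise the span crosses a token boundary and a
    :class:`SpanValidationError` is raised naming the span.
    """
    tags = ["O"] * len(token_spans)
    starts = {s: i for i, (s, _) in enumerate(token_spans)}
    ends = {e: i for i, (_, e) in enumerate(token_spans)}
    for ann in annotations:
        if ann.start not in starts or ann.end not in ends:
            raise SpanValidationError(
                f"annotation ({ann.start}, {ann.end}, {ann.label}) crosses a "
                f"token boundary"
            )
        first, last = starts[ann.start], ends[ann.end]
        tags[first] = f"B-{ann.label}"
        for k in range(first + 1, last + 1):
            tags[k] = f"I-{ann.label}"
    return tags


def iob_to_spans(
    token_spans: list[tuple[int, int]], tags: list[str], text: str = ""
) -> list[Annotation]:
    """Decode an IOB/IOB2 tag sequence back to character-span annotations.

    An I-tag opening a new entity (lenient IOB input) starts one.
    """
    spans: list[Annotation] = []
    open_start: int | None = None
    open_label: str | None = None

    def close(upto: int) -> None:
        nonlocal open_start, open_label
        if open_label is not None:
            end = token_spans[upto][1]
            surface = text[open_start:end] if text else ""
            spans.append(Annotation(open_start, end, open_label, surface))
        open_start, open_label = None, None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i - 1)
        elif tag.startswith("B-"):
            close(i - 1)
            open_start, open_label = token_spans[i][0], tag[2:]
        elif tag.startswith("I-"):
            if open_label != tag[2:]:
                close(i - 1)
                open_start, open_label = token_spans[i][0], tag[2:]
        else:
            raise StandoffParseError(f"bad IOB tag {tag!r} at token {i}")
    close(len(tags) - 1)
    return spans


# ---------------------------------------------------------------------------
# CoNLL two-column format

def write_conll(
    sentences: list[tuple[list[tuple[str, int, int]], list[Annotation]]]
) -> str:
    """Render sentences as two-column CoNLL: ``token<TAB>tag``, blank-line
    separated, IOB2 tags."""
    blocks = []
    for tokens, annotations in sentences:
        spans = [(s, e) for _, s, e in tokens]
        tags = spans_to_iob(spans, annotations)
        blocks.append(
            "".join(f"{tok}\t{tag}\n" for (tok, _, _), tag in zip(tokens, tags))
        )
    return "\n".join(blocks)


def read_conll(
    content: str,
) -> list[tuple[list[tuple[str, int, int]], list[Annotation]]]:
    """Parse two-column CoNLL into sentences of (tokens-with-offsets,
    annotations). Token offsets are reconstructed assuming single-space
    joining; round-trips :func:`write_conll` output."""
    sentences = []
    block: list[tuple[str, str]] = []

    def flush() -> None:
        if not block:
            return
        tokens: list[tuple[str, int, int]] = []
        pos = 0
        for tok, _ in block:
            tokens.append((tok, pos, pos + len(tok)))
            pos += len(tok) + 1
        spans = [(s, e) for _, s, e in tokens]
        text = " ".join(tok for tok, _ in block)
        anns = iob_to_spans(spans, [tag for _, tag in block], text)
        sentences.append((tokens, anns))
        block.clear()

    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise StandoffParseError(
                f"line {lineno}: expected 'token<TAB>tag', got {line!r}"
            )
        block.append((parts[0], parts[1]))
    flush()
    return sentences


# ---------------------------------------------------------------------------
# JSONL span datasets

def write_jsonl(documents: list[Document]) -> str:
    """One JSON record per line: ``{"doc_id", "text", "entities": [[s,e,label]]}``."""
    lines = []
    for doc in documents:
        record = {
            "doc_id": doc.doc_id,
            "text": doc.text,
            "entities": [[a.start, a.end, a.label] for a in doc.annotations],
        }
        lines.append(json.dumps(record, ensure_ascii=False))
    return "\n".join(lines) + ("\n" if lines else "")


def read_jsonl(content: str) -> list[Document]:
    """Parse a JSONL span dataset; rejects overlapping or out-of-range spans
    with the offending line and span in the message."""
    documents = []
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError as exc:
            raise StandoffParseError(f"line {lineno}: invalid JSON: {exc}") from None
        text = record["text"]
        entities = record.get("entities", [])
        anns = []
        for s, e, label in entities:
            if not (0 <= s < e <= len(text)):
                raise StandoffParseError(
                    f"line {lineno}: span ({s}, {e}) outside text of length "
                    f"{len(text)}"
                )
            anns.append(Annotation(s, e, label, text[s:e]))
        anns.sort(key=lambda a: (a.start, a.end))
        for prev, cur in zip(anns, anns[1:]):
            if cur.start < prev.end:
                raise StandoffParseError(
                    f"line {lineno}: overlapping spans ({prev.start}, {prev.end}) "
                    f"and ({cur.start}, {cur.end})"
                )
        documents.append(
            Document(record.get("doc_id", f"doc{lineno}"), text, anns)
        )
    return documents


def relabel(ann: Annotation, **changes) -> Annotation:
    """Return a copy of an annotation with fields replaced."""
    return replace(ann, **changes)
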