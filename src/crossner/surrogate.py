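"""De-identification mask detection and surrogate replacement.

Clinical corpora ship with privacy-sensitive tokens replaced by typed
placeholders (the default dialect is the MIMIC-style ``[**Type ...**]``).
To restore natural-looking text before translation, each placeholder is
swapped for a randomly sampled, type-compatible surrogate value, and every
annotation offset in the document is remapped through the resulting
:class:`OffsetMap`.

Replacement guarantees:

* non-mask text is character-for-character unchanged;
* annotations disjoint from all masks keep their exact surface string;
* annotations fully inside a mask are retargeted to the whole surrogate span;
* an annotation straddling a mask boundary is an error (no silent truncation);
* output is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .standoff_io import Annotation, Document

logger = logging.getLogger(__name__)

MASK_TYPES = ("name", "date", "year", "phone", "id_number", "address", "numeric", "other")

#: keyword (lowercase substring of the placeholder body) -> mask type.
#: Checked in order; first hit wins.
DEFAULT_TYPE_MAP: tuple[tuple[str, str], ...] = (
    ("first name", "name"),
    ("last name", "name"),
    ("name", "name"),
    ("doctor", "name"),
    ("date of birth", "date"),
    ("dob", "date"),
    ("date", "date"),
    ("year", "year"),
    ("phone", "phone"),
    ("telephone", "phone"),
    ("pager", "phone"),
    ("id number", "id_number"),
    ("identifier", "id_number"),
    ("medical record", "id_number"),
    ("mrn", "id_number"),
    ("address", "address"),
    ("hospital", "address"),
    ("location", "address"),
    ("numeric", "numeric"),
    ("number", "numeric"),
)


class MaskError(ValueError):
    """Unbalanced delimiters or an annotation straddling a mask boundary."""


@dataclass(frozen=True)
class Mask:
    """A typed placeholder occurrence: the span covers the delimiters too."""

    start: int
    end: int
    mask_type: str
    content: str = ""


@dataclass
class MaskPattern:
    """Placeholder dialect: delimiters plus the keyword -> type table."""

    open: str = "[**"
    close: str = "**]"
    type_map: tuple[tuple[str, str], ...] = DEFAULT_TYPE_MAP

    def classify(self, content: str) -> str:
        lowered = content.lower()
        for keyword, mask_type in self.type_map:
            if keyword in lowered:
                return mask_type
        return "other"


@dataclass
class OffsetMap:
    """Piecewise-linear old->new offset mapping built during replacement.

    ``anchors`` holds (old, new) pairs at every segment boundary; offsets
    inside an unreplaced segment shift by the segment's delta. Mapping is
    strictly order-preserving for offsets outside replaced regions.
    """

    anchors: list[tuple[int, int]] = field(default_factory=list)
    replaced: list[tuple[int, int, int, int]] = field(default_factory=list)

    def map(self, old: int) -> int:
        for old_s, old_e, new_s, new_e in self.replaced:
            if old_s < old < old_e:
                raise MaskError(f"offset {old} falls inside replaced region "
                                f"({old_s}, {old_e})")
            if old == old_e:
                return new_e
        delta = 0
        for a_old, a_new in self.anchors:
            if a_old <= old:
                delta = a_new - a_old
            else:
                break
        return old + delta


def detect_masks(text: str, pattern: MaskPattern | None = None) -> list[Mask]:
    """Find all typed placeholders in document order.

    Unknown keywords fall back to type ``other``. Unbalanced delimiters raise
    :class:`MaskError` with the character position of the offender.
    """
    pattern = pattern or MaskPattern()
    masks: list[Mask] = []
    pos = 0
    while True:
        start = text.find(pattern.open, pos)
        stray_close = text.find(pattern.close, pos)
        if start == -1:
            if stray_close != -1 and pattern.open != pattern.close:
                raise MaskError(
                    f"closing delimiter without opener at position {stray_close}"
                )
            break
        if stray_close != -1 and stray_close < start and pattern.open != pattern.close:
            raise MaskError(
                f"closing delimiter without opener at position {stray_close}"
            )
        body_start = start + len(pattern.open)
        end_open = text.find(pattern.close, body_start)
        if end_open == -1:
            raise MaskError(f"unclosed mask delimiter at position {start}")
        content = text[body_start:end_open]
        end = end_open + len(pattern.close)
        masks.append(Mask(start, end, pattern.classify(content), content))
        pos = end
    return masks


# ---------------------------------------------------------------------------
# Built-in surrogate samplers.  Small bundled word lists keep the package
# dependency-free; realism at the level of "plausible token of the right
# type", not locale fidelity.

_FIRST_NAMES = (
    "James", "Mary", "Robert", "Patricia", "John", "Jennifer", "Michael",
    "Linda", "David", "Elizabeth", "William", "Barbara", "Richard", "Susan",
    "Joseph", "Jessica", "Thomas", "Sarah", "Charles", "Karen", "Anna",
    "Peter", "Laura", "Kevin", "Nancy", "Brian", "Margaret", "Omar", "Chen",
    "Fatima",
)
_LAST_NAMES = (
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Nguyen", "Kim", "Patel", "Schmidt", "Weber", "Fischer", "Meyer",
    "Wagner", "Becker",
)
_STREETS = (
    "Oak Street", "Maple Avenue", "Cedar Lane", "Elm Drive", "Pine Road",
    "Birch Court", "Willow Way", "Chestnut Boulevard",
)
_CITIES = (
    "Springfield", "Riverside", "Fairview", "Georgetown", "Clinton",
    "Greenville", "Bristol", "Salem",
)

DEFAULT_DATE_FORMATS = ("%m/%d/%Y", "%Y-%m-%d", "%B %d, %Y", "%m/%d/%y")


def builtin_samplers(
    seed: int, date_formats: tuple[str, ...] = DEFAULT_DATE_FORMATS
) -> dict:
    """Seeded surrogate generators, one per mask type.

    Each sampler is a callable ``(mask_content: str) -> str``; the content of
    the original placeholder is available so e.g. the numeric sampler can
    match the digit width it replaces. Streams are reproducible per seed.
    """
    import datetime

    rng = random.Random(seed)

    def name(_: str) -> str:
        return f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}"

    def date(_: str) -> str:
        day = datetime.date(1950, 1, 1) + datetime.timedelta(
            days=rng.randrange(0, 27000)
        )
        return day.strftime(rng.choice(date_formats))

    def year(_: str) -> str:
        return str(rng.randrange(1950, 2024))

    def phone(_: str) -> str:
        return f"{rng.randrange(100, 999)}-{rng.randrange(100, 999)}-{rng.randrange(1000, 9999)}"

    def id_number(_: str) -> str:
        return "".join(rng.choice("0123456789") for _ in range(7))

    def address(_: str) -> str:
        return f"{rng.randrange(1, 999)} {rng.choice(_STREETS)}, {rng.choice(_CITIES)}"

    def numeric(content: str) -> str:
        width = sum(ch.isdigit() for ch in content) or rng.randrange(2, 5)
        first = rng.choice("123456789")
        rest = "".join(rng.choice("0123456789") for _ in range(width - 1))
        return first + rest

    def other(_: str) -> str:
        return "".join(
            rng.choice("abcdefghijklmnopqrstuvwxyz0123456789") for _ in range(6)
        )

    return {
        "name": name,
        "date": date,
        "year": year,
        "phone": phone,
        "id_number": id_number,
        "address": address,
        "numeric": numeric,
        "other": other,
    }


def replace_masks(
    doc: Document,
    masks: list[Mask],
    samplers: dict | None = None,
    seed: int = 0,
) -> tuple[Document, OffsetMap]:
    """Replace every mask with a sampled type-compatible surrogate and remap
    all annotation offsets.

    Annotations disjoint from masks keep their surface; annotations fully
    inside a mask are retargeted to the full surrogate span (the label still
    describes the surrogate). A straddling annotation raises
    :class:`MaskError` naming the document and span.
    """
    samplers = samplers if samplers is not None else builtin_samplers(seed)
    masks = sorted(masks, key=lambda m: m.start)
    for a, b in zip(masks, masks[1:]):
        if b.start < a.end:
            raise MaskError(f"{doc.doc_id}: overlapping masks at {a.start} and {b.start}")

    for ann in doc.annotations:
        for m in masks:
            inside = m.start <= ann.start and ann.end <= m.end
            disjoint = ann.end <= m.start or ann.start >= m.end
            if not (inside or disjoint):
                raise MaskError(
                    f"{doc.doc_id}: annotation ({ann.start}, {ann.end}, "
                    f"{ann.label}) straddles mask ({m.start}, {m.end})"
                )

    pieces: list[str] = []
    offset_map = OffsetMap(anchors=[(0, 0)])
    cursor = 0
    new_len = 0
    for m in masks:
        sampler = samplers.get(m.mask_type)
        if sampler is None:
            logger.warning(
                "%s: no sampler for mask type %r; using 'other'",
                doc.doc_id,
                m.mask_type,
            )
            sampler = samplers["other"]
        surrogate = sampler(m.content)
        pieces.append(doc.text[cursor : m.start])
        new_len += m.start - cursor
        new_start = new_len
        pieces.append(surrogate)
        new_len += len(surrogate)
        offset_map.replaced.append((m.start, m.end, new_start, new_len))
        offset_map.anchors.append((m.end, new_len))
        cursor = m.end
    pieces.append(doc.text[cursor:])
    new_text = "".join(pieces)

    new_annotations = []
    for ann in doc.annotations:
        host = next(
            (m for m in masks if m.start <= ann.start and ann.end <= m.end), None
        )
        if host is not None:
            region = next(r for r in offset_map.replaced if r[0] == host.start)
            new_s, new_e = region[2], region[3]
        else:
            new_s, new_e = offset_map.map(ann.start), offset_map.map(ann.end)
        new_annotations.append(
            Annotation(new_s, new_e, ann.label, new_text[new_s:new_e])
        )
    return Document(doc.doc_id, new_text, new_annotations), offset_map
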