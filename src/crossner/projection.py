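"""Alignment matrices, the diagonality filter, and character-level span
projection.

A word alignment between a source sentence of ``w_src`` tokens and a target
sentence of ``w_tgt`` tokens is viewed as a binary matrix ``A`` of shape
``w_src x w_tgt``. Plausible alignments of parallel sentences hug the
corner-to-corner diagonal; degenerate alignments (tabular text, failed
translations) scatter far from it. The *diagonality score* is the mean
perpendicular Euclidean distance of the nonzero entries ``(i, j)`` (1-based)
to the line through ``(1, 1)`` and ``(w_src, w_tgt)``; a sentence pair is
kept iff its score does not exceed the threshold ``t`` (default 1.8). A
pair with no links at all is always rejected.

Annotations are projected at the character level: the source tokens a span
overlaps are collected, their linked target tokens gathered, and the target
span is the hull from the minimum start to the maximum end of those tokens.
A span none of whose tokens is linked is discarded (with a logged reason).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .standoff_io import Annotation
from .sentencize import Sentence

logger = logging.getLogger(__name__)

_TOKEN = re.compile(r"\S+")

#: Labels removed before projection by default: their definitions are too
#: context-bound to survive transfer to general-domain target text.
DEFAULT_LABEL_BLACKLIST = frozenset({"Reason", "ADE"})


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Maximal whitespace-delimited tokens with their character spans."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(text)]


@dataclass(frozen=True)
class FilterConfig:
    """Diagonality filter threshold ``t`` (score above t => pair dropped)."""

    t: float = 1.8

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"threshold t must be >= 0, got {self.t}")


@dataclass
class AlignmentMatrix:
    """Binary token-correspondence matrix of shape (w_src, w_tgt)."""

    A: np.ndarray
    w_src: int
    w_tgt: int

    @classmethod
    def from_links(
        cls, links: set[tuple[int, int]], w_src: int, w_tgt: int
    ) -> "AlignmentMatrix":
        if w_src < 1 or w_tgt < 1:
            raise ValueError("matrix dimensions must be >= 1")
        A = np.zeros((w_src, w_tgt), dtype=np.uint8)
        for i, j in links:
            if not (0 <= i < w_src and 0 <= j < w_tgt):
                raise ValueError(
                    f"link ({i}, {j}) out of range for {w_src}x{w_tgt} matrix"
                )
            A[i, j] = 1
        return cls(A, w_src, w_tgt)


@dataclass
class SentencePair:
    """A tokenized source/target sentence pair with its alignment links."""

    src_text: str
    tgt_text: str
    src_tokens: list[tuple[str, int, int]]
    tgt_tokens: list[tuple[str, int, int]]
    links: set[tuple[int, int]] = field(default_factory=set)

    @classmethod
    def from_texts(
        cls, src_text: str, tgt_text: str, links: set[tuple[int, int]]
    ) -> "SentencePair":
        pair = cls(
            src_text,
            tgt_text,
            tokenize_with_offsets(src_text),
            tokenize_with_offsets(tgt_text),
            links,
        )
        for i, j in links:
            if i >= len(pair.src_tokens) or j >= len(pair.tgt_tokens):
                raise ValueError(
                    f"link ({i}, {j}) out of range for "
                    f"{len(pair.src_tokens)}x{len(pair.tgt_tokens)} tokens"
                )
        return pair

    def matrix(self) -> AlignmentMatrix:
        return AlignmentMatrix.from_links(
            self.links, max(len(self.src_tokens), 1), max(len(self.tgt_tokens), 1)
        )


def diagonality_score(m: AlignmentMatrix) -> float:
    """Mean perpendicular distance of nonzero entries to the corner-to-corner
    line.

    Entries are addressed 1-based; the line runs from (1, 1) to
    (w_src, w_tgt). For a 1x1 matrix the line degenerates to the point
    (1, 1) and plain Euclidean distance is used. Zero iff every link lies
    on the line. Raises ``ValueError`` on an all-zero matrix.
    """
    rows, cols = np.nonzero(m.A)
    if rows.size == 0:
        raise ValueError("diagonality score undefined for an all-zero matrix")
    i = rows.astype(float) + 1.0
    j = cols.astype(float) + 1.0
    dx = float(m.w_src - 1)
    dy = float(m.w_tgt - 1)
    if dx == 0.0 and dy == 0.0:
        dists = np.hypot(i - 1.0, j - 1.0)
    else:
        # distance from (i, j) to the line through (1,1) with direction (dx, dy)
        dists = np.abs(dy * (i - 1.0) - dx * (j - 1.0)) / np.hypot(dx, dy)
    return float(dists.mean())


def passes_filter(m: AlignmentMatrix, cfg: FilterConfig | None = None) -> bool:
    """True iff the pair's diagonality score is within threshold.

    An all-zero matrix carries no usable alignment and never passes.
    """
    cfg = cfg or FilterConfig()
    if not m.A.any():
        return False
    return diagonality_score(m) <= cfg.t


def project_annotation(ann: Annotation, pair: SentencePair) -> Annotation | None:
    """Project a source-sentence annotation onto the target sentence.

    Source tokens overlapping ``[start, end)`` are collected; their aligned
    target tokens give the hull span (min start, max end). Returns ``None``
    (a logged discard) when no overlapped source token has a link.
    """
    src_idx = [
        k
        for k, (_, s, e) in enumerate(pair.src_tokens)
        if s < ann.end and ann.start < e
    ]
    tgt_idx = sorted({j for (i, j) in pair.links if i in set(src_idx)})
    if not tgt_idx:
        logger.debug(
            "discarding %s (%d, %d): no alignment link for its tokens",
            ann.label,
            ann.start,
            ann.end,
        )
        return None
    start = min(pair.tgt_tokens[j][1] for j in tgt_idx)
    end = max(pair.tgt_tokens[j][2] for j in tgt_idx)
    return Annotation(start, end, ann.label, pair.tgt_text[start:end])


@dataclass
class ProjectionReport:
    """Bookkeeping for one synthesis run."""

    sentences_in: int = 0
    sentences_out: int = 0
    pairs_filtered: int = 0
    annotations_in: int = 0
    annotations_out: int = 0
    blacklisted: dict = field(default_factory=dict)
    discarded_unlinked: dict = field(default_factory=dict)
    projected: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "sentences_in": self.sentences_in,
            "sentences_out": self.sentences_out,
            "pairs_filtered": self.pairs_filtered,
            "filter_rate": (
                self.pairs_filtered / self.sentences_in if self.sentences_in else 0.0
            ),
            "annotations_in": self.annotations_in,
            "annotations_out": self.annotations_out,
            "blacklisted": dict(self.blacklisted),
            "discarded_unlinked": dict(self.discarded_unlinked),
            "projected": dict(self.projected),
        }


def synthesize_corpus(
    sentences: list[Sentence],
    translator,
    aligner,
    cfg: FilterConfig | None = None,
    translation_config=None,
    label_blacklist: frozenset[str] = DEFAULT_LABEL_BLACKLIST,
) -> tuple[list[Sentence], ProjectionReport]:
    """Run the full target-language synthesis pipeline over sentences.

    translate -> align -> build matrices -> diagonality filter -> project
    each annotation. Returns target-language sentences (annotations at
    character level) and a :class:`ProjectionReport`.
    """
    cfg = cfg or FilterConfig()
    report = ProjectionReport(sentences_in=len(sentences))
    texts = [s.text for s in sentences]
    try:
        translations = translator.translate(texts, translation_config)
    except Exception as exc:
        raise RuntimeError(f"translation backend failed: {exc}") from exc
    if len(translations) != len(texts):
        raise RuntimeError(
            f"translator returned {len(translations)} outputs for "
            f"{len(texts)} sentences"
        )
    link_sets = aligner.align(list(zip(texts, translations)))
    if len(link_sets) != len(texts):
        raise RuntimeError(
            f"aligner returned {len(link_sets)} link sets for {len(texts)} pairs"
        )

    out: list[Sentence] = []
    for idx, (sent, tgt_text, links) in enumerate(
        zip(sentences, translations, link_sets)
    ):
        report.annotations_in += len(sent.annotations)
        pair = SentencePair.from_texts(sent.text, tgt_text, links)
        if not passes_filter(pair.matrix(), cfg):
            report.pairs_filtered += 1
            continue
        kept_anns = []
        for ann in sent.annotations:
            if ann.label in label_blacklist:
                report.blacklisted[ann.label] = (
                    report.blacklisted.get(ann.label, 0) + 1
                )
                continue
            projected = project_annotation(ann, pair)
            if projected is None:
                report.discarded_unlinked[ann.label] = (
                    report.discarded_unlinked.get(ann.label, 0) + 1
                )
                continue
            kept_anns.append(projected)
            report.projected[ann.label] = report.projected.get(ann.label, 0) + 1
        kept_anns.sort(key=lambda a: (a.start, a.end))
        out.append(
            Sentence(sent.doc_id, len(out), tgt_text, 0, kept_anns)
        )
        report.annotations_out += len(kept_anns)
    report.sentences_out = len(out)
    return out, report
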