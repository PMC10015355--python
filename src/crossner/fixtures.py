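"""Seeded synthetic-corpus generator.

The real source corpus (annotated English medication-extraction notes) is
access-restricted, so every pipeline stage is exercised on structurally
equivalent synthetic data instead: templated clinical-style sentences with
typed entities from the 7-label medication set, typed de-identification
masks, and deterministic pseudo-translations with exact gold alignments.

Two properties make the fixtures useful as oracles rather than mere noise:

* the generator keeps full bookkeeping (every entity, mask and expected
  count), so downstream statistics can be checked exactly;
* pseudo-translation is a pure token transform (suffixing + a seeded local
  reordering), so gold alignment links are correct by construction, and
  deliberately scrambled pairs use full token reversal, whose diagonality
  score grows linearly with sentence length and therefore reliably trips
  the filter.

Templates with entities are at least 9 tokens long so that a reversed pair
always scores far above the default threshold (mean distance ~0.35 * n for
an n-token reversal).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .standoff_io import Annotation, Document
from .sentencize import Sentence
from .backends import format_pharaoh

NER_LABELS_7 = ("Drug", "Strength", "Route", "Form", "Dosage", "Frequency", "Duration")

_VOCAB = {
    "Drug": ("Aspirin", "Lisinopril", "Metformin", "Warfarin", "Atorvastatin",
             "Ibuprofen", "Omeprazole", "Prednisone"),
    "Strength": ("81 mg", "10 mg", "500 mg", "5 mg", "20 mg", "40 mg"),
    "Route": ("PO", "IV", "orally", "subcutaneously", "topically"),
    "Form": ("tablet", "capsule", "solution", "cream", "injection"),
    "Dosage": ("one", "two", "half", "three"),
    "Frequency": ("daily", "twice daily", "every morning", "at bedtime", "weekly"),
    "Duration": ("for 3 days", "for 2 weeks", "for one month", "for 10 days"),
}

# slots in braces become annotated entities; templates carrying entities are
# kept >= 9 tokens so reversal-scrambled pairs always exceed the filter
# threshold
_ENTITY_TEMPLATES = (
    "Pt was started on {Drug} {Strength} {Route} {Frequency} after admission .",
    "Continue {Drug} {Strength} one {Form} {Route} {Frequency} as before .",
    "She will take {Dosage} {Form} of {Drug} {Frequency} {Duration} .",
    "Plan to give {Drug} {Strength} {Route} {Frequency} {Duration} today .",
    "He received {Dosage} {Form} {Drug} {Strength} {Route} this morning .",
    "Discharge meds include {Drug} {Strength} {Route} {Frequency} going forward .",
)
_MASK_TEMPLATES = (
    "Seen by [**Name**] on [**Date**] for follow up .",
    "Contact [**Phone**] regarding patient [**ID Number**] if needed .",
    "Admitted in [**Year**] to [**Hospital**] ward .",
)
_PLAIN_TEMPLATES = (
    "Follow up as needed .",
    "No acute distress noted .",
    "Vitals stable throughout the stay .",
)


@dataclass
class FixtureSpec:
    """Generation parameters; a fixed seed yields a byte-identical corpus."""

    seed: int = 0
    n_documents: int = 10
    sentences_per_doc: tuple[int, int] = (3, 8)
    mask_rate: float = 0.25
    unannotated_rate: float = 0.2
    scramble_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mask_rate", "unannotated_rate", "scramble_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class Bookkeeping:
    per_label: dict = field(default_factory=dict)
    n_sentences: int = 0
    n_annotated_sentences: int = 0
    n_masks: int = 0
    scrambled_indices: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_label": dict(self.per_label),
            "n_sentences": self.n_sentences,
            "n_annotated_sentences": self.n_annotated_sentences,
            "n_masks": self.n_masks,
            "scrambled_indices": list(self.scrambled_indices),
        }


def _fill_template(template: str, rng: random.Random) -> tuple[str, list[Annotation]]:
    out: list[str] = []
    annotations: list[Annotation] = []
    pos = 0
    for piece in template.split(" "):
        if piece.startswith("{") and piece.endswith("}"):
            label = piece[1:-1]
            value = rng.choice(_VOCAB[label])
            annotations.append(Annotation(pos, pos + len(value), label, value))
            out.append(value)
            pos += len(value) + 1
        else:
            out.append(piece)
            pos += len(piece) + 1
    return " ".join(out), annotations


def generate_masked_corpus(spec: FixtureSpec) -> tuple[list[Document], Bookkeeping]:
    """Generate documents of templated clinical-style sentences with typed
    entities and de-identification masks, plus exact bookkeeping."""
    rng = random.Random(spec.seed)
    books = Bookkeeping()
    documents: list[Document] = []
    for d in range(spec.n_documents):
        n_sents = rng.randint(*spec.sentences_per_doc)
        parts: list[str] = []
        annotations: list[Annotation] = []
        offset = 0
        for _ in range(n_sents):
            roll = rng.random()
            if roll < spec.mask_rate:
                text, anns = rng.choice(_MASK_TEMPLATES), []
                books.n_masks += text.count("[**")
            elif roll < spec.mask_rate + spec.unannotated_rate:
                text, anns = rng.choice(_PLAIN_TEMPLATES), []
            else:
                text, anns = _fill_template(rng.choice(_ENTITY_TEMPLATES), rng)
                books.n_annotated_sentences += 1
            for a in anns:
                annotations.append(
                    Annotation(a.start + offset, a.end + offset, a.label, a.surface)
                )
                books.per_label[a.label] = books.per_label.get(a.label, 0) + 1
            parts.append(text)
            offset += len(text) + 1
            books.n_sentences += 1
        doc_text = "\n".join(parts) + "\n"
        documents.append(Document(f"synth-{d:03d}", doc_text, annotations))
    return documents, books


def make_pseudo_parallel(
    sentences: list[Sentence],
    seed: int = 0,
    scramble_fraction: float = 0.0,
    n_scrambled: int | None = None,
) -> tuple[list[tuple[str, str, set[tuple[int, int]]]], list[int]]:
    """Deterministically pseudo-translate sentences with exact gold links.

    Normal pairs: every token gets a ``_DE`` suffix and at most a couple of
    seeded adjacent swaps, keeping the alignment near-diagonal. Scrambled
    pairs (``n_scrambled`` explicit, else ``scramble_fraction`` of all)
    receive a full token reversal — an adversarial long-range permutation
    whose diagonality score exceeds any reasonable threshold for sentences
    of >= 9 tokens. Returns (source text, target text, links) triples and
    the scrambled indices.
    """
    rng = random.Random(seed)
    n = len(sentences)
    if n_scrambled is None:
        n_scrambled = round(scramble_fraction * n)
    scrambled = sorted(rng.sample(range(n), min(n_scrambled, n)))
    scrambled_set = set(scrambled)
    pairs = []
    for idx, sent in enumerate(sentences):
        tokens = sent.text.split()
        size = len(tokens)
        if idx in scrambled_set:
            perm = list(reversed(range(size)))
        else:
            perm = list(range(size))
            i = 0
            while i < size - 1:
                if rng.random() < 0.2:
                    perm[i], perm[i + 1] = perm[i + 1], perm[i]
                    i += 2
                else:
                    i += 1
        target = [""] * size
        for i, tok in enumerate(tokens):
            target[perm[i]] = tok + "_DE"
        links = {(i, perm[i]) for i in range(size)}
        pairs.append((sent.text, " ".join(target), links))
    return pairs, scrambled


def pairs_to_pharaoh(pairs) -> str:
    """Serialize the gold link sets of pseudo-parallel pairs to Pharaoh."""
    return "\n".join(format_pharaoh(links) for _, _, links in pairs) + "\n"


class FixtureTranslator:
    """Translation backend replaying fixed (source -> target) pairs.

    Duplicate source sentences are replayed in their original order, so the
    backend is exact even when the corpus repeats a sentence.
    """

    name = "fixture"

    def __init__(self, pairs):
        self.queues: dict[str, list[str]] = {}
        for src, tgt, _ in pairs:
            self.queues.setdefault(src, []).append(tgt)
        self.cursor: dict[str, int] = {}

    def translate(self, sentences, config=None):
        out = []
        for s in sentences:
            k = self.cursor.get(s, 0)
            queue = self.queues[s]
            out.append(queue[min(k, len(queue) - 1)])
            self.cursor[s] = k + 1
        return out


class FixtureAligner:
    """Alignment backend replaying the gold links of fixed pairs."""

    name = "fixture"

    def __init__(self, pairs):
        self.queues: dict[tuple[str, str], list[set]] = {}
        for src, tgt, links in pairs:
            self.queues.setdefault((src, tgt), []).append(links)
        self.cursor: dict[tuple[str, str], int] = {}

    def align(self, pairs):
        out = []
        for key in pairs:
            k = self.cursor.get(key, 0)
            queue = self.queues[key]
            out.append(queue[min(k, len(queue) - 1)])
            self.cursor[key] = k + 1
        return out
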