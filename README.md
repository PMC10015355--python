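# crossner

Cross-lingual synthesis of annotated named-entity-recognition (NER) corpora
for clinical text, plus a lightweight transition-based NER tagger.

## The problem

Annotated clinical corpora exist almost exclusively in English, and privacy
law makes building equivalents in other languages slow and often impossible
to publish. `crossner` implements a pipeline that manufactures a
target-language medication-NER corpus from an English standoff-annotated
corpus without any target-language annotation effort:

1. **Surrogate replacement** — de-identification placeholders such as
   `[**Name**]` are detected, typed, and replaced by sampled surrogates of
   the same semantic type (names, dates, years, phone numbers, ID numbers,
   digit strings of matched width), with every annotation offset remapped
   exactly.
2. **Sentence splitting** — documents are segmented, annotations are
   localized to sentence-relative offsets (a boundary that would cut an
   annotation dissolves, merging the sentences), and sentences without
   annotations are dropped.
3. **Translation and word alignment** — pluggable backends over text
   protocols (one-sentence-per-line translation; `src ||| tgt` bitext in,
   Pharaoh `i-j` links out). Seeded mock backends make the whole pipeline
   testable without any model.
4. **Alignment-quality filtering** — each sentence pair's alignment is a
   binary matrix A of shape w_src × w_tgt. The *diagonality score* is the
   mean perpendicular distance of the nonzero entries (i, j), 1-based, to
   the line through (1, 1) and (w_src, w_tgt):

   d(A) = mean over nonzero (i,j) of |Δy·(i−1) − Δx·(j−1)| / √(Δx² + Δy²),
   with Δx = w_src − 1, Δy = w_tgt − 1.

   Plausible alignments hug that corner-to-corner line; collapsed or
   scrambled alignments do not. A pair is kept iff d(A) ≤ t (default
   t = 1.8); a pair with no links is always dropped.
5. **Character-level annotation projection** — each source span's tokens
   are mapped through the links; the target span is the hull (min start,
   max end) of the aligned target tokens, keeping the label. Spans with no
   linked token are discarded and counted.

The package also ships the evaluation protocol (entity-level, token-wise
IOB and character-wise label P/R/F1 with label-frequency-weighted totals,
an 80/10/10 split, cross-model F1 delta tables) and a small trainable NER
model: hashed (Bloom) feature embeddings → a residual convolutional context
encoder → a greedy stateful transition parser over IOB actions, trained
with Adam in pure numpy. It is intentionally tiny: a few megabytes of
parameters, minutes of CPU training.

## Worked example

```python
from crossner import (Annotation, Document, detect_masks, replace_masks,
                      split_document, drop_unannotated, FilterConfig,
                      SentencePair, diagonality_score, passes_filter,
                      project_annotation)

doc = Document(
    "note-001",
    "Seen by [**Name**] today. Started aspirin 81 mg PO daily.",
    [Annotation(34, 41, "Drug", "aspirin"), Annotation(42, 47, "Strength", "81 mg")],
)
doc, _ = replace_masks(doc, detect_masks(doc.text), seed=7)
print(doc.text)
print([(a.start, a.end, a.label, a.surface) for a in doc.annotations])

sentences = drop_unannotated(split_document(doc))
pair = SentencePair.from_texts(
    "Take aspirin daily", "Nehmen Sie täglich Aspirin",
    {(0, 0), (0, 1), (1, 3), (2, 2)},
)
print(round(diagonality_score(pair.matrix()), 4),
      passes_filter(pair.matrix(), FilterConfig(t=1.8)))
print(project_annotation(Annotation(5, 12, "Drug", "aspirin"), pair))
```

prints

```
Seen by William Jones today. Started aspirin 81 mg PO daily.
[(37, 44, 'Drug', 'aspirin'), (45, 50, 'Strength', '81 mg')]
0.4854 True
Annotation(start=19, end=26, label='Drug', surface='Aspirin')
```

The placeholder became a sampled name and both annotation spans shifted by
the length difference while keeping their exact surface strings. The
four-link alignment of the 3-token/4-token pair scores 0.4854 — well under
the 1.8 threshold — and the `Drug` span lands on `Aspirin` at characters
19–26 of the German sentence. A reversed (scrambled) alignment of a
9-token pair scores 3.77 and is filtered out.

A command-line interface wires the stages end to end
(`crossner synthesize | filter-stats | train | evaluate | compare |
fixtures generate`); every run writes a `config.yaml` snapshot of its
effective parameters.

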