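"""Published reference results for the German-target medication NER
transfer experiment this toolkit implements.

These tables are *inputs*, not outputs: the per-tag test-set scores of the
German-trained model and of the English-trained counterpart, and the label
distribution of the synthesized corpus. They feed the delta-table and
aggregation arithmetic (e.g. ``crossner compare``) without requiring the
access-restricted source corpus or a pretrained translation model.

Rows are (precision %, recall %, F1 %, gold label count).
"""

# label distribution of the synthesized corpus (8599 sentence pairs)
CORPUS_LABEL_COUNTS = {
    "Drug": 8305,
    "Strength": 4071,
    "Route": 4549,
    "Form": 4238,
    "Dosage": 409,
    "Frequency": 5242,
    "Duration": 3419,
}
CORPUS_ANNOTATION_TOTAL = 30233
CORPUS_SENTENCES = 8599
CORPUS_TOKENS = 172695

# German-trained model, token-wise IOB evaluation on the held-out test split
GERMAN_MODEL_SCORES = {
    "Drug": (67.33, 66.17, 66.74, 8305),
    "Strength": (92.34, 90.99, 91.66, 4071),
    "Route": (89.93, 90.14, 90.04, 4549),
    "Form": (91.94, 89.24, 90.57, 4238),
    "Dosage": (87.83, 87.57, 87.70, 409),
    "Frequency": (79.14, 76.92, 78.01, 5242),
    "Duration": (67.86, 52.78, 59.37, 3419),
}
GERMAN_MODEL_TOTAL = (82.31, 80.79, 81.54, 30233)

# English-trained counterpart on the English side of the same sentence pairs
ENGLISH_MODEL_SCORES = {
    "Drug": (80.94, 82.02, 81.47, 8305),
    "Strength": (89.02, 90.12, 89.57, 4071),
    "Route": (85.55, 95.08, 90.06, 4549),
    "Form": (94.36, 87.12, 90.60, 4238),
    "Dosage": (89.41, 89.97, 89.69, 409),
    "Frequency": (80.55, 80.15, 80.35, 5242),
    "Duration": (62.50, 51.02, 56.18, 3419),
}
ENGLISH_MODEL_TOTAL = (85.14, 85.82, 85.48, 30233)
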