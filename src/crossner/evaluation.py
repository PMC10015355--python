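"""Metrics and reporting: entity-level, token-wise IOB and character-wise
label scores, frequency-weighted totals, dataset statistics, the 80/10/10
split, and cross-model delta tables.

All scores are percentages. The weighted total of a report averages the
per-tag values with the per-tag gold counts of the evaluated data as
weights. Zero-denominator convention: precision (recall) is 0 when there
are no predictions (no gold spans).
"""

from __future__ import annotations

import csv
import io
import json
import random
from collections import Counter
from dataclasses import dataclass, field

from .standoff_io import Annotation
from .projection import tokenize_with_offsets


@dataclass
class TagScore:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    """Per-tag precision/recall/F1 (in %) plus frequency-weighted totals."""

    mode: str
    per_tag: dict[str, TagScore] = field(default_factory=dict)
    total: TagScore | None = None

    def as_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "per_tag": {
                tag: {
                    "precision": s.precision,
                    "recall": s.recall,
                    "f1": s.f1,
                    "support": s.support,
                }
                for tag, s in self.per_tag.items()
            },
        }
        if self.total:
            d["total"] = {
                "precision": self.total.precision,
                "recall": self.total.recall,
                "f1": self.total.f1,
                "support": self.total.support,
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["tag", "precision", "recall", "f1", "support"])
        for tag in sorted(self.per_tag):
            s = self.per_tag[tag]
            writer.writerow(
                [tag, f"{s.precision:.2f}", f"{s.recall:.2f}", f"{s.f1:.2f}", s.support]
            )
        if self.total:
            t = self.total
            writer.writerow(
                ["Total", f"{t.precision:.2f}", f"{t.recall:.2f}", f"{t.f1:.2f}", t.support]
            )
        return buf.getvalue()


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _build_report(mode: str, counts: dict[str, tuple[int, int, int]]) -> EvalReport:
    report = EvalReport(mode=mode)
    for tag, (tp, fp, fn) in sorted(counts.items()):
        p, r, f = _prf(tp, fp, fn)
        report.per_tag[tag] = TagScore(p, r, f, support=tp + fn)
    weights = {t: s.support for t, s in report.per_tag.items()}
    total_w = sum(weights.values())
    if total_w:
        report.total = TagScore(
            sum(report.per_tag[t].precision * w for t, w in weights.items()) / total_w,
            sum(report.per_tag[t].recall * w for t, w in weights.items()) / total_w,
            sum(report.per_tag[t].f1 * w for t, w in weights.items()) / total_w,
            support=total_w,
        )
    return report


def entity_prf(
    gold: list[list[Annotation]], pred: list[list[Annotation]]
) -> EvalReport:
    """Exact-match entity scores: a prediction counts iff start, end and
    label all agree with a gold span of the same sentence (multiset match)."""
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold vs {len(pred)} pred sentence sets")
    counts: dict[str, list[int]] = {}

    def bucket(tag: str) -> list[int]:
        return counts.setdefault(tag, [0, 0, 0])

    for g_sent, p_sent in zip(gold, pred):
        g_multi = Counter((a.start, a.end, a.label) for a in g_sent)
        p_multi = Counter((a.start, a.end, a.label) for a in p_sent)
        for key in g_multi | p_multi:
            label = key[2]
            tp = min(g_multi[key], p_multi[key])
            bucket(label)[0] += tp
            bucket(label)[1] += p_multi[key] - tp
            bucket(label)[2] += g_multi[key] - tp
    return _build_report("entity", {t: tuple(v) for t, v in counts.items()})


def token_iob_eval(gold_tags: list[list[str]], pred_tags: list[list[str]]) -> EvalReport:
    """Token-level scores with B-x and I-x pooled per label x.

    Each token carries one label (or none, for O); per-label counts are
    computed over these token label assignments.
    """
    if len(gold_tags) != len(pred_tags):
        raise ValueError("sentence count mismatch")
    counts: dict[str, list[int]] = {}

    def strip(tag: str) -> str | None:
        return tag[2:] if tag not in ("O", "") else None

    for s_idx, (g_seq, p_seq) in enumerate(zip(gold_tags, pred_tags)):
        if len(g_seq) != len(p_seq):
            raise ValueError(
                f"sentence {s_idx}: tag sequence lengths differ "
                f"({len(g_seq)} vs {len(p_seq)})"
            )
        for g, p in zip(g_seq, p_seq):
            gl, pl = strip(g), strip(p)
            if gl == pl:
                if gl is not None:
                    counts.setdefault(gl, [0, 0, 0])[0] += 1
            else:
                if pl is not None:
                    counts.setdefault(pl, [0, 0, 0])[1] += 1
                if gl is not None:
                    counts.setdefault(gl, [0, 0, 0])[2] += 1
    return _build_report("token_iob", {t: tuple(v) for t, v in counts.items()})


def char_label_f1(
    gold: list[tuple[str, list[Annotation]]],
    pred: list[tuple[str, list[Annotation]]],
) -> EvalReport:
    """Character-wise label classification scores.

    Every character of a text is assigned at most one label per side;
    overlapping spans with conflicting labels on the same text are an error.
    """
    if len(gold) != len(pred):
        raise ValueError("sentence count mismatch")

    def paint(text: str, anns: list[Annotation]) -> list[str | None]:
        canvas: list[str | None] = [None] * len(text)
        for a in anns:
            for k in range(a.start, min(a.end, len(text))):
                if canvas[k] is not None and canvas[k] != a.label:
                    raise ValueError(
                        f"conflicting labels {canvas[k]}/{a.label} at char {k}"
                    )
                canvas[k] = a.label
        return canvas

    counts: dict[str, list[int]] = {}
    for (g_text, g_anns), (p_text, p_anns) in zip(gold, pred):
        if g_text != p_text:
            raise ValueError("gold and pred refer to different texts")
        g_canvas = paint(g_text, g_anns)
        p_canvas = paint(p_text, p_anns)
        for gl, pl in zip(g_canvas, p_canvas):
            if gl == pl:
                if gl is not None:
                    counts.setdefault(gl, [0, 0, 0])[0] += 1
            else:
                if pl is not None:
                    counts.setdefault(pl, [0, 0, 0])[1] += 1
                if gl is not None:
                    counts.setdefault(gl, [0, 0, 0])[2] += 1
    return _build_report("char_label", {t: tuple(v) for t, v in counts.items()})


def split_dataset(
    n_sentences: int,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[int], list[int], list[int]]:
    """Seeded disjoint train/val/test index split.

    Validation and test sizes are ``round(ratio * n)``; the training split
    takes the remainder, so the partition is exact. n=8599 with the default
    ratios gives (6879, 860, 860).
    """
    if n_sentences < 3:
        raise ValueError("need at least 3 sentences to split")
    n_val = int(round(ratios[1] * n_sentences))
    n_test = int(round(ratios[2] * n_sentences))
    indices = list(range(n_sentences))
    random.Random(seed).shuffle(indices)
    test = indices[:n_test]
    val = indices[n_test : n_test + n_val]
    train = indices[n_test + n_val :]
    return train, val, test


def dataset_stats(sentences) -> dict:
    """Sentence, per-label annotation and whitespace-token counts."""
    per_label: Counter = Counter()
    tokens = 0
    for sent in sentences:
        per_label.update(a.label for a in sent.annotations)
        tokens += len(tokenize_with_offsets(sent.text))
    return {
        "sentences": len(sentences),
        "annotations": sum(per_label.values()),
        "per_label": dict(sorted(per_label.items())),
        "tokens": tokens,
    }


def compare_models(report_a: EvalReport, report_b: EvalReport) -> dict[str, float]:
    """Per-tag and total F1 deltas (a minus b), in percentage points."""
    if set(report_a.per_tag) != set(report_b.per_tag):
        raise ValueError(
            f"label sets differ: {sorted(report_a.per_tag)} vs "
            f"{sorted(report_b.per_tag)}"
        )
    deltas = {
        tag: report_a.per_tag[tag].f1 - report_b.per_tag[tag].f1
        for tag in report_a.per_tag
    }
    if report_a.total and report_b.total:
        deltas["Total"] = report_a.total.f1 - report_b.total.f1
    return deltas


def report_from_table(
    mode: str,
    rows: dict[str, tuple[float, float, float, int]],
    total: tuple[float, float, float, int] | None = None,
) -> EvalReport:
    """Build a report from externally given per-tag (P, R, F1, support)
    rows, e.g. a published results table; if ``total`` is omitted it is
    recomputed by support-weighted averaging."""
    report = EvalReport(mode=mode)
    for tag, (p, r, f, n) in rows.items():
        report.per_tag[tag] = TagScore(p, r, f, n)
    if total is not None:
        report.total = TagScore(*total)
    else:
        w = sum(s.support for s in report.per_tag.values())
        if w:
            report.total = TagScore(
                sum(s.precision * s.support for s in report.per_tag.values()) / w,
                sum(s.recall * s.support for s in report.per_tag.values()) / w,
                sum(s.f1 * s.support for s in report.per_tag.values()) / w,
                support=w,
            )
    return report


def deltas_to_csv(deltas: dict[str, float], report_a: EvalReport) -> str:
    """Delta table as CSV: tag, model-a F1, delta."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["tag", "f1", "delta"])
    for tag, delta in deltas.items():
        f1 = (
            report_a.total.f1
            if tag == "Total" and report_a.total
            else report_a.per_tag[tag].f1
        )
        writer.writerow([tag, f"{f1:.2f}", f"{delta:+.2f}"])
    return buf.getvalue()
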