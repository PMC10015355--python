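"""Diagonality scoring, filtering and character-level span projection.

The score is checked against an independent brute-force oracle that walks
every matrix cell and computes the point-to-line distance by vector
projection (a different derivation than the production formula).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossner.backends import IdentityBackend, ReversibleBackend
from crossner.projection import (
    AlignmentMatrix,
    FilterConfig,
    SentencePair,
    diagonality_score,
    passes_filter,
    project_annotation,
    synthesize_corpus,
    tokenize_with_offsets,
)
from crossner.standoff_io import Annotation


def oracle_score(A: np.ndarray) -> float:
    """Brute-force mean point-to-line distance via explicit vector projection."""
    w_src, w_tgt = A.shape
    p0 = np.array([1.0, 1.0])
    direction = np.array([float(w_src), float(w_tgt)]) - p0
    dists = []
    for i in range(w_src):
        for j in range(w_tgt):
            if not A[i, j]:
                continue
            p = np.array([i + 1.0, j + 1.0])
            if np.allclose(direction, 0.0):
                dists.append(float(np.linalg.norm(p - p0)))
                continue
            u = direction / np.linalg.norm(direction)
            rejection = (p - p0) - np.dot(p - p0, u) * u
            dists.append(float(np.linalg.norm(rejection)))
    return float(np.mean(dists))


class TestTokenize:
    def test_offsets_tile_non_whitespace(self):
        tokens = tokenize_with_offsets("Nehmen Sie täglich Aspirin")
        assert [(s, e) for _, s, e in tokens] == [(0, 6), (7, 10), (11, 18), (19, 26)]

    def test_empty(self):
        assert tokenize_with_offsets("") == []

    def test_single_char(self):
        assert tokenize_with_offsets("x") == [("x", 0, 1)]


class TestDiagonalityScore:
    def test_identity_scores_zero(self):
        m = AlignmentMatrix.from_links({(0, 0), (1, 1), (2, 2)}, 3, 3)
        assert diagonality_score(m) == 0.0

    def test_anti_diagonal_3x3(self):
        m = AlignmentMatrix.from_links({(0, 2), (1, 1), (2, 0)}, 3, 3)
        # distances (sqrt2, 0, sqrt2) averaged
        assert diagonality_score(m) == pytest.approx(2 * math.sqrt(2) / 3, abs=1e-4)
        assert diagonality_score(m) == pytest.approx(0.9428, abs=1e-4)

    def test_rectangular_2x3(self):
        m = AlignmentMatrix.from_links({(0, 0), (0, 1), (1, 2)}, 2, 3)
        assert diagonality_score(m) == pytest.approx(1 / math.sqrt(5) / 3, abs=1e-9)

    def test_all_zero_matrix_raises(self):
        m = AlignmentMatrix(np.zeros((2, 2), dtype=np.uint8), 2, 2)
        with pytest.raises(ValueError):
            diagonality_score(m)

    def test_degenerate_1x1_is_distance_to_corner(self):
        m = AlignmentMatrix.from_links({(0, 0)}, 1, 1)
        assert diagonality_score(m) == 0.0

    @given(
        st.integers(1, 12),
        st.integers(1, 12),
        st.integers(0, 2**32 - 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, w_src, w_tgt, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((w_src, w_tgt)) < 0.3).astype(np.uint8)
        if not A.any():
            A[rng.integers(w_src), rng.integers(w_tgt)] = 1
        m = AlignmentMatrix(A, w_src, w_tgt)
        assert diagonality_score(m) == pytest.approx(oracle_score(A), abs=1e-9)

    @given(st.integers(1, 10), st.integers(1, 10), st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_transpose_invariance(self, w_src, w_tgt, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((w_src, w_tgt)) < 0.4).astype(np.uint8)
        if not A.any():
            A[0, 0] = 1
        a = diagonality_score(AlignmentMatrix(A, w_src, w_tgt))
        b = diagonality_score(AlignmentMatrix(A.T.copy(), w_tgt, w_src))
        assert a == pytest.approx(b, abs=1e-12)

    @given(st.integers(2, 10), st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_adding_on_line_link_never_increases_score(self, n, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((n, n)) < 0.3).astype(np.uint8)
        if not A.any():
            A[rng.integers(n), rng.integers(n)] = 1
        before = diagonality_score(AlignmentMatrix(A.copy(), n, n))
        k = int(rng.integers(n))
        A[k, k] = 1  # (k+1, k+1) lies exactly on the corner-to-corner line
        after = diagonality_score(AlignmentMatrix(A, n, n))
        assert after <= before + 1e-12


class TestPassesFilter:
    def test_identity_passes_default_threshold(self):
        m = AlignmentMatrix.from_links({(0, 0), (1, 1), (2, 2)}, 3, 3)
        assert passes_filter(m, FilterConfig(t=1.8))

    def test_far_corner_link_fails(self):
        m = AlignmentMatrix.from_links({(0, 4)}, 5, 5)
        assert diagonality_score(m) == pytest.approx(4 / math.sqrt(2), abs=1e-9)
        assert not passes_filter(m, FilterConfig(t=1.8))

    def test_empty_link_set_fails(self):
        m = AlignmentMatrix(np.zeros((3, 3), dtype=np.uint8), 3, 3)
        assert not passes_filter(m, FilterConfig(t=1.8))

    @given(st.integers(1, 8), st.integers(1, 8), st.integers(0, 2**32 - 1),
           st.floats(0, 5), st.floats(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_threshold(self, w_src, w_tgt, seed, t1, t2):
        rng = np.random.default_rng(seed)
        A = (rng.random((w_src, w_tgt)) < 0.4).astype(np.uint8)
        m = AlignmentMatrix(A, w_src, w_tgt)
        lo, hi = sorted([t1, t2])
        if passes_filter(m, FilterConfig(t=lo)):
            assert passes_filter(m, FilterConfig(t=hi))


class TestProjectAnnotation:
    def test_spec_worked_example(self):
        pair = SentencePair.from_texts(
            "Take aspirin daily",
            "Nehmen Sie täglich Aspirin",
            {(0, 0), (0, 1), (1, 3), (2, 2)},
        )
        out = project_annotation(Annotation(5, 12, "Drug", "aspirin"), pair)
        assert (out.start, out.end, out.label, out.surface) == (19, 26, "Drug", "Aspirin")

    def test_identity_pair_identical_span(self):
        text = "take two aspirin now"
        pair = SentencePair.from_texts(text, text, {(k, k) for k in range(4)})
        ann = Annotation(9, 16, "Drug", "aspirin")
        out = project_annotation(ann, pair)
        assert (out.start, out.end) == (9, 16)

    def test_unlinked_token_discarded(self):
        pair = SentencePair.from_texts("take aspirin", "nimm etwas", {(0, 0)})
        assert project_annotation(Annotation(5, 12, "Drug", "aspirin"), pair) is None

    def test_non_contiguous_targets_give_hull(self):
        pair = SentencePair.from_texts(
            "a bb c", "x bb y c", {(1, 1), (1, 3)}
        )
        out = project_annotation(Annotation(2, 4, "Drug", "bb"), pair)
        assert (out.start, out.end) == (2, 8)

    def test_projected_spans_inside_target(self, parallel_pairs, annotated_sentences):
        for sent, (src, tgt, links) in zip(annotated_sentences, parallel_pairs):
            pair = SentencePair.from_texts(src, tgt, links)
            for ann in sent.annotations:
                out = project_annotation(ann, pair)
                if out is not None:
                    assert 0 <= out.start < out.end <= len(tgt)
                    assert out.label == ann.label


class TestSynthesizeCorpus:
    def test_identity_backend_end_to_end_identity(self, annotated_sentences):
        backend = IdentityBackend()
        out, report = synthesize_corpus(
            annotated_sentences, backend, backend, FilterConfig(t=1.8),
            label_blacklist=frozenset(),
        )
        assert report.pairs_filtered == 0
        assert report.discarded_unlinked == {}
        source = sorted(
            (a.start, a.end, a.label)
            for s in annotated_sentences
            for a in s.annotations
        )
        target = sorted(
            (a.start, a.end, a.label) for s in out for a in s.annotations
        )
        assert source == target

    def test_reversible_mock_conserves_counts_with_suffixed_surfaces(
        self, annotated_sentences
    ):
        backend = ReversibleBackend(seed=5)
        out, report = synthesize_corpus(
            annotated_sentences, backend, backend, FilterConfig(t=1.8),
            label_blacklist=frozenset(),
        )
        assert report.annotations_out == report.annotations_in
        for sent in out:
            for ann in sent.annotations:
                # each aligned target token is a _DE-suffixed source token
                for token in ann.surface.split():
                    assert token.endswith("_DE")

    def test_blacklist_removes_labels_before_projection(self):
        from crossner.sentencize import Sentence

        sent = Sentence(
            "d", 0, "stopped aspirin for nausea", 0,
            [Annotation(8, 15, "Drug", "aspirin"), Annotation(20, 26, "Reason", "nausea")],
        )
        backend = IdentityBackend()
        out, report = synthesize_corpus([sent], backend, backend)
        assert [a.label for a in out[0].annotations] == ["Drug"]
        assert report.blacklisted == {"Reason": 1}
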