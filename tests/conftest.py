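import pytest

from crossner.fixtures import FixtureSpec, generate_masked_corpus, make_pseudo_parallel
from crossner.sentencize import drop_unannotated, split_document
from crossner.standoff_io import Annotation
from crossner.sentencize import Sentence


@pytest.fixture(scope="session")
def small_corpus():
    """Ten synthetic documents with entities and masks, plus bookkeeping."""
    return generate_masked_corpus(FixtureSpec(seed=7, n_documents=10))


@pytest.fixture(scope="session")
def annotated_sentences(small_corpus):
    docs, _ = small_corpus
    sentences = []
    for doc in docs:
        sentences.extend(drop_unannotated(split_document(doc)))
    return sentences


@pytest.fixture(scope="session")
def parallel_pairs(annotated_sentences):
    """Unscrambled pseudo-parallel pairs with gold links."""
    pairs, scrambled = make_pseudo_parallel(annotated_sentences, seed=11)
    assert scrambled == []
    return pairs


@pytest.fixture
def memorization_set():
    """Ten short two-label sentences for overfit/memorization checks."""
    import random

    rng = random.Random(1)
    drugs = ["Aspirin", "Metformin", "Warfarin", "Lisinopril"]
    doses = ["81 mg", "500 mg", "10 mg"]
    sentences = []
    for i in range(10):
        d, s = rng.choice(drugs), rng.choice(doses)
        text = f"Pt took {d} {s} today ."
        sentences.append(
            Sentence(
                "memo",
                i,
                text,
                0,
                [
                    Annotation(8, 8 + len(d), "Drug", d),
                    Annotation(9 + len(d), 9 + len(d) + len(s), "Strength", s),
                ],
            )
        )
    return sentences
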