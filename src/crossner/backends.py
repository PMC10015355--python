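"""Pluggable translation and word-alignment backends.

Real machine-translation and alignment engines are integrated strictly over
text protocols (sentences in / translations out, bitext in / Pharaoh ``i-j``
links out) via subprocesses, keeping the core free of model dependencies.
Two seeded mock backends are first-class citizens for testing:

* ``identity`` — translation returns the input verbatim; alignment links
  token ``k`` to token ``k``.
* ``reversible`` — every token becomes ``token_DE`` and token order is
  locally permuted by a seeded, sentence-keyed permutation; the aligner
  recomputes the same permutation, so gold links are exact by construction.
"""

from __future__ import annotations

import hashlib
import random
import subprocess
from dataclasses import dataclass


class BackendError(RuntimeError):
    """External backend failure; carries the diagnostic output."""


class PharaohParseError(ValueError):
    """Malformed ``i-j`` token in a Pharaoh alignment record."""


@dataclass
class TranslationConfig:
    """Decoding configuration passed to translation backends.

    ``beam_width`` mirrors the beam-search setting of neural MT decoders
    (default 5); mock backends ignore it but validate it.
    """

    beam_width: int = 5
    backend_name: str = "identity"

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError(f"beam_width must be >= 1, got {self.beam_width}")


# ---------------------------------------------------------------------------
# Pharaoh + bitext text formats

def parse_pharaoh(line: str, pair_index: int = 0) -> set[tuple[int, int]]:
    """Parse one Pharaoh alignment record (``"0-0 1-2"``) into a link set."""
    links: set[tuple[int, int]] = set()
    for token in line.split():
        left, sep, right = token.partition("-")
        if not sep or not left.isdigit() or not right.isdigit():
            raise PharaohParseError(
                f"pair {pair_index}: malformed Pharaoh token {token!r}"
            )
        links.add((int(left), int(right)))
    return links


def format_pharaoh(links: set[tuple[int, int]]) -> str:
    return " ".join(f"{i}-{j}" for i, j in sorted(links))


def write_bitext(pairs: list[tuple[str, str]]) -> str:
    """One ``src ||| tgt`` line per pair (the input format of common
    aligners). Raises on a ``|||`` inside a sentence or an empty side."""
    lines = []
    for idx, (src, tgt) in enumerate(pairs):
        if "|||" in src or "|||" in tgt:
            raise ValueError(f"pair {idx}: sentence contains the '|||' separator")
        if "\n" in src or "\n" in tgt:
            raise ValueError(f"pair {idx}: sentence contains a newline")
        if not src.strip() or not tgt.strip():
            raise ValueError(f"pair {idx}: empty source or target sentence")
        lines.append(f"{src} ||| {tgt}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Mock backends

class IdentityBackend:
    """Translation is the identity; alignment links are the diagonal."""

    name = "identity"

    def translate(self, sentences: list[str], config: TranslationConfig | None = None) -> list[str]:
        return list(sentences)

    def align(self, pairs: list[tuple[str, str]]) -> list[set[tuple[int, int]]]:
        out = []
        for src, tgt in pairs:
            n = min(len(src.split()), len(tgt.split()))
            out.append({(k, k) for k in range(n)})
        return out


class ReversibleBackend:
    """Deterministic pseudo-translation with exact gold alignments.

    Each token is suffixed with ``_DE`` and token order is permuted by a
    permutation keyed on (seed, source sentence), built from seeded adjacent
    swaps so alignments stay near-diagonal. ``align`` recomputes the same
    permutation from the source side, so links are correct by construction
    and the transform is invertible.
    """

    name = "reversible"
    suffix = "_DE"

    def __init__(self, seed: int = 0, swap_rate: float = 0.3):
        self.seed = seed
        self.swap_rate = swap_rate

    def _permutation(self, sentence: str) -> list[int]:
        """positions: perm[i] = target position of source token i."""
        tokens = sentence.split()
        n = len(tokens)
        key = hashlib.sha256(f"{self.seed}:{sentence}".encode()).digest()
        rng = random.Random(int.from_bytes(key[:8], "big"))
        perm = list(range(n))
        i = 0
        while i < n - 1:
            if rng.random() < self.swap_rate:
                perm[i], perm[i + 1] = perm[i + 1], perm[i]
                i += 2
            else:
                i += 1
        return perm

    def translate(self, sentences: list[str], config: TranslationConfig | None = None) -> list[str]:
        out = []
        for sent in sentences:
            tokens = sent.split()
            perm = self._permutation(sent)
            target = [""] * len(tokens)
            for i, tok in enumerate(tokens):
                target[perm[i]] = tok + self.suffix
            out.append(" ".join(target))
        return out

    def align(self, pairs: list[tuple[str, str]]) -> list[set[tuple[int, int]]]:
        out = []
        for src, _ in pairs:
            perm = self._permutation(src)
            out.append({(i, p) for i, p in enumerate(perm)})
        return out


# ---------------------------------------------------------------------------
# Subprocess adapters (text protocol only)

class ExternalTranslator:
    """Run an external MT command: sentences on stdin (one per line),
    translations on stdout (one per line, same order)."""

    def __init__(self, command: list[str], name: str = "external"):
        self.command = command
        self.name = name

    def translate(self, sentences: list[str], config: TranslationConfig | None = None) -> list[str]:
        payload = "\n".join(sentences) + ("\n" if sentences else "")
        proc = subprocess.run(
            self.command, input=payload, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise BackendError(
                f"translator {self.command} failed (rc={proc.returncode}): "
                f"{proc.stderr.strip()}"
            )
        out = proc.stdout.splitlines()
        if len(out) != len(sentences):
            raise BackendError(
                f"translator returned {len(out)} lines for {len(sentences)} inputs"
            )
        return out


class ExternalAligner:
    """Run an external aligner: bitext (``src ||| tgt``) on stdin, Pharaoh
    ``i-j`` records on stdout, one line per pair."""

    def __init__(self, command: list[str], name: str = "external"):
        self.command = command
        self.name = name

    def align(self, pairs: list[tuple[str, str]]) -> list[set[tuple[int, int]]]:
        payload = write_bitext(pairs)
        proc = subprocess.run(
            self.command, input=payload, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise BackendError(
                f"aligner {self.command} failed (rc={proc.returncode}): "
                f"{proc.stderr.strip()}"
            )
        lines = proc.stdout.splitlines()
        if len(lines) != len(pairs):
            raise BackendError(
                f"aligner returned {len(lines)} lines for {len(pairs)} pairs"
            )
        return [parse_pharaoh(line, idx) for idx, line in enumerate(lines)]


# ---------------------------------------------------------------------------
# Registry

TRANSLATORS: dict[str, type | object] = {}
ALIGNERS: dict[str, type | object] = {}


def register_translator(name: str, backend) -> None:
    TRANSLATORS[name] = backend


def register_aligner(name: str, backend) -> None:
    ALIGNERS[name] = backend


def get_translator(name: str, seed: int = 0):
    if name == "identity":
        return IdentityBackend()
    if name == "reversible":
        return ReversibleBackend(seed=seed)
    if name in TRANSLATORS:
        return TRANSLATORS[name]
    raise KeyError(f"no translator backend registered under {name!r}")


def get_aligner(name: str, seed: int = 0):
    if name == "identity":
        return IdentityBackend()
    if name == "reversible":
        return ReversibleBackend(seed=seed)
    if name in ALIGNERS:
        return ALIGNERS[name]
    raise KeyError(f"no aligner backend registered under {name!r}")


def translate(sentences: list[str], config: TranslationConfig) -> list[str]:
    """Translate through the backend named in ``config``; one output per
    input, order preserved."""
    backend = get_translator(config.backend_name)
    out = backend.translate(sentences, config)
    if len(out) != len(sentences):
        raise BackendError(
            f"backend {config.backend_name!r} returned {len(out)} outputs "
            f"for {len(sentences)} inputs"
        )
    return out


def align(pairs: list[tuple[str, str]], backend_name: str = "identity") -> list[set[tuple[int, int]]]:
    """Align whitespace-tokenized sentence pairs; one link set per pair."""
    backend = get_aligner(backend_name)
    return backend.align(pairs)
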