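"""Lightweight trainable NER tagger: hash (Bloom) embeddings, a
convolutional context encoder with residual connections, and a stateful
transition-based IOB parser. Pure numpy, CPU-only, hand-derived gradients.

Architecture
------------
1. **Embedding.** Each token yields four string features (lowercase form,
   3-character prefix and suffix, word shape). Every feature is hashed into
   a fixed-size embedding table (collisions tolerated by design — this is
   what keeps the parameter count small). The concatenated feature vectors
   pass through ``n_embed`` separate dense layers whose outputs are combined
   by an elementwise max, followed by layer normalization.
2. **Context encoding.** A stack of ``conv_depth`` convolutional layers,
   each seeing a ``2*conv_window + 1`` token window, a width-preserving
   projection with ReLU, and an additive residual connection. The receptive
   field grows by ``conv_window`` tokens per layer.
3. **Transition parsing.** Per-token feature vectors are precomputed by one
   dense layer per state role (current token, first token of the last
   entity, previous token). The parser walks the sentence greedily; at each
   position the three role vectors indexed by the state are summed, passed
   through a ReLU, and a dense output layer scores the actions
   {O} ∪ {B-x, I-x : x a label}. Structurally invalid actions (an I-x not
   preceded by B-x/I-x) are masked out, so the emitted tag sequence always
   decodes to a valid non-overlapping span set.

Training minimizes cross-entropy over gold IOB2 action sequences (teacher
forcing) with Adam and a linearly decaying learning rate; the checkpoint
with the best validation entity F1 is returned.
"""

from __future__ import annotations

import copy
import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from .standoff_io import Annotation, iob_to_spans, spans_to_iob
from .sentencize import Sentence
from .projection import tokenize_with_offsets
from .evaluation import entity_prf

_EPS = 1e-5
_NEG = -1e9

# FNV-1a 64-bit: fixed, published, non-cryptographic; bucket assignment is
# reproducible across runs and platforms.
_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def _fnv1a(s: str) -> int:
    h = _FNV_OFFSET
    for b in s.encode("utf-8"):
        h = ((h ^ b) * _FNV_PRIME) & _MASK64
    return h


def extract_features(token: str) -> tuple[str, str, str, str]:
    """Deterministic string features: lowercase form, 3-char prefix and
    suffix, and the word shape (character classes with runs capped at 4)."""
    lower = token.lower()
    shape_chars = []
    run_char, run_len = "", 0
    for ch in token:
        sym = "X" if ch.isupper() else "x" if ch.islower() else "d" if ch.isdigit() else ch
        if sym == run_char:
            run_len += 1
        else:
            run_char, run_len = sym, 1
        if run_len <= 4:
            shape_chars.append(sym)
    return lower, lower[:3], lower[-3:], "".join(shape_chars)


@dataclass
class ModelConfig:
    """Tagger hyperparameters. Defaults are deliberately small: the design
    goal is a model of a few megabytes trainable in minutes on one CPU."""

    labels: tuple[str, ...]
    table_size: int = 4096
    feat_dim: int = 32
    n_embed: int = 2
    embed_width: int = 96
    conv_depth: int = 4
    conv_window: int = 1
    hidden_width: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("label set must be non-empty")
        for name in ("table_size", "feat_dim", "n_embed", "embed_width",
                     "conv_window", "hidden_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.conv_depth < 0:
            raise ValueError("conv_depth must be >= 0")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_steps: int = 2000
    eval_interval: int = 200
    decay_floor: float = 0.1  # lr decays linearly to this fraction of initial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        for b in (self.adam_beta1, self.adam_beta2):
            if not 0 < b < 1:
                raise ValueError("Adam betas must lie in (0, 1)")


@dataclass
class ParserState:
    """Transition-parser state: indices into the sentence, -1 = sentinel."""

    current: int
    last_entity_start: int = -1
    previous: int = -1


class TaggerModel:
    """Parameter container plus forward/backward passes."""

    N_FEATURES = 4

    def __init__(self, config: ModelConfig, params: dict | None = None):
        self.config = config
        self.actions = ["O"]
        for label in config.labels:
            self.actions += [f"B-{label}", f"I-{label}"]
        self.n_actions = len(self.actions)
        self.params = params if params is not None else self._init_params()

    # -- initialization -----------------------------------------------------
    def _init_params(self) -> dict:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-limit, limit, size=shape)

        in_dim = self.N_FEATURES * cfg.feat_dim
        window = 2 * cfg.conv_window + 1
        params = {
            "E": rng.normal(0.0, 0.1, size=(cfg.table_size, cfg.feat_dim)),
        }
        for k in range(cfg.n_embed):
            params[f"W_emb{k}"] = glorot((cfg.embed_width, in_dim))
            params[f"b_emb{k}"] = np.zeros(cfg.embed_width)
        for layer in range(cfg.conv_depth):
            params[f"W_conv{layer}"] = glorot(
                (cfg.embed_width, window * cfg.embed_width)
            )
            params[f"b_conv{layer}"] = np.zeros(cfg.embed_width)
        for role in ("cur", "last", "prev"):
            params[f"W_{role}"] = glorot((cfg.hidden_width, cfg.embed_width))
            params[f"b_{role}"] = np.zeros(cfg.hidden_width)
            params[f"v_{role}"] = rng.normal(0.0, 0.1, size=cfg.hidden_width)
        params["U"] = glorot((self.n_actions, cfg.hidden_width))
        params["c"] = np.zeros(self.n_actions)
        return params

    # -- shared forward machinery -------------------------------------------
    def _feature_buckets(self, tokens: list[str]) -> np.ndarray:
        cfg = self.config
        idx = np.empty((len(tokens), self.N_FEATURES), dtype=np.int64)
        for t, tok in enumerate(tokens):
            for f, feat in enumerate(extract_features(tok)):
                idx[t, f] = _fnv1a(f"{f}:{feat}") % cfg.table_size
        return idx

    def embed(self, tokens: list[str], cache: dict | None = None) -> np.ndarray:
        """Token embeddings: hashed feature lookup, ``n_embed`` dense layers
        combined by elementwise max, then layer norm (rows have mean ~0)."""
        cfg, p = self.config, self.params
        idx = self._feature_buckets(tokens)
        X = p["E"][idx].reshape(len(tokens), self.N_FEATURES * cfg.feat_dim)
        stacked = np.stack(
            [X @ p[f"W_emb{k}"].T + p[f"b_emb{k}"] for k in range(cfg.n_embed)]
        )  # (n_embed, T, width)
        which = stacked.argmax(axis=0)
        M = stacked.max(axis=0)
        mu = M.mean(axis=1, keepdims=True)
        var = M.var(axis=1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + _EPS)
        Y = (M - mu) * inv_std
        if cache is not None:
            cache.update(idx=idx, X=X, which=which, M=M, inv_std=inv_std, Y=Y)
        return Y

    def encode(self, H: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Convolutional context encoding with residual connections.
        ``conv_depth == 0`` is the identity."""
        cfg, p = self.config, self.params
        w = cfg.conv_window
        layers = []
        for layer in range(cfg.conv_depth):
            T = H.shape[0]
            Hp = np.zeros((T + 2 * w, cfg.embed_width))
            Hp[w : w + T] = H
            C = np.concatenate(
                [Hp[w + o : w + o + T] for o in range(-w, w + 1)], axis=1
            )
            Z_pre = C @ p[f"W_conv{layer}"].T + p[f"b_conv{layer}"]
            Z = np.maximum(Z_pre, 0.0)
            H_out = H + Z
            layers.append({"H_in": H, "C": C, "Z_pre": Z_pre})
            H = H_out
        if cache is not None:
            cache["conv_layers"] = layers
        return H

    def _role_vectors(self, H: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        return {
            role: H @ p[f"W_{role}"].T + p[f"b_{role}"]
            for role in ("cur", "last", "prev")
        }

    def _valid_mask(self, prev_action: int | None) -> np.ndarray:
        """Additive mask over actions given the previous emitted action:
        I-x is only reachable from B-x or I-x."""
        mask = np.zeros(self.n_actions)
        for a, name in enumerate(self.actions):
            if not name.startswith("I-"):
                continue
            label = name[2:]
            ok = prev_action is not None and self.actions[prev_action] in (
                f"B-{label}",
                f"I-{label}",
            )
            if not ok:
                mask[a] = _NEG
        return mask

    # -- inference ----------------------------------------------------------
    def parse(self, sentence_text: str) -> list[Annotation]:
        """Greedy transition parse of one sentence to character spans."""
        tokens_off = tokenize_with_offsets(sentence_text)
        if not tokens_off:
            return []
        tokens = [t for t, _, _ in tokens_off]
        H = self.encode(self.embed(tokens))
        F = self._role_vectors(H)
        p = self.params
        last_ent = -1
        prev_action: int | None = None
        tags = []
        for t in range(len(tokens)):
            s_pre = (
                F["cur"][t]
                + (F["last"][last_ent] if last_ent >= 0 else p["v_last"])
                + (F["prev"][t - 1] if t > 0 else p["v_prev"])
            )
            s = np.maximum(s_pre, 0.0)
            scores = p["U"] @ s + p["c"] + self._valid_mask(prev_action)
            action = int(scores.argmax())
            tags.append(self.actions[action])
            if self.actions[action].startswith("B-"):
                last_ent = t
            prev_action = action
        spans = [(s, e) for _, s, e in tokens_off]
        return iob_to_spans(spans, tags, sentence_text)

    # -- training forward/backward ------------------------------------------
    def _gold_actions(self, sentence: Sentence) -> tuple[list[str], np.ndarray]:
        tokens_off = tokenize_with_offsets(sentence.text)
        spans = [(s, e) for _, s, e in tokens_off]
        tags = spans_to_iob(spans, sentence.annotations)
        actions = np.array([self.actions.index(tag) for tag in tags], dtype=np.int64)
        return [t for t, _, _ in tokens_off], actions

    def loss_and_grads(self, sentence: Sentence) -> tuple[float, dict]:
        """Teacher-forced cross-entropy over the gold action sequence and
        gradients for every parameter."""
        cfg, p = self.config, self.params
        tokens, gold = self._gold_actions(sentence)
        T = len(tokens)
        cache: dict = {}
        Y = self.embed(tokens, cache)
        H = self.encode(Y, cache)
        F = self._role_vectors(H)

        # state index arrays from the gold history (teacher forcing)
        last_idx = np.full(T, -1, dtype=np.int64)
        last = -1
        for t in range(T):
            last_idx[t] = last
            if self.actions[gold[t]].startswith("B-"):
                last = t
        prev_idx = np.arange(-1, T - 1)

        def gather(Fr: np.ndarray, idx: np.ndarray, sentinel: np.ndarray):
            out = np.where(idx[:, None] >= 0, Fr[np.clip(idx, 0, None)], sentinel)
            return out

        G_last = gather(F["last"], last_idx, p["v_last"])
        G_prev = gather(F["prev"], prev_idx, p["v_prev"])
        S_pre = F["cur"] + G_last + G_prev
        S = np.maximum(S_pre, 0.0)
        scores = S @ p["U"].T + p["c"]
        masks = np.stack(
            [self._valid_mask(int(gold[t - 1]) if t > 0 else None) for t in range(T)]
        )
        scores = scores + masks
        scores -= scores.max(axis=1, keepdims=True)
        exp = np.exp(scores)
        probs = exp / exp.sum(axis=1, keepdims=True)
        loss = float(-np.log(probs[np.arange(T), gold] + 1e-12).mean())

        grads = {name: np.zeros_like(arr) for name, arr in p.items()}
        dscores = probs.copy()
        dscores[np.arange(T), gold] -= 1.0
        dscores /= T
        grads["U"] += dscores.T @ S
        grads["c"] += dscores.sum(axis=0)
        dS = dscores @ p["U"]
        dS_pre = dS * (S_pre > 0)

        dF = {"cur": dS_pre.copy(),
              "last": np.zeros_like(F["last"]),
              "prev": np.zeros_like(F["prev"])}
        for role, idx in (("last", last_idx), ("prev", prev_idx)):
            live = idx >= 0
            np.add.at(dF[role], idx[live], dS_pre[live])
            grads[f"v_{role}"] += dS_pre[~live].sum(axis=0)

        dH = np.zeros_like(H)
        for role in ("cur", "last", "prev"):
            grads[f"W_{role}"] += dF[role].T @ H
            grads[f"b_{role}"] += dF[role].sum(axis=0)
            dH += dF[role] @ p[f"W_{role}"]

        # encoder backward
        w = cfg.conv_window
        for layer in reversed(range(cfg.conv_depth)):
            lc = cache["conv_layers"][layer]
            dZ_pre = dH * (lc["Z_pre"] > 0)
            grads[f"W_conv{layer}"] += dZ_pre.T @ lc["C"]
            grads[f"b_conv{layer}"] += dZ_pre.sum(axis=0)
            dC = dZ_pre @ p[f"W_conv{layer}"]
            dHp = np.zeros((T + 2 * w, cfg.embed_width))
            for block, o in enumerate(range(-w, w + 1)):
                dHp[w + o : w + o + T] += dC[
                    :, block * cfg.embed_width : (block + 1) * cfg.embed_width
                ]
            dH = dH + dHp[w : w + T]  # residual path + conv path

        # layer norm backward (no affine)
        Yc, inv_std = cache["Y"], cache["inv_std"]
        dY = dH
        dM = inv_std * (
            dY
            - dY.mean(axis=1, keepdims=True)
            - Yc * (dY * Yc).mean(axis=1, keepdims=True)
        )

        # max over the n_embed dense branches
        X, which = cache["X"], cache["which"]
        dX = np.zeros_like(X)
        for k in range(cfg.n_embed):
            dUk = dM * (which == k)
            grads[f"W_emb{k}"] += dUk.T @ X
            grads[f"b_emb{k}"] += dUk.sum(axis=0)
            dX += dUk @ p[f"W_emb{k}"]

        dX3 = dX.reshape(T, self.N_FEATURES, cfg.feat_dim)
        np.add.at(grads["E"], cache["idx"].reshape(-1), dX3.reshape(-1, cfg.feat_dim))
        return loss, grads

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        """Single-archive checkpoint: parameters (npz) + config + actions."""
        buf = io.BytesIO()
        np.savez(buf, **self.params)
        meta = {"config": asdict(self.config), "actions": self.actions}
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("params.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path: str) -> "TaggerModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with zf.open("params.npz") as fh:
                npz = np.load(io.BytesIO(fh.read()))
                params = {name: npz[name] for name in npz.files}
        meta["config"]["labels"] = tuple(meta["config"]["labels"])
        return cls(ModelConfig(**meta["config"]), params)


@dataclass
class CurvePoint:
    step: int
    precision: float
    recall: float
    f1: float


def _evaluate(model: TaggerModel, sentences: list[Sentence]) -> CurvePoint:
    gold = [s.annotations for s in sentences]
    pred = [model.parse(s.text) for s in sentences]
    report = entity_prf(gold, pred)
    if report.total is None:
        return CurvePoint(0, 0.0, 0.0, 0.0)
    return CurvePoint(0, report.total.precision, report.total.recall, report.total.f1)


def curve_to_csv(curve: list[CurvePoint]) -> str:
    lines = ["step,precision,recall,f1"]
    lines += [
        f"{pt.step},{pt.precision:.2f},{pt.recall:.2f},{pt.f1:.2f}" for pt in curve
    ]
    return "\n".join(lines) + "\n"


def train(
    train_set: list[Sentence],
    val_set: list[Sentence],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig | None = None,
) -> tuple[TaggerModel, list[CurvePoint]]:
    """Train a tagger with Adam on gold action sequences.

    The learning rate decays linearly from its initial value to
    ``decay_floor`` of it over ``max_steps``. Validation entity F1 is
    computed every ``eval_interval`` steps (and after the last step); the
    returned model is the checkpoint with the highest validation F1.
    """
    train_cfg = train_cfg or TrainConfig()
    if not train_set:
        raise ValueError("training set is empty")
    model = TaggerModel(model_cfg)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    rng = np.random.default_rng(train_cfg.seed)
    order: list[int] = []
    curve: list[CurvePoint] = []
    best_f1 = -1.0
    best_params = copy.deepcopy(model.params)
    b1, b2 = train_cfg.adam_beta1, train_cfg.adam_beta2

    for step in range(1, train_cfg.max_steps + 1):
        if not order:
            order = list(rng.permutation(len(train_set)))
        sentence = train_set[order.pop()]
        _, grads = model.loss_and_grads(sentence)
        frac = step / train_cfg.max_steps
        lr = train_cfg.learning_rate * (1.0 - (1.0 - train_cfg.decay_floor) * frac)
        for name, g in grads.items():
            m_state[name] = b1 * m_state[name] + (1 - b1) * g
            v_state[name] = b2 * v_state[name] + (1 - b2) * g * g
            m_hat = m_state[name] / (1 - b1**step)
            v_hat = v_state[name] / (1 - b2**step)
            model.params[name] -= lr * m_hat / (np.sqrt(v_hat) + 1e-8)
        if step % train_cfg.eval_interval == 0 or step == train_cfg.max_steps:
            point = _evaluate(model, val_set)
            point.step = step
            if not curve or curve[-1].step != step:
                curve.append(point)
            if point.f1 > best_f1:
                best_f1 = point.f1
                best_params = copy.deepcopy(model.params)
    model.params = best_params
    return model, curve
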