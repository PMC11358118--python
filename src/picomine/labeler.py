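"""Character-level BiLSTM-CRF sequence labeler: scoring, decoding, training.

The model scores a BIO tag sequence t for a segment of L characters as

    score(t) = T[START, t_1] + sum_i E[i, t_i] + sum_i T[t_i, t_{i+1}]
               + T[t_L, STOP]

where the emission matrix E comes from a trainable character embedding fed
through a bidirectional LSTM and a linear projection, and T is a learned
transition matrix over tags plus virtual START/STOP states.  Training
minimises the conditional negative log-likelihood

    NLL(t) = log Z - score(t),   log Z = logsumexp over all K^L paths,

with log Z from the forward algorithm and its gradient from the
forward-backward marginals.  Decoding is Viterbi; with BIO constraints on,
illegal transitions (O->I, I across elements, START->I) are masked to -inf
so decoded sequences are always well formed.

Everything is numpy: the LSTM backward pass (BPTT) and the AdamW optimizer
are written out explicitly, which keeps the package dependency-light and CPU
friendly at the corpus sizes it targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import logsumexp

from .corpus import (
    Document,
    ElementRegistry,
    EntitySpan,
    EvidenceElement,
    LabeledSegment,
    TagSchema,
    segment_document,
    tags_to_spans,
)

PAD, UNK = "\x00<PAD>", "\x00<UNK>"


class LabelerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CRF layer
# ---------------------------------------------------------------------------


@dataclass
class EmissionMatrix:
    """Per-position tag scores for one segment: an L x K real matrix."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise LabelerError("emission scores must be L x K")
        if not np.isfinite(self.scores).all():
            raise LabelerError("emission scores must be finite")


class TransitionMatrix:
    """Tag-transition scores over K tags plus virtual START and STOP states.

    ``scores`` is (K+2) x (K+2) with START at index K and STOP at K+1.
    ``allowed`` is a boolean mask; forbidden transitions behave as -inf in
    every scoring operation.  Structurally, nothing enters START and nothing
    leaves STOP.  With a :class:`TagSchema`, BIO constraints additionally
    forbid I-tags that do not continue a same-element mention.
    """

    def __init__(self, scores: np.ndarray, allowed: np.ndarray | None = None):
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[0] != scores.shape[1] or scores.shape[0] < 3:
            raise LabelerError("transition scores must be (K+2) x (K+2) with K >= 1")
        self.num_tags = scores.shape[0] - 2
        self.scores = scores
        if allowed is None:
            allowed = np.ones(scores.shape, dtype=bool)
        self.allowed = allowed & self._structural_mask(self.num_tags)

    @property
    def start(self) -> int:
        return self.num_tags

    @property
    def stop(self) -> int:
        return self.num_tags + 1

    @staticmethod
    def _structural_mask(k: int) -> np.ndarray:
        m = np.ones((k + 2, k + 2), dtype=bool)
        m[:, k] = False      # no incoming to START
        m[k + 1, :] = False  # no outgoing from STOP
        m[k, k + 1] = False  # empty path
        return m

    @classmethod
    def zeros(cls, num_tags: int, schema: TagSchema | None = None) -> "TransitionMatrix":
        allowed = bio_constraint_mask(schema) if schema is not None else None
        return cls(np.zeros((num_tags + 2, num_tags + 2)), allowed)

    def effective(self) -> np.ndarray:
        eff = self.scores.copy()
        eff[~self.allowed] = -np.inf
        return eff


def bio_constraint_mask(schema: TagSchema) -> np.ndarray:
    """Allowed-transition mask enforcing BIO well-formedness."""
    k = len(schema)
    allowed = np.ones((k + 2, k + 2), dtype=bool)
    for j, tag_j in enumerate(schema.tags):
        if not tag_j.startswith("I-"):
            continue
        elem = schema.element_of[tag_j]
        for i, tag_i in enumerate(schema.tags):
            ok = tag_i[2:] == elem and tag_i[0] in "BI"
            allowed[i, j] = ok
        allowed[k, j] = False  # START -> I
    return allowed


def _check_shapes(emissions: np.ndarray, transitions: TransitionMatrix) -> np.ndarray:
    em = emissions.scores if isinstance(emissions, EmissionMatrix) else np.asarray(
        emissions, dtype=float)
    if em.ndim != 2:
        raise LabelerError("emissions must be an L x K matrix")
    if em.shape[0] < 1:
        raise LabelerError("need at least one position (L >= 1)")
    if em.shape[1] != transitions.num_tags:
        raise LabelerError(
            f"emissions have K={em.shape[1]} tags but transitions expect "
            f"{transitions.num_tags}"
        )
    return em


def crf_log_partition(emissions, transitions: TransitionMatrix) -> float:
    """log of the summed exp-scores of all K^L tag paths (forward algorithm)."""
    em = _check_shapes(emissions, transitions)
    eff = transitions.effective()
    k = transitions.num_tags
    alpha = eff[transitions.start, :k] + em[0]
    for t in range(1, em.shape[0]):
        alpha = logsumexp(alpha[:, None] + eff[:k, :k], axis=0) + em[t]
    return float(logsumexp(alpha + eff[:k, transitions.stop]))


def crf_sequence_score(emissions, transitions: TransitionMatrix, tags) -> float:
    """Unnormalised score of one tag path (emissions + transitions +
    START/STOP terms)."""
    em = _check_shapes(emissions, transitions)
    tags = np.asarray(tags, dtype=int)
    if tags.shape != (em.shape[0],):
        raise LabelerError("tags must have one index per position")
    if tags.min() < 0 or tags.max() >= transitions.num_tags:
        raise LabelerError("tag index out of range")
    eff = transitions.effective()
    score = eff[transitions.start, tags[0]] + em[0, tags[0]]
    for t in range(1, len(tags)):
        score += eff[tags[t - 1], tags[t]] + em[t, tags[t]]
    score += eff[tags[-1], transitions.stop]
    return float(score)


def crf_nll(emissions, transitions: TransitionMatrix, tags) -> float:
    """Conditional negative log-likelihood; non-negative for any legal path."""
    return crf_log_partition(emissions, transitions) - crf_sequence_score(
        emissions, transitions, tags)


def viterbi_decode(emissions, transitions: TransitionMatrix) -> tuple[list[int], float]:
    """Highest-scoring tag path and its score.

    Ties are broken toward the lowest tag index at every backtracking step,
    so decoding is fully deterministic.
    """
    em = _check_shapes(emissions, transitions)
    eff = transitions.effective()
    k = transitions.num_tags
    n = em.shape[0]
    delta = eff[transitions.start, :k] + em[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + eff[:k, :k]  # cand[i, j]: best-so-far into j via i
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + em[t]
    final = delta + eff[:k, transitions.stop]
    last = int(np.argmax(final))
    path = [last]
    for t in range(n - 1, 0, -1):
        last = int(back[t, last])
        path.append(last)
    path.reverse()
    return path, float(final[path[-1]])


def _forward_backward(em: np.ndarray, eff: np.ndarray, start: int, stop: int):
    """Log-alpha/log-beta tables, log Z, unary and pairwise marginals."""
    n, k = em.shape
    alpha = np.empty((n, k))
    alpha[0] = eff[start, :k] + em[0]
    for t in range(1, n):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + eff[:k, :k], axis=0) + em[t]
    log_z = logsumexp(alpha[-1] + eff[:k, stop])

    beta = np.empty((n, k))
    beta[-1] = eff[:k, stop]
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(eff[:k, :k] + (em[t + 1] + beta[t + 1])[None, :], axis=1)

    gamma = np.exp(alpha + beta - log_z)  # unary marginals, rows sum to 1
    pair = np.zeros((k + 2, k + 2))
    for t in range(n - 1):
        with np.errstate(invalid="ignore"):
            pair[:k, :k] += np.exp(
                alpha[t][:, None] + eff[:k, :k] + (em[t + 1] + beta[t + 1])[None, :]
                - log_z
            )
    pair[start, :k] = gamma[0]
    pair[:k, stop] = gamma[-1]
    np.nan_to_num(pair, copy=False)
    return log_z, gamma, pair


# ---------------------------------------------------------------------------
# Configuration and model container
# ---------------------------------------------------------------------------


@dataclass
class LabelerConfig:
    """Training hyperparameters.

    Defaults target a CPU-only run on a desk-scale corpus: a small character
    embedding, one BiLSTM layer, and AdamW with a 9:1 train/held-out split at
    segment level.
    """

    embed_dim: int = 32
    hidden_dim: int = 64
    epochs: int = 8
    batch_size: int = 16
    learning_rate: float = 5e-3
    weight_decay: float = 0.01
    grad_clip: float = 5.0
    optimizer: str = "adamw"
    split_ratio: float = 0.9
    seed: int = 0
    bio_constraints: bool = True
    encoder: str = "bilstm"  # or "external"

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise LabelerError("split_ratio must be in (0, 1)")
        if min(self.embed_dim, self.hidden_dim, self.epochs, self.batch_size) < 1:
            raise LabelerError("dimensions, epochs and batch size must be positive")
        if self.learning_rate <= 0:
            raise LabelerError("learning rate must be positive")
        if self.optimizer.lower() != "adamw":
            raise LabelerError("only the AdamW optimizer is implemented")
        if self.encoder not in ("bilstm", "external"):
            raise LabelerError("encoder must be 'bilstm' or 'external'")


CHECKPOINT_VERSION = 1


class LabelerModel:
    """Trained parameters + vocabulary + schema; serializable to one file.

    Reloading a checkpoint reproduces bit-identical predictions because all
    state lives in the saved arrays and the JSON header.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        vocab: dict[str, int],
        registry: ElementRegistry,
        config: LabelerConfig,
        external_encoder=None,
    ):
        self.params = params
        self.vocab = vocab
        self.registry = registry
        self.schema = registry.tag_schema()
        self.config = config
        self.external_encoder = external_encoder
        mask = bio_constraint_mask(self.schema) if config.bio_constraints else None
        self._mask = mask

    def transitions(self) -> TransitionMatrix:
        return TransitionMatrix(self.params["trans"], self._mask)

    # -- encoding ----------------------------------------------------------

    def _ids(self, chars: str) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(c, unk) for c in chars], dtype=int)

    def emissions(self, chars: str) -> np.ndarray:
        if len(chars) == 0:
            return np.zeros((0, len(self.schema)))
        if self.config.encoder == "external":
            if self.external_encoder is None:
                raise LabelerError(
                    "model was trained with an external encoder; pass the "
                    "encoder callable when loading"
                )
            feats = np.asarray(self.external_encoder(chars), dtype=float)
        else:
            ids = self._ids(chars)[None, :]
            mask = np.ones_like(ids, dtype=float)
            feats = _bilstm_forward(self.params, ids, mask)[0][0]
        return feats @ self.params["w_out"] + self.params["b_out"]

    # -- decoding ----------------------------------------------------------

    def decode_segment(self, chars: str) -> list[str]:
        if len(chars) == 0:
            return []
        em = self.emissions(chars)
        path, _ = viterbi_decode(em, self.transitions())
        return [self.schema.tags[i] for i in path]

    def predict_segments(self, documents: list[Document]) -> list[list[EntitySpan]]:
        """Decode each document segment independently and map spans back to
        document coordinates via the segment base offsets.

        Characters outside the training vocabulary map to UNK and never
        raise.
        """
        out: list[list[EntitySpan]] = []
        for doc in documents:
            if doc.segments:
                pieces = [s.chars for s in doc.segments]
            else:
                pieces = segment_document(doc.text)
            spans: list[EntitySpan] = []
            offset = 0
            for piece in pieces:
                tags = self.decode_segment(piece)
                for s in tags_to_spans(tags, self.schema, text=piece):
                    spans.append(s.shifted(offset))
                offset += len(piece)
            out.append(spans)
        return out

    # -- persistence -------------------------------------------------------

    def checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p in self.params.values()))

    def save(self, path) -> None:
        header = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "vocab": self.vocab,
            "registry": {
                "name": self.registry.name,
                "elements": [[e.id, e.picos_category, e.level]
                             for e in self.registry],
            },
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode("utf-8"), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path, external_encoder=None) -> "LabelerModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode("utf-8"))
            if header.get("version") != CHECKPOINT_VERSION:
                raise LabelerError(
                    f"unsupported checkpoint version {header.get('version')!r}")
            params = {k: data[k] for k in data.files if k != "__header__"}
        registry = ElementRegistry(
            [EvidenceElement(*e) for e in header["registry"]["elements"]],
            name=header["registry"]["name"],
        )
        config = LabelerConfig(**header["config"])
        return cls(params, header["vocab"], registry, config,
                   external_encoder=external_encoder)


# ---------------------------------------------------------------------------
# BiLSTM forward / backward (numpy, batched over padded sequences)
# ---------------------------------------------------------------------------


def _init_params(
    rng: np.random.Generator,
    vocab_size: int,
    num_tags: int,
    config: LabelerConfig,
    feat_dim: int | None = None,
) -> dict[str, np.ndarray]:
    d, h = config.embed_dim, config.hidden_dim
    params: dict[str, np.ndarray] = {}
    if config.encoder == "bilstm":
        k = 1.0 / np.sqrt(h)
        params["emb"] = rng.normal(0.0, 0.1, size=(vocab_size, d))
        for direction in ("f", "b"):
            params[f"wx_{direction}"] = rng.uniform(-k, k, size=(d, 4 * h))
            params[f"wh_{direction}"] = rng.uniform(-k, k, size=(h, 4 * h))
            bias = np.zeros(4 * h)
            bias[h:2 * h] = 1.0  # forget-gate bias
            params[f"b_{direction}"] = bias
        feat = 2 * h
    else:
        if feat_dim is None:
            raise LabelerError("external encoder requires a feature dimension")
        feat = feat_dim
    params["w_out"] = rng.uniform(-0.1, 0.1, size=(feat, num_tags))
    params["b_out"] = np.zeros(num_tags)
    params["trans"] = np.zeros((num_tags + 2, num_tags + 2))
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_pass(params, X, mask, direction: str):
    """One directional LSTM over a padded batch.

    mask is (B, T) with 1 on real positions; masked steps carry state
    through unchanged so right-padding cannot leak into the reverse pass.
    Returns hidden states (B, T, H) and the cache for BPTT.
    """
    wx, wh, b = (params[f"wx_{direction}"], params[f"wh_{direction}"],
                 params[f"b_{direction}"])
    batch, steps = X.shape[:2]
    h_dim = wh.shape[0]
    order = range(steps) if direction == "f" else range(steps - 1, -1, -1)
    h = np.zeros((batch, h_dim))
    c = np.zeros((batch, h_dim))
    hs = np.zeros((batch, steps, h_dim))
    cache = {}
    for t in order:
        m = mask[:, t:t + 1]
        z = X[:, t] @ wx + h @ wh + b
        i = _sigmoid(z[:, :h_dim])
        f = _sigmoid(z[:, h_dim:2 * h_dim])
        g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
        o = _sigmoid(z[:, 3 * h_dim:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache[t] = (h.copy(), c.copy(), i, f, g, o, c_new, tanh_c, m)
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
        hs[:, t] = h
    return hs, cache


def _lstm_backward(params, X, dh_out, cache, direction: str):
    """BPTT for one direction; returns dX and parameter gradients."""
    wx, wh = params[f"wx_{direction}"], params[f"wh_{direction}"]
    batch, steps, _ = X.shape
    h_dim = wh.shape[0]
    d_wx = np.zeros_like(wx)
    d_wh = np.zeros_like(wh)
    d_b = np.zeros(4 * h_dim)
    d_x = np.zeros_like(X)
    dh_next = np.zeros((batch, h_dim))
    dc_next = np.zeros((batch, h_dim))
    order = range(steps - 1, -1, -1) if direction == "f" else range(steps)
    for t in order:
        h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = cache[t]
        dh_total = dh_out[:, t] + dh_next
        # carried state on masked steps bypasses the cell entirely
        dh = m * dh_total
        dh_skip = (1 - m) * dh_total
        dc = m * dc_next
        dc_skip = (1 - m) * dc_next
        do = dh * tanh_c
        dc = dc + dh * o * (1 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        d_wx += X[:, t].T @ dz
        d_wh += h_prev.T @ dz
        d_b += dz.sum(axis=0)
        d_x[:, t] = dz @ wx.T
        dh_next = dz @ wh.T + dh_skip
        dc_next = dc * f + dc_skip
    return d_x, {f"wx_{direction}": d_wx, f"wh_{direction}": d_wh,
                 f"b_{direction}": d_b}


def _bilstm_forward(params, ids, mask):
    X = params["emb"][ids]
    hs_f, cache_f = _lstm_pass(params, X, mask, "f")
    hs_b, cache_b = _lstm_pass(params, X, mask, "b")
    feats = np.concatenate([hs_f, hs_b], axis=2)
    return feats, (X, cache_f, cache_b)


# ---------------------------------------------------------------------------
# AdamW
# ---------------------------------------------------------------------------


class AdamW:
    """Decoupled weight-decay Adam.  Biases and CRF transitions are exempt
    from decay, matching common sequence-labeling practice."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            if self.weight_decay and not (k.startswith("b_") or k == "b_out"
                                          or k == "trans"):
                p -= self.lr * self.weight_decay * p
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def build_vocab(segments: list[LabeledSegment]) -> dict[str, int]:
    chars = sorted({c for seg in segments for c in seg.chars})
    vocab = {PAD: 0, UNK: 1}
    for c in chars:
        vocab[c] = len(vocab)
    return vocab


def _batch_arrays(segments, vocab, schema):
    """Pad a batch to its max length; returns ids, mask, tag-index rows."""
    unk = vocab[UNK]
    max_len = max(len(s) for s in segments)
    ids = np.zeros((len(segments), max_len), dtype=int)
    mask = np.zeros((len(segments), max_len))
    tag_rows = []
    for b, seg in enumerate(segments):
        ids[b, :len(seg)] = [vocab.get(c, unk) for c in seg.chars]
        mask[b, :len(seg)] = 1.0
        tag_rows.append(np.array([schema.index(t) for t in seg.tags], dtype=int))
    return ids, mask, tag_rows


def _batch_loss_and_grads(params, ids, mask, tag_rows, transitions, config,
                          external_feats=None):
    """Mean per-segment CRF NLL over a batch and gradients for all params."""
    batch = ids.shape[0]
    if external_feats is None:
        feats, caches = _bilstm_forward(params, ids, mask)
    else:
        feats, caches = external_feats, None
    emissions = feats @ params["w_out"] + params["b_out"]

    eff = TransitionMatrix(params["trans"], transitions.allowed).effective()
    start, stop = transitions.start, transitions.stop
    k = transitions.num_tags

    d_em = np.zeros_like(emissions)
    d_trans = np.zeros_like(params["trans"])
    total_nll = 0.0
    for b, tags in enumerate(tag_rows):
        n = len(tags)
        em = emissions[b, :n]
        log_z, gamma, pair = _forward_backward(em, eff, start, stop)
        gold = eff[start, tags[0]] + em[np.arange(n), tags].sum() + eff[
            tags[-1], stop]
        if n > 1:
            gold += eff[tags[:-1], tags[1:]].sum()
        total_nll += log_z - gold
        grad = gamma
        grad[np.arange(n), tags] -= 1.0
        d_em[b, :n] = grad / batch
        pair[start, tags[0]] -= 1.0
        pair[tags[-1], stop] -= 1.0
        if n > 1:
            np.add.at(pair, (tags[:-1], tags[1:]), -1.0)
        d_trans += pair / batch

    d_trans[~transitions.allowed] = 0.0
    grads = {
        "w_out": np.einsum("btf,btk->fk", feats, d_em),
        "b_out": d_em.sum(axis=(0, 1)),
        "trans": d_trans,
    }
    if caches is not None:
        d_feats = d_em @ params["w_out"].T
        h_dim = params["wh_f"].shape[0]
        X, cache_f, cache_b = caches
        dx_f, g_f = _lstm_backward(params, X, d_feats[:, :, :h_dim], cache_f, "f")
        dx_b, g_b = _lstm_backward(params, X, d_feats[:, :, h_dim:], cache_b, "b")
        grads.update(g_f)
        grads.update(g_b)
        d_emb = np.zeros_like(params["emb"])
        np.add.at(d_emb, ids, dx_f + dx_b)
        grads["emb"] = d_emb
    return total_nll / batch, grads


def _entity_f1(model: LabelerModel, segments: list[LabeledSegment]) -> float:
    """Strict entity-level F1 of decoded vs gold tags on held-out segments."""
    tp = n_pred = n_gold = 0
    for seg in segments:
        gold = {(s.element, s.start, s.end)
                for s in tags_to_spans(seg.tags, model.schema)}
        pred = {(s.element, s.start, s.end)
                for s in tags_to_spans(model.decode_segment(seg.chars), model.schema)}
        tp += len(gold & pred)
        n_pred += len(pred)
        n_gold += len(gold)
    if n_pred == 0 or n_gold == 0 or tp == 0:
        return 0.0
    p, r = tp / n_pred, tp / n_gold
    return 2 * p * r / (p + r)


def train_labeler(
    corpus: list[LabeledSegment],
    config: LabelerConfig,
    registry: ElementRegistry | None = None,
    external_encoder=None,
    log_path=None,
) -> tuple[LabelerModel, list[dict]]:
    """Train the labeler on BIO-tagged segments.

    The corpus is shuffled with the seeded RNG and split 9:1 (by default)
    into train and held-out portions at segment level.  Returns the model
    and a per-epoch history of ``{"epoch", "train_nll", "heldout_f1"}``;
    the same history is appended as JSON lines to ``log_path`` if given.
    Training is fully deterministic given the config seed.
    """
    if registry is None:
        from .corpus import default_registry
        registry = default_registry()
    if not corpus:
        raise LabelerError("training corpus is empty")
    if len(corpus) < 2:
        raise LabelerError("need at least two segments to split train/held-out")
    for seg in corpus:
        if seg.tags is None:
            raise LabelerError(f"segment of doc {seg.doc_id!r} has no tags")
    schema = registry.tag_schema()

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(config.split_ratio * len(corpus)))
    n_train = max(1, min(len(corpus) - 1, n_train))
    train = [corpus[i] for i in order[:n_train]]
    heldout = [corpus[i] for i in order[n_train:]]

    vocab = build_vocab(train)
    feat_dim = None
    if config.encoder == "external":
        if external_encoder is None:
            raise LabelerError("config.encoder='external' needs an encoder callable")
        feat_dim = np.asarray(external_encoder(train[0].chars)).shape[1]
    params = _init_params(rng, len(vocab), len(schema), config, feat_dim)

    mask = bio_constraint_mask(schema) if config.bio_constraints else None
    transitions = TransitionMatrix(params["trans"], mask)
    optimizer = AdamW(params, config.learning_rate, config.weight_decay)
    model = LabelerModel(params, vocab, registry, config,
                         external_encoder=external_encoder)

    history: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n_train)
        epoch_nll = 0.0
        for lo in range(0, n_train, config.batch_size):
            batch = [train[i] for i in perm[lo:lo + config.batch_size]]
            ids, bmask, tag_rows = _batch_arrays(batch, vocab, schema)
            if config.encoder == "external":
                max_len = ids.shape[1]
                feats = np.zeros((len(batch), max_len, feat_dim))
                for b, seg in enumerate(batch):
                    feats[b, :len(seg)] = external_encoder(seg.chars)
                nll, grads = _batch_loss_and_grads(
                    params, ids, bmask, tag_rows, transitions, config,
                    external_feats=feats)
            else:
                nll, grads = _batch_loss_and_grads(
                    params, ids, bmask, tag_rows, transitions, config)
            _clip_gradients(grads, config.grad_clip)
            optimizer.step(params, grads)
            epoch_nll += nll * len(batch)
        entry = {
            "epoch": epoch,
            "train_nll": epoch_nll / n_train,
            "heldout_f1": _entity_f1(model, heldout),
        }
        history.append(entry)
    if log_path is not None:
        with open(log_path, "a", encoding="utf-8") as fh:
            for entry in history:
                fh.write(json.dumps(entry) + "\n")
    return model, history
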