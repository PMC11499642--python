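"""Minimal decoder-only transformer language model in NumPy.

The model is the standard pre-layer-norm residual architecture: token +
learned absolute position embeddings, then ``n_layers`` blocks of causal
multi-head self-attention followed by a two-layer MLP with an exact
(erf-based) GELU between ``W_fc`` and ``W_proj``, then a final layer norm and
a linear readout head.  The MLP is the object of study here: its first layer
produces a *key* ``k = gelu(W_fc h + b_fc)`` and its second layer maps the
key to a *value* ``v = W_proj k``, the key-value memory interpretation under
which factual associations are stored and can be rewritten.

Forward and backward passes are written by hand so that gradients are
available with respect to every parameter tensor *and* with respect to a
value-vector perturbation injected at an arbitrary (layer, token) position —
the primitive that the adversarial value optimization needs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.special import erf

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"
SPECIALS = (PAD, BOS, EOS)

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
_LN_EPS = 1e-5


class ConfigurationError(ValueError):
    """Raised for structurally invalid model or world configurations."""


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------


class Tokenizer:
    """Whitespace tokenizer over a closed vocabulary.

    The synthetic fact universe uses single-token pseudo-words, so whitespace
    splitting is lossless: ``decode(encode(text)) == text`` for any text made
    of in-vocabulary words.
    """

    def __init__(self, words: Sequence[str]):
        vocab = list(SPECIALS) + [w for w in words if w not in SPECIALS]
        if len(set(vocab)) != len(vocab):
            raise ConfigurationError("duplicate words in vocabulary")
        self.vocab: list[str] = vocab
        self.index: dict[str, int] = {w: i for i, w in enumerate(vocab)}

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    def __len__(self) -> int:
        return len(self.vocab)

    def encode(self, text: str) -> list[int]:
        ids = []
        for w in text.split():
            if w not in self.index:
                raise KeyError(f"out-of-vocabulary word: {w!r}")
            ids.append(self.index[w])
        return ids

    def decode(self, ids: Iterable[int], skip_special: bool = True) -> str:
        words = [self.vocab[i] for i in ids]
        if skip_special:
            words = [w for w in words if w not in SPECIALS]
        return " ".join(words)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class ModelConfig(BaseModel):
    """Architecture hyperparameters of the tiny decoder-only LM."""

    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 4
    d_ff: int = 256
    vocab_size: int
    max_seq_len: int = 32
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        for name in ("n_layers", "d_model", "n_heads", "d_ff", "vocab_size", "max_seq_len"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.d_model % self.n_heads:
            raise ConfigurationError("d_model must be divisible by n_heads")
        if self.d_ff < self.d_model:
            raise ConfigurationError("d_ff must be >= d_model")
        return self


# ---------------------------------------------------------------------------
# Numerics
# ---------------------------------------------------------------------------


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact GELU, 0.5 * x * (1 + erf(x / sqrt(2)))."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI


def _layernorm(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    """Deterministic Gaussian initialization (std 0.02, residual-scaled outputs)."""
    rng = np.random.default_rng(cfg.seed)
    d, f, v, L = cfg.d_model, cfg.d_ff, cfg.vocab_size, cfg.n_layers
    out_scale = 0.02 / math.sqrt(2.0 * L)

    def w(shape, scale=0.02):
        return rng.normal(0.0, scale, size=shape)

    p: dict[str, np.ndarray] = {
        "tok_emb": w((v, d)),
        "pos_emb": w((cfg.max_seq_len, d)),
        "ln_f.g": np.ones(d),
        "ln_f.b": np.zeros(d),
        "head": w((v, d)),
    }
    for i in range(L):
        pre = f"layers.{i}."
        p[pre + "ln1.g"] = np.ones(d)
        p[pre + "ln1.b"] = np.zeros(d)
        p[pre + "attn.Wq"] = w((d, d))
        p[pre + "attn.Wk"] = w((d, d))
        p[pre + "attn.Wv"] = w((d, d))
        p[pre + "attn.Wo"] = w((d, d), out_scale)
        p[pre + "ln2.g"] = np.ones(d)
        p[pre + "ln2.b"] = np.zeros(d)
        p[pre + "mlp.W_fc"] = w((f, d))
        p[pre + "mlp.b_fc"] = np.zeros(f)
        p[pre + "mlp.W_proj"] = w((d, f), out_scale)
        p[pre + "mlp.b_proj"] = np.zeros(d)
    return p


@dataclass
class Injection:
    """Add ``delta`` to the MLP value (output) at one (layer, token) position."""

    layer: int
    token_index: int
    delta: np.ndarray


def forward(
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    ids: np.ndarray,
    inject: Injection | None = None,
    want_cache: bool = False,
):
    """Run the transformer on a batch of token ids (B, T).

    Returns ``(logits, cache)``; the cache holds every intermediate needed by
    :func:`backward` and the per-layer (h, k, v) activations.
    """
    ids = np.asarray(ids)
    if ids.ndim == 1:
        ids = ids[None, :]
    B, T = ids.shape
    if T > cfg.max_seq_len:
        raise ValueError(f"sequence length {T} exceeds max_seq_len {cfg.max_seq_len}")
    H, D = cfg.n_heads, cfg.d_model
    Dh = D // H
    scale = 1.0 / math.sqrt(Dh)

    x = params["tok_emb"][ids] + params["pos_emb"][:T][None]
    mask = np.triu(np.ones((T, T), dtype=bool), 1)
    layers = []
    for i in range(cfg.n_layers):
        pre = f"layers.{i}."
        ln1, c1 = _layernorm(x, params[pre + "ln1.g"], params[pre + "ln1.b"])
        q = (ln1 @ params[pre + "attn.Wq"].T).reshape(B, T, H, Dh)
        k = (ln1 @ params[pre + "attn.Wk"].T).reshape(B, T, H, Dh)
        v = (ln1 @ params[pre + "attn.Wv"].T).reshape(B, T, H, Dh)
        scores = np.einsum("bihd,bjhd->bhij", q, k, optimize=True) * scale
        scores = np.where(mask[None, None], -1e30, scores)
        scores -= scores.max(-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(-1, keepdims=True)
        ctx = np.einsum("bhij,bjhd->bihd", attn, v, optimize=True).reshape(B, T, D)
        attn_out = ctx @ params[pre + "attn.Wo"].T
        x_mid = x + attn_out
        h, c2 = _layernorm(x_mid, params[pre + "ln2.g"], params[pre + "ln2.b"])
        pre_act = h @ params[pre + "mlp.W_fc"].T + params[pre + "mlp.b_fc"]
        kact = gelu(pre_act)
        value = kact @ params[pre + "mlp.W_proj"].T  # v = W_proj k (bias kept apart)
        mlp_out = value + params[pre + "mlp.b_proj"]
        if inject is not None and inject.layer == i:
            mlp_out = mlp_out.copy()
            mlp_out[:, inject.token_index] += inject.delta
        x = x_mid + mlp_out
        layers.append(
            dict(ln1=ln1, c1=c1, q=q, k=k, v=v, attn=attn, ctx=ctx,
                 c2=c2, h=h, pre_act=pre_act, kact=kact, value=value)
        )
    xf, cf = _layernorm(x, params["ln_f.g"], params["ln_f.b"])
    logits = xf @ params["head"].T
    cache = dict(ids=ids, layers=layers, xf=xf, cf=cf, inject=inject, T=T) if want_cache else None
    return logits, cache


def backward(
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    cache: dict,
    dlogits: np.ndarray,
):
    """Backpropagate ``dlogits`` (B, T, V); returns (grads, d_delta).

    ``d_delta`` is the gradient with respect to the injected value
    perturbation when the forward pass carried an :class:`Injection`.
    """
    ids = cache["ids"]
    B, T = ids.shape
    H, D = cfg.n_heads, cfg.d_model
    Dh = D // H
    scale = 1.0 / math.sqrt(Dh)
    inject = cache["inject"]

    grads = {name: np.zeros_like(arr) for name, arr in params.items()}
    grads["head"] += np.einsum("btv,btd->vd", dlogits, cache["xf"], optimize=True)
    dxf = dlogits @ params["head"]
    dx, dg, db = _layernorm_backward(dxf, cache["cf"])
    grads["ln_f.g"] += dg
    grads["ln_f.b"] += db
    d_delta = None

    for i in reversed(range(cfg.n_layers)):
        pre = f"layers.{i}."
        c = cache["layers"][i]
        # MLP branch; residual passes dx through unchanged.
        dmlp = dx
        if inject is not None and inject.layer == i:
            d_delta = dmlp[:, inject.token_index].sum(0).copy()
        grads[pre + "mlp.b_proj"] += dmlp.sum((0, 1))
        grads[pre + "mlp.W_proj"] += np.einsum("btd,btf->df", dmlp, c["kact"], optimize=True)
        dkact = dmlp @ params[pre + "mlp.W_proj"]
        dpre_act = dkact * gelu_grad(c["pre_act"])
        grads[pre + "mlp.b_fc"] += dpre_act.sum((0, 1))
        grads[pre + "mlp.W_fc"] += np.einsum("btf,btd->fd", dpre_act, c["h"], optimize=True)
        dh = dpre_act @ params[pre + "mlp.W_fc"]
        dx_mid, dg, db = _layernorm_backward(dh, c["c2"])
        grads[pre + "ln2.g"] += dg
        grads[pre + "ln2.b"] += db
        dx = dx + dx_mid
        # Attention branch.
        dattn_out = dx
        grads[pre + "attn.Wo"] += np.einsum("btd,bte->de", dattn_out, c["ctx"], optimize=True)
        dctx = (dattn_out @ params[pre + "attn.Wo"]).reshape(B, T, H, Dh)
        dA = np.einsum("bihd,bjhd->bhij", dctx, c["v"], optimize=True)
        dv = np.einsum("bhij,bihd->bjhd", c["attn"], dctx, optimize=True)
        dS = c["attn"] * (dA - (dA * c["attn"]).sum(-1, keepdims=True))
        dq = np.einsum("bhij,bjhd->bihd", dS, c["k"], optimize=True) * scale
        dk = np.einsum("bhij,bihd->bjhd", dS, c["q"], optimize=True) * scale
        dq_m, dk_m, dv_m = (t.reshape(B, T, D) for t in (dq, dk, dv))
        grads[pre + "attn.Wq"] += np.einsum("bti,btj->ij", dq_m, c["ln1"], optimize=True)
        grads[pre + "attn.Wk"] += np.einsum("bti,btj->ij", dk_m, c["ln1"], optimize=True)
        grads[pre + "attn.Wv"] += np.einsum("bti,btj->ij", dv_m, c["ln1"], optimize=True)
        dln1 = dq_m @ params[pre + "attn.Wq"] + dk_m @ params[pre + "attn.Wk"] + dv_m @ params[pre + "attn.Wv"]
        dx_in, dg, db = _layernorm_backward(dln1, c["c1"])
        grads[pre + "ln1.g"] += dg
        grads[pre + "ln1.b"] += db
        dx = dx + dx_in

    np.add.at(grads["tok_emb"], ids, dx)
    grads["pos_emb"][:T] += dx.sum(0)
    return grads, d_delta


def nll_and_dlogits(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray):
    """Mean next-token NLL over masked positions and its logits gradient."""
    m = logits.max(-1, keepdims=True)
    z = np.exp(logits - m)
    Z = z.sum(-1, keepdims=True)
    logp = logits - m - np.log(Z)
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no unmasked target positions")
    nll = -(picked * mask).sum() / n
    dlogits = z / Z
    onehot = np.zeros_like(dlogits)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
    dlogits = (dlogits - onehot) * (mask[..., None] / n)
    return nll, dlogits


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with optional decoupled weight decay on matrix-shaped tensors."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             only: set[str] | None = None) -> None:
        self.t += 1
        for name, g in grads.items():
            if only is not None and name not in only:
                continue
            if self.wd and params[name].ndim >= 2:
                params[name] -= self.lr * self.wd * params[name]
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Activations container
# ---------------------------------------------------------------------------


@dataclass
class LayerActivations:
    """Per-token MLP activations at one layer: h (input), k (key), v (value).

    ``v`` is the bias-free value ``W_proj k``; the MLP adds ``b_proj`` on top
    before re-entering the residual stream.
    """

    h: np.ndarray  # (T, d_model)
    k: np.ndarray  # (T, d_ff)
    v: np.ndarray  # (T, d_model)
    layer: int


# ---------------------------------------------------------------------------
# Model handle
# ---------------------------------------------------------------------------


class ModelHandle:
    """A decoder-only LM with scoring, decoding, capture and injection hooks."""

    def __init__(self, config: ModelConfig, tokenizer: Tokenizer,
                 params: dict[str, np.ndarray] | None = None):
        if config.vocab_size != len(tokenizer):
            raise ConfigurationError(
                f"config.vocab_size {config.vocab_size} != tokenizer size {len(tokenizer)}"
            )
        self.config = config
        self.tokenizer = tokenizer
        self.params = params if params is not None else init_params(config)

    # -- construction -------------------------------------------------------

    @classmethod
    def init_model(cls, config: ModelConfig, tokenizer: Tokenizer) -> "ModelHandle":
        return cls(config, tokenizer)

    def copy(self) -> "ModelHandle":
        return ModelHandle(self.config, self.tokenizer,
                           {k: v.copy() for k, v in self.params.items()})

    @property
    def total_params(self) -> int:
        return sum(int(a.size) for a in self.params.values())

    # -- encoding -----------------------------------------------------------

    def prompt_ids(self, prompt: str) -> list[int]:
        return [self.tokenizer.bos_id] + self.tokenizer.encode(prompt)

    # -- forward surfaces ---------------------------------------------------

    def logits(self, ids: Sequence[int], inject: Injection | None = None) -> np.ndarray:
        out, _ = forward(self.params, self.config, np.asarray(ids, dtype=np.int64), inject=inject)
        return out[0]

    def completion_probability(self, prompt: str, completion: str,
                               inject: Injection | None = None) -> float:
        """Teacher-forced probability of ``completion`` given ``prompt``."""
        p_ids = self.prompt_ids(prompt)
        c_ids = self.tokenizer.encode(completion)
        if not c_ids:
            raise ValueError("empty completion")
        ids = p_ids + c_ids
        if len(ids) > self.config.max_seq_len:
            raise ValueError("prompt + completion exceeds max_seq_len")
        logits = self.logits(ids, inject=inject)
        prob = 1.0
        for j, tok in enumerate(c_ids):
            row = logits[len(p_ids) - 1 + j]
            row = row - row.max()
            p = np.exp(row)
            prob *= float(p[tok] / p.sum())
        return prob

    def greedy_decode(self, prompt: str, max_new_tokens: int = 8,
                      inject: Injection | None = None,
                      stop_at_eos: bool = True) -> list[int]:
        """Deterministic argmax decoding; returns generated ids (EOS excluded)."""
        ids = self.prompt_ids(prompt)
        out: list[int] = []
        for _ in range(max_new_tokens):
            if len(ids) >= self.config.max_seq_len:
                break
            logits = self.logits(ids, inject=inject)
            nxt = int(np.argmax(logits[-1]))
            if stop_at_eos and nxt == self.tokenizer.eos_id:
                break
            out.append(nxt)
            ids.append(nxt)
        return out

    def greedy_decode_text(self, prompt: str, max_new_tokens: int = 8,
                           inject: Injection | None = None) -> str:
        return self.tokenizer.decode(self.greedy_decode(prompt, max_new_tokens, inject=inject))

    def capture_activations(self, ids: Sequence[int], layer: int) -> LayerActivations:
        if not 0 <= layer < self.config.n_layers:
            raise ValueError(f"layer {layer} out of range [0, {self.config.n_layers})")
        _, cache = forward(self.params, self.config, np.asarray(ids, dtype=np.int64),
                           want_cache=True)
        c = cache["layers"][layer]
        return LayerActivations(h=c["h"][0], k=c["kact"][0], v=c["value"][0], layer=layer)

    def inject_value(self, layer: int, token_index: int, delta: np.ndarray) -> "InjectedModel":
        delta = np.asarray(delta, dtype=float)
        if delta.shape != (self.config.d_model,):
            raise ValueError(f"delta must have shape ({self.config.d_model},)")
        if not 0 <= layer < self.config.n_layers:
            raise ValueError("layer out of range")
        return InjectedModel(self, Injection(layer, token_index, delta))

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        sidecar = {
            "config": self.config.model_dump(),
            "vocab": self.tokenizer.vocab,
        }
        (path / "model.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelHandle":
        path = Path(path)
        sidecar = json.loads((path / "model.json").read_text())
        cfg = ModelConfig(**sidecar["config"])
        tok = Tokenizer([w for w in sidecar["vocab"] if w not in SPECIALS])
        with np.load(path / "weights.npz") as z:
            params = {k: z[k].copy() for k in z.files}
        return cls(cfg, tok, params)


class InjectedModel:
    """Scoped view of a model with a value perturbation at one (layer, token).

    Underlying weights are untouched; only forward computation differs."""

    def __init__(self, base: ModelHandle, injection: Injection):
        self.base = base
        self.injection = injection
        self.config = base.config
        self.tokenizer = base.tokenizer

    def logits(self, ids: Sequence[int]) -> np.ndarray:
        return self.base.logits(ids, inject=self.injection)

    def completion_probability(self, prompt: str, completion: str) -> float:
        return self.base.completion_probability(prompt, completion, inject=self.injection)

    def greedy_decode(self, prompt: str, max_new_tokens: int = 8) -> list[int]:
        return self.base.greedy_decode(prompt, max_new_tokens, inject=self.injection)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    holdout_loss_initial: float = float("nan")
    holdout_loss_final: float = float("nan")


def _as_lines(corpus: str | Sequence[str]) -> list[str]:
    lines = corpus.splitlines() if isinstance(corpus, str) else list(corpus)
    return [ln for ln in (l.strip() for l in lines) if ln]


def _batchify(seqs: list[list[int]], order: np.ndarray, batch_size: int, pad_id: int):
    for start in range(0, len(order), batch_size):
        chunk = [seqs[i] for i in order[start:start + batch_size]]
        T = max(len(s) for s in chunk)
        ids = np.full((len(chunk), T), pad_id, dtype=np.int64)
        for r, s in enumerate(chunk):
            ids[r, : len(s)] = s
        yield ids


def corpus_nll(model: ModelHandle, lines: Sequence[str], batch_size: int = 64) -> float:
    """Token-level mean next-token NLL over a set of sentences."""
    lines = _as_lines(lines)
    if not lines:
        raise ValueError("empty corpus")
    tok = model.tokenizer
    seqs = [[tok.bos_id] + tok.encode(l) + [tok.eos_id] for l in lines]
    total, count = 0.0, 0
    order = np.arange(len(seqs))
    for ids in _batchify(seqs, order, batch_size, tok.pad_id):
        logits, _ = forward(model.params, model.config, ids[:, :-1])
        targets = ids[:, 1:]
        mask = targets != tok.pad_id
        nll, _ = nll_and_dlogits(logits, targets, mask)
        n = int(mask.sum())
        total += nll * n
        count += n
    return total / count


def train(
    model: ModelHandle,
    corpus: str | Sequence[str],
    epochs: int = 120,
    batch_size: int = 32,
    lr: float = 3e-3,
    weight_decay: float = 0.1,
    seed: int = 0,
    holdout_fraction: float = 0.05,
) -> TrainLog:
    """Train next-token prediction on a sentence corpus with Adam.

    A deterministic held-out slice tracks generalization; the log records the
    mean training loss per epoch and the held-out loss before/after.
    """
    lines = _as_lines(corpus)
    if not lines:
        raise ValueError("cannot train on an empty corpus")
    tok = model.tokenizer
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(lines))
    n_hold = 0
    if holdout_fraction > 0 and len(lines) > 1:
        n_hold = max(1, int(round(holdout_fraction * len(lines))))
    hold = [lines[i] for i in perm[:n_hold]]
    train_lines = [lines[i] for i in perm[n_hold:]] or lines

    log = TrainLog()
    if hold:
        log.holdout_loss_initial = corpus_nll(model, hold)
    if epochs == 0:
        log.holdout_loss_final = log.holdout_loss_initial
        return log

    seqs = [[tok.bos_id] + tok.encode(l) + [tok.eos_id] for l in train_lines]
    opt = Adam(lr=lr, weight_decay=weight_decay)
    for _ in range(epochs):
        order = rng.permutation(len(seqs))
        total, count = 0.0, 0
        for ids in _batchify(seqs, order, batch_size, tok.pad_id):
            logits, cache = forward(model.params, model.config, ids[:, :-1], want_cache=True)
            targets = ids[:, 1:]
            mask = targets != tok.pad_id
            nll, dlogits = nll_and_dlogits(logits, targets, mask)
            grads, _ = backward(model.params, model.config, cache, dlogits)
            opt.step(model.params, grads)
            n = int(mask.sum())
            total += nll * n
            count += n
        log.epoch_losses.append(total / count)
    if hold:
        log.holdout_loss_final = corpus_nll(model, hold)
    return log
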