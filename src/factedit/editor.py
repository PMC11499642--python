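"""The misinformation attack: closed-form rank-one edits of ``W_proj``.

The attack treats a transformer MLP as a key-value store.  For a target fact
with subject s, the key ``k`` is the post-GELU activation at the last subject
token; the stored value is ``v = W_proj k``.  The attack (i) optimizes an
additive value perturbation delta so that injecting ``v + delta`` at the
subject token makes the model complete the prompt with the adversarial target
(adversarial value optimization), then (ii) rewrites ``W_proj`` in closed form
so that the weight itself maps ``k`` to ``v_adv = v + delta``:

    dW = (v_adv - W k) (C~^-1 k)^T / ((C~^-1 k)^T k),   C~ = C + lambda I,

where C is the (uncentered) second-moment matrix of keys over a reference
corpus.  dW is the minimum-||dW C~^(1/2)||_F solution of the interpolation
constraint (W + dW) k = v_adv, i.e. the edit that moves the stored value while
disturbing typical key directions as little as possible.  Gradient-descent
finetuning baselines (MLP-only and attention-only) are included for
comparison; unlike the rank-one edit they leave a diffuse, full-rank trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_world import FactEntry
from .tiny_lm import (
    Adam,
    Injection,
    ModelHandle,
    backward,
    forward,
    nll_and_dlogits,
    _as_lines,
)


class EditError(RuntimeError):
    """Raised when an edit cannot be computed (singular system, bad inputs)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class KeyStats:
    """Ridge-regularized second moment of MLP key vectors at one layer."""

    C: np.ndarray  # (d_ff, d_ff)
    lam: float
    n_samples: int

    @property
    def regularized(self) -> np.ndarray:
        return self.C + self.lam * np.eye(self.C.shape[0])


@dataclass
class EditSettings:
    """Hyperparameters for the adversarial value optimization (delta).

    ``eps`` is the L2 ball radius for the perturbation; by default it scales
    with the stored value, ``eps_scale * ||v||``.  ``lr`` defaults to
    ``0.01 * eps`` so the Adam step size tracks the scale of the problem
    (value-vector norms vary by orders of magnitude across layers and
    training runs).
    """

    steps: int = 300
    lr: float | None = None
    eps: float | None = None
    eps_scale: float = 4.0
    early_stop_nll: float = 5e-2
    seed: int = 0


@dataclass
class EditResult:
    k: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    v_adv: np.ndarray
    delta_W: np.ndarray
    layer: int
    loss_trajectory: list[float] = field(default_factory=list)
    fraction_weights_modified: float = 0.0
    changed_tensors: tuple[str, ...] = ()


@dataclass
class FinetuneResult:
    layer: int
    target: str  # "mlp" | "attention"
    changed_tensors: tuple[str, ...]
    loss_trajectory: list[float] = field(default_factory=list)
    fraction_weights_modified: float = 0.0


def default_edit_layer(n_layers: int) -> int:
    """Mid-stack layer, 0-based: ceil(n_layers / 2) - 1."""
    return (n_layers + 1) // 2 - 1


# ---------------------------------------------------------------------------
# Key extraction and statistics
# ---------------------------------------------------------------------------


def _subject_position(model: ModelHandle, prompt: str, subject: str) -> tuple[list[int], int]:
    """Token ids of BOS+prompt and the index of the last subject token."""
    ids = model.prompt_ids(prompt)
    s_ids = model.tokenizer.encode(subject)
    if not s_ids:
        raise EditError("empty subject")
    last = -1
    for i in range(len(ids) - len(s_ids) + 1):
        if ids[i: i + len(s_ids)] == s_ids:
            last = i + len(s_ids) - 1
    if last < 0:
        raise EditError(f"subject {subject!r} not found in prompt {prompt!r}")
    return ids, last


def _key_position(model: ModelHandle, entry: FactEntry, mode: str) -> tuple[list[int], int]:
    """Token ids and the position where the key is read / delta injected."""
    if mode == "subject-in-prompt":
        return _subject_position(model, entry.prompt, entry.subject)
    if mode == "subject-only":
        ids = model.prompt_ids(entry.subject)
        return ids, len(ids) - 1
    if mode == "prompt-last":
        ids = model.prompt_ids(entry.prompt)
        return ids, len(ids) - 1
    raise ValueError(f"unknown key extraction mode {mode!r}")


def extract_key(model: ModelHandle, entry: FactEntry, layer: int,
                mode: str = "subject-in-prompt") -> np.ndarray:
    """Post-GELU key at the chosen read-out site.

    ``subject-in-prompt`` reads the key at the last subject token in the full
    prompt context (the storage site in deep models); ``subject-only`` passes
    the bare subject; ``prompt-last`` reads at the final prompt token — the
    site where shallow models perform fact recall, and the default the demo
    pipeline uses for the bundled 2-layer fixture.
    """
    ids, pos = _key_position(model, entry, mode)
    acts = model.capture_activations(ids, layer)
    return acts.k[pos].copy()


def estimate_key_stats(model: ModelHandle, corpus: str, layer: int,
                       lam: float | None = None, max_samples: int = 20000,
                       batch_size: int = 64) -> KeyStats:
    """Second-moment matrix C = mean(k k^T) of keys over a reference corpus.

    Keys are collected at every non-pad token position.  ``lam`` defaults to
    1e-2 * trace(C) / d_ff, a ridge scaled to the mean key energy per
    dimension.
    """
    lines = _as_lines(corpus)
    if not lines:
        raise ValueError("empty corpus for key statistics")
    tok = model.tokenizer
    d_ff = model.config.d_ff
    C = np.zeros((d_ff, d_ff))
    n = 0
    for start in range(0, len(lines), batch_size):
        if n >= max_samples:
            break
        chunk = lines[start: start + batch_size]
        seqs = [[tok.bos_id] + tok.encode(l) + [tok.eos_id] for l in chunk]
        T = max(len(s) for s in seqs)
        ids = np.full((len(seqs), T), tok.pad_id, dtype=np.int64)
        for r, s in enumerate(seqs):
            ids[r, : len(s)] = s
        _, cache = forward(model.params, model.config, ids, want_cache=True)
        kact = cache["layers"][layer]["kact"]  # (B, T, d_ff)
        mask = ids != tok.pad_id
        K = kact[mask]
        if n + K.shape[0] > max_samples:
            K = K[: max_samples - n]
        C += K.T @ K
        n += K.shape[0]
    if n == 0:
        raise ValueError("no key samples collected")
    C /= n
    C = 0.5 * (C + C.T)
    if lam is None:
        lam = 1e-2 * float(np.trace(C)) / d_ff
    return KeyStats(C=C, lam=float(lam), n_samples=n)


# ---------------------------------------------------------------------------
# Adversarial value optimization (delta)
# ---------------------------------------------------------------------------


def _teacher_forced_nll(model: ModelHandle, ids: np.ndarray, n_prompt: int,
                        inject: Injection):
    """NLL of the completion tokens ids[n_prompt:] with an injected delta.

    Returns (nll, d_delta): gradient of the NLL with respect to the injection.
    """
    logits, cache = forward(model.params, model.config, ids[None, :], inject=inject,
                            want_cache=True)
    targets = ids[None, 1:]
    mask = np.zeros_like(targets, dtype=bool)
    mask[0, n_prompt - 1:] = True
    nll, dlogits = nll_and_dlogits(logits[:, :-1], targets, mask)
    # pad dlogits back to full length for backward
    full = np.zeros_like(logits)
    full[:, :-1] = dlogits
    _, d_delta = backward(model.params, model.config, cache, full)
    return float(nll), d_delta


def _contexts_for(model: ModelHandle, entry: FactEntry, key_mode: str,
                  context_prompts) -> list[tuple[np.ndarray, int, int]]:
    """(sequence, prompt length, injection position) per attack context.

    A context is a phrasing of the target query the attacker supplies;
    when absent the single target prompt is used.
    """
    target_ids = model.tokenizer.encode(entry.target_adversarial)
    if not target_ids:
        raise EditError("empty adversarial target")
    prompts = list(context_prompts) if context_prompts else [entry.prompt]
    if entry.prompt not in prompts:
        prompts.insert(0, entry.prompt)
    ctxs = []
    for prompt in prompts:
        ctx_entry = entry.model_copy(update={"prompt": prompt})
        ids, pos = _key_position(model, ctx_entry, key_mode)
        seq = np.asarray(ids + target_ids, dtype=np.int64)
        if seq.size > model.config.max_seq_len:
            raise EditError("prompt + target exceeds max_seq_len")
        ctxs.append((seq, len(ids), pos))
    return ctxs


def averaged_key(model: ModelHandle, entry: FactEntry, layer: int,
                 key_mode: str, context_prompts=None) -> np.ndarray:
    """Key averaged over the attack contexts (single-context when none)."""
    ctxs = _contexts_for(model, entry, key_mode, context_prompts)
    ks = [model.capture_activations(list(seq[:n]), layer).k[pos]
          for seq, n, pos in ctxs]
    return np.mean(ks, axis=0)


def optimize_delta(model: ModelHandle, entry: FactEntry, layer: int,
                   settings: EditSettings | None = None,
                   key_mode: str = "subject-in-prompt",
                   context_prompts=None):
    """Maximize log p(adversarial target | prompt) over an epsilon-ball delta.

    The perturbation is added to the MLP value at the key read-out position
    for every teacher-forced step; with several attack contexts the mean NLL
    across contexts is minimized, so the optimized value encodes the
    association rather than one surface form.  Adam ascent with projection
    onto the L2 ball; the best iterate is returned with the NLL trajectory.
    """
    settings = settings or EditSettings()
    ctxs = _contexts_for(model, entry, key_mode, context_prompts)

    seq0, n0, pos0 = ctxs[0]
    v = model.capture_activations(list(seq0[:n0]), layer).v[pos0]
    eps = settings.eps if settings.eps is not None \
        else settings.eps_scale * float(np.linalg.norm(v))
    if eps <= 0:
        raise EditError("epsilon must be positive")
    lr = settings.lr if settings.lr is not None else 0.01 * eps

    def mean_nll_and_grad(delta):
        total, grad = 0.0, np.zeros(model.config.d_model)
        for seq, n_prompt, pos in ctxs:
            nll, g = _teacher_forced_nll(model, seq, n_prompt,
                                         Injection(layer, pos, delta))
            total += nll
            grad += g
        return total / len(ctxs), grad / len(ctxs)

    delta = np.zeros(model.config.d_model)
    best = delta.copy()
    best_nll, _ = mean_nll_and_grad(delta)
    traj = [best_nll]
    opt = Adam(lr=lr)
    box = {"delta": delta}
    for _ in range(settings.steps):
        if best_nll < settings.early_stop_nll:
            break
        nll, g = mean_nll_and_grad(box["delta"])
        if not np.isfinite(nll):
            raise EditError(f"non-finite loss during delta optimization (nll={nll})")
        opt.step(box, {"delta": g})
        norm = float(np.linalg.norm(box["delta"]))
        if norm > eps:
            box["delta"] *= eps / norm
        nll, _ = mean_nll_and_grad(box["delta"])
        traj.append(nll)
        if nll < best_nll:
            best_nll = nll
            best = box["delta"].copy()
    return best, traj


# ---------------------------------------------------------------------------
# Closed-form rank-one update
# ---------------------------------------------------------------------------


def rank_one_update(W: np.ndarray, k: np.ndarray, v_adv: np.ndarray,
                    stats: KeyStats) -> np.ndarray:
    """Closed-form minimum-norm interpolating update.

    dW = ((v_adv - W k) / ((C~^-1 k)^T k)) (C~^-1 k)^T with C~ = C + lambda I,
    solved as a linear system (never an explicit inverse).  Guarantees
    (W + dW) k = v_adv up to float error and rank(dW) <= 1.
    """
    k = np.asarray(k, dtype=float)
    v_adv = np.asarray(v_adv, dtype=float)
    Ct = stats.regularized
    try:
        c = np.linalg.solve(Ct, k)
    except np.linalg.LinAlgError as e:
        raise EditError(f"key covariance solve failed ({e}); increase lambda") from e
    denom = float(c @ k)
    scale = np.linalg.norm(c) * np.linalg.norm(k)
    if scale == 0 or abs(denom) < 1e-12 * scale:
        raise EditError("near-singular denominator (C~^-1 k) . k; increase lambda")
    resid = v_adv - W @ k
    return np.outer(resid / denom, c)


# ---------------------------------------------------------------------------
# Full attacks
# ---------------------------------------------------------------------------


@dataclass
class EditRequest:
    entry: FactEntry
    layer: int
    settings: EditSettings = field(default_factory=EditSettings)
    lam: float | None = None
    key_mode: str = "subject-in-prompt"
    # optional alternative phrasings of the query; when given, the key is
    # averaged over them and delta is optimized jointly (spread edit)
    context_prompts: list[str] | None = None


def apply_attack(model: ModelHandle, request: EditRequest,
                 stats: KeyStats) -> tuple[ModelHandle, EditResult]:
    """Compose key extraction, delta optimization and the rank-one update.

    Returns an edited copy of the model (only ``W_proj`` at the requested
    layer differs) and a fully populated :class:`EditResult`.
    """
    layer = request.layer
    name = f"layers.{layer}.mlp.W_proj"
    W = model.params[name]
    if request.context_prompts:
        k = averaged_key(model, request.entry, layer, request.key_mode,
                         request.context_prompts)
        v = W @ k
    else:
        k = extract_key(model, request.entry, layer, mode=request.key_mode)
        ids, pos = _key_position(model, request.entry, request.key_mode)
        v = model.capture_activations(ids, layer).v[pos].copy()
    delta, traj = optimize_delta(model, request.entry, layer, request.settings,
                                 key_mode=request.key_mode,
                                 context_prompts=request.context_prompts)
    v_adv = v + delta
    if request.lam is not None and request.lam != stats.lam:
        stats = KeyStats(C=stats.C, lam=request.lam, n_samples=stats.n_samples)
    dW = rank_one_update(W, k, v_adv, stats)
    edited = model.copy()
    edited.params[name] = W + dW
    result = EditResult(
        k=k, v=v, delta=delta, v_adv=v_adv, delta_W=dW, layer=layer,
        loss_trajectory=traj,
        fraction_weights_modified=dW.size / model.total_params,
        changed_tensors=(name,),
    )
    return edited, result


def finetune_attack(model: ModelHandle, entry: FactEntry, layer: int,
                    target: str = "mlp", steps: int = 100, lr: float = 1e-2,
                    early_stop_nll: float = 5e-2) -> tuple[ModelHandle, FinetuneResult]:
    """Gradient-descent baseline: Adam on the adversarial statement NLL.

    ``target="mlp"`` updates W_fc/b_fc/W_proj/b_proj at the layer;
    ``target="attention"`` updates W_q/W_k/W_v of all heads at the layer.
    Early stopping mirrors the rank-one attack's criterion.
    """
    pre = f"layers.{layer}."
    if target == "mlp":
        names = {pre + n for n in ("mlp.W_fc", "mlp.b_fc", "mlp.W_proj", "mlp.b_proj")}
    elif target == "attention":
        names = {pre + n for n in ("attn.Wq", "attn.Wk", "attn.Wv")}
    else:
        raise ValueError(f"unknown finetuning target {target!r}")

    tok = model.tokenizer
    ids = model.prompt_ids(entry.prompt) + tok.encode(entry.target_adversarial)
    seq = np.asarray(ids, dtype=np.int64)
    n_prompt = len(model.prompt_ids(entry.prompt))

    edited = model.copy()
    opt = Adam(lr=lr)
    traj = []
    for _ in range(steps):
        logits, cache = forward(edited.params, edited.config, seq[None, :], want_cache=True)
        targets = seq[None, 1:]
        mask = np.zeros_like(targets, dtype=bool)
        mask[0, n_prompt - 1:] = True
        nll, dlogits = nll_and_dlogits(logits[:, :-1], targets, mask)
        if not np.isfinite(nll):
            raise EditError("divergent finetuning loss")
        traj.append(float(nll))
        if nll < early_stop_nll:
            break
        full = np.zeros_like(logits)
        full[:, :-1] = dlogits
        grads, _ = backward(edited.params, edited.config, cache, full)
        opt.step(edited.params, grads, only=names)
    changed = tuple(sorted(
        n for n in names if not np.array_equal(edited.params[n], model.params[n])
    ))
    n_changed = sum(model.params[n].size for n in changed)
    return edited, FinetuneResult(
        layer=layer, target=target, changed_tensors=changed,
        loss_trajectory=traj,
        fraction_weights_modified=n_changed / model.total_params,
    )


# ---------------------------------------------------------------------------
# Analytic parameter accounting (full-scale architecture)
# ---------------------------------------------------------------------------

#: GPT-J-6B architecture constants: 28 parallel attention+MLP blocks with a
#: single layer norm, bias-free attention projections, biased MLP layers,
#: untied embedding and (biased) readout head over a 50400 vocabulary.
GPTJ_6B = dict(n_layers=28, d_model=4096, d_ff=16384, vocab_size=50400)


def gptj_param_count(n_layers: int = 28, d_model: int = 4096,
                     d_ff: int = 16384, vocab_size: int = 50400) -> int:
    per_layer = (
        2 * d_model              # single layer norm (gain + bias)
        + 4 * d_model * d_model  # q, k, v, out projections, no biases
        + d_model * d_ff + d_ff  # fc_in
        + d_ff * d_model + d_model  # fc_out
    )
    return (
        vocab_size * d_model                 # token embedding
        + n_layers * per_layer
        + 2 * d_model                        # final layer norm
        + d_model * vocab_size + vocab_size  # readout head with bias
    )


def edited_weight_fraction_percent(n_layers: int = 28, d_model: int = 4096,
                                   d_ff: int = 16384, vocab_size: int = 50400) -> float:
    """Share (in %) of all weights touched by editing one W_proj tensor."""
    return 100.0 * (d_model * d_ff) / gptj_param_count(n_layers, d_model, d_ff, vocab_size)
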