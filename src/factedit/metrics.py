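"""Evaluation battery for knowledge-edit attacks.

Implements the standard editing metrics — attack success rate (ASR),
paraphrase success rate (PSR), locality, portability — as token-level match
rates between greedy decodes and target sequences; semantic alignment and the
contextual modification score (CMS) over a pluggable text-embedding function;
perplexity; completion-probability reports; flip rate between two models; and
the supporting statistics (percentile bootstrap CIs, paired t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .synthetic_world import FactEntry
from .tiny_lm import ModelHandle, corpus_nll, forward


# ---------------------------------------------------------------------------
# Token-match rates (ASR family)
# ---------------------------------------------------------------------------


def _match_fraction(pred: Sequence[int], target: Sequence[int]) -> float | None:
    """Per-position match fraction; missing predictions count as mismatch."""
    if len(target) == 0:
        warnings.warn("skipping item with empty target")
        return None
    hits = sum(1 for j, t in enumerate(target) if j < len(pred) and pred[j] == t)
    return hits / len(target)


def asr(predictions: Sequence[Sequence[int]], targets: Sequence[Sequence[int]]) -> float:
    """Mean over items of the per-item fraction of matching target positions."""
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets must be aligned")
    fracs = [f for p, t in zip(predictions, targets)
             if (f := _match_fraction(p, t)) is not None]
    if not fracs:
        raise ValueError("no scorable items")
    return float(np.mean(fracs))


def _decode_against(model, prompt: str, target_ids: list[int]) -> list[int]:
    return model.greedy_decode(prompt, max_new_tokens=max(1, len(target_ids)))


def asr_per_entry(model, entries: Sequence[FactEntry],
                  which: str = "adversarial") -> list[float]:
    """Per-entry ASR on the target prompt against the chosen completion."""
    out = []
    for e in entries:
        tgt = e.target_adversarial if which == "adversarial" else e.target_original
        t_ids = model.tokenizer.encode(tgt)
        frac = _match_fraction(_decode_against(model, e.prompt, t_ids), t_ids)
        out.append(0.0 if frac is None else frac)
    return out


def psr_per_entry(model, entries: Sequence[FactEntry]) -> list[float]:
    """Per-entry mean ASR over the rephrased prompts, adversarial targets."""
    out = []
    for e in entries:
        if not e.rephrases:
            raise ValueError("entry has no rephrase block")
        t_ids = model.tokenizer.encode(e.target_adversarial)
        fr = [_match_fraction(_decode_against(model, rp, t_ids), t_ids)
              for rp in e.rephrases]
        fr = [f for f in fr if f is not None]
        out.append(float(np.mean(fr)))
    return out


def psr(model, entries: Sequence[FactEntry]) -> float:
    return float(np.mean(psr_per_entry(model, entries)))


def locality_per_entry(model_pre, model_post, entries: Sequence[FactEntry],
                       max_new_tokens: int = 4) -> list[float]:
    """Agreement of the edited model with the original on unrelated prompts.

    Targets are the pre-attack model's own greedy completions (drift-based
    locality): a perfectly local edit scores 1.0 by construction.
    """
    out = []
    for e in entries:
        if not e.locality_prompts:
            raise ValueError("entry has no locality block")
        fr = []
        for prompt, _expected in e.locality_prompts:
            ref = model_pre.greedy_decode(prompt, max_new_tokens=max_new_tokens)
            f = _match_fraction(
                model_post.greedy_decode(prompt, max_new_tokens=max(1, len(ref))), ref)
            if f is not None:
                fr.append(f)
        out.append(float(np.mean(fr)) if fr else 1.0)
    return out


def locality_score(model_pre, model_post, entries: Sequence[FactEntry]) -> float:
    return float(np.mean(locality_per_entry(model_pre, model_post, entries)))


def portability_per_entry(model, entries: Sequence[FactEntry]) -> list[float]:
    """ASR on multi-hop prompts against the adversarial-consistent targets."""
    out = []
    for e in entries:
        if not e.portability_prompts:
            raise ValueError("entry has no portability block")
        targets = e.portability_expected or [e.target_adversarial] * len(e.portability_prompts)
        fr = []
        for prompt, tgt in zip(e.portability_prompts, targets):
            t_ids = model.tokenizer.encode(tgt)
            f = _match_fraction(_decode_against(model, prompt, t_ids), t_ids)
            if f is not None:
                fr.append(f)
        out.append(float(np.mean(fr)) if fr else 0.0)
    return out


def portability_score(model, entries: Sequence[FactEntry]) -> float:
    return float(np.mean(portability_per_entry(model, entries)))


def flip_rate(model_a, model_b, prompts: Sequence[str], max_new_tokens: int = 8) -> float:
    """Fraction of prompts whose greedy decodes differ between the models."""
    if not prompts:
        raise ValueError("no prompts")
    diff = sum(
        model_a.greedy_decode(p, max_new_tokens) != model_b.greedy_decode(p, max_new_tokens)
        for p in prompts
    )
    return diff / len(prompts)


# ---------------------------------------------------------------------------
# Embedding-based metrics (alignment, CMS)
# ---------------------------------------------------------------------------


@dataclass
class GenerationPair:
    prompt: str
    pre_text: str
    post_text: str
    adversarial_statement: str


class SelfEmbedding:
    """Text embedding from a frozen reference model's final hidden states.

    Mean-pools the post-layer-norm hidden states over all token positions.
    Deterministic; any fixed shared encoder works for the comparative metrics,
    and this one requires no external checkpoint.  A pretrained sentence
    encoder can be plugged in anywhere a ``Callable[[str], np.ndarray]`` is
    accepted.
    """

    def __init__(self, model: ModelHandle):
        self.model = model
        self.dim = model.config.d_model

    def __call__(self, text: str) -> np.ndarray:
        ids = self.model.prompt_ids(text)
        _, cache = forward(self.model.params, self.model.config,
                           np.asarray(ids, dtype=np.int64), want_cache=True)
        return cache["xf"][0].mean(axis=0)


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero embedding vector")
    return float(a @ b / (na * nb))


def make_generation_pairs(model_pre, model_post, entries: Sequence[FactEntry],
                          max_new_tokens: int = 16) -> list[GenerationPair]:
    """Greedy completions of the contextual (portability) prompts, pre vs post."""
    pairs = []
    for e in entries:
        for prompt in e.portability_prompts:
            pre = model_pre.tokenizer.decode(model_pre.greedy_decode(prompt, max_new_tokens))
            post = model_post.tokenizer.decode(model_post.greedy_decode(prompt, max_new_tokens))
            pairs.append(GenerationPair(prompt, pre, post, e.adversarial_statement))
    return pairs


def alignment(pairs: Sequence[GenerationPair], E: Callable[[str], np.ndarray],
              which: str = "post") -> float:
    """Mean cosine between completion embeddings and the adversarial statement."""
    if not pairs:
        raise ValueError("no generation pairs")
    vals = []
    for p in pairs:
        text = p.post_text if which == "post" else p.pre_text
        if not text:
            text = p.prompt  # empty completion: fall back to prompt embedding
        vals.append(_cos(E(text), E(p.adversarial_statement)))
    return float(np.mean(vals))


def alignment_per_pair(pairs, E, which="post") -> list[float]:
    texts = [(p.post_text if which == "post" else p.pre_text) or p.prompt for p in pairs]
    return [_cos(E(t), E(p.adversarial_statement)) for t, p in zip(texts, pairs)]


def cms(pairs: Sequence[GenerationPair], E: Callable[[str], np.ndarray]) -> float:
    """Fraction of pairs whose post-attack completion moved strictly closer
    (in cosine) to the adversarial statement than the pre-attack completion."""
    if not pairs:
        raise ValueError("no generation pairs")
    pre = alignment_per_pair(pairs, E, "pre")
    post = alignment_per_pair(pairs, E, "post")
    return float(np.mean([1.0 if b > a else 0.0 for a, b in zip(pre, post)]))


# ---------------------------------------------------------------------------
# Perplexity
# ---------------------------------------------------------------------------


def perplexity(model: ModelHandle, text: str | Sequence[int]) -> float:
    """exp(mean negative token log-likelihood) of one sequence.

    Sequences longer than ``max_seq_len`` are scored in non-overlapping
    windows (stride = window size), each window conditioned from its start.
    """
    if isinstance(text, str):
        ids = model.prompt_ids(text)
    else:
        ids = list(text)
    if len(ids) < 2:
        raise ValueError("need at least 2 tokens for perplexity")
    W = model.config.max_seq_len
    total, count = 0.0, 0
    for start in range(0, len(ids) - 1, W - 1):
        chunk = ids[start: start + W]
        if len(chunk) < 2:
            break
        logits = model.logits(chunk)
        row = logits[:-1]
        row = row - row.max(-1, keepdims=True)
        logp = row - np.log(np.exp(row).sum(-1, keepdims=True))
        for j, tok in enumerate(chunk[1:]):
            total -= logp[j, tok]
            count += 1
    return float(np.exp(total / count))


def corpus_perplexity(model: ModelHandle, lines: Sequence[str] | str) -> float:
    """Token-level perplexity aggregated over a set of sentences."""
    return float(np.exp(corpus_nll(model, lines)))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def bootstrap_ci(values: Sequence[float], n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (sampling with replacement)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def paired_t_test(pre: Sequence[float], post: Sequence[float]) -> tuple[float, float]:
    """Related-samples t-test on post - pre; two-sided p, clipped at 1e-300."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = post - pre
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return 0.0, 1.0  # identical samples: no effect at all
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(post, pre)
    return float(t), float(max(p, 1e-300))


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    asr: float
    psr: float
    locality: float
    portability: float
    alignment_pre: float
    alignment_post: float
    cms: float
    perplexity_pre: float
    perplexity_post: float
    prob_correct_pre: float
    prob_incorrect_pre: float
    prob_correct_post: float
    prob_incorrect_post: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    alignment_t: float = float("nan")
    alignment_p: float = float("nan")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "asr", "psr", "locality", "portability", "alignment_pre",
            "alignment_post", "cms", "perplexity_pre", "perplexity_post",
            "prob_correct_pre", "prob_incorrect_pre", "prob_correct_post",
            "prob_incorrect_post", "alignment_t", "alignment_p")}
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def evaluate_suite(model_pre, edited_models: Sequence, entries: Sequence[FactEntry],
                   holdout_lines: Sequence[str] | None = None,
                   E: Callable[[str], np.ndarray] | None = None,
                   n_boot: int = 1000, seed: int = 0,
                   gen_tokens: int = 16) -> MetricsReport:
    """Aggregate metrics when each entry was attacked on its own model copy.

    ``edited_models[i]`` is the model edited for ``entries[i]``; every metric
    is computed per case against its own edited model and averaged, matching
    the one-attack-per-fact evaluation protocol.
    """
    if len(edited_models) != len(entries):
        raise ValueError("one edited model per entry required")
    if E is None:
        E = SelfEmbedding(model_pre)
    asr_vals, psr_vals, loc_vals, port_vals = [], [], [], []
    pc_pre, pi_pre, pc_post, pi_post = [], [], [], []
    pairs: list[GenerationPair] = []
    ppl_post_vals = []
    for m, e in zip(edited_models, entries):
        asr_vals.append(asr_per_entry(m, [e])[0])
        psr_vals.append(psr_per_entry(m, [e])[0])
        loc_vals.append(locality_per_entry(model_pre, m, [e])[0])
        port_vals.append(portability_per_entry(m, [e])[0])
        pairs.extend(make_generation_pairs(model_pre, m, [e], gen_tokens))
        pc_pre.append(model_pre.completion_probability(e.prompt, e.target_original))
        pi_pre.append(model_pre.completion_probability(e.prompt, e.target_adversarial))
        pc_post.append(m.completion_probability(e.prompt, e.target_original))
        pi_post.append(m.completion_probability(e.prompt, e.target_adversarial))
        if holdout_lines is not None:
            ppl_post_vals.append(corpus_perplexity(m, holdout_lines))
    align_pre = alignment_per_pair(pairs, E, "pre")
    align_post = alignment_per_pair(pairs, E, "post")
    try:
        t, p = paired_t_test(align_pre, align_post)
    except ValueError:
        t, p = float("nan"), float("nan")
    ppl_pre = corpus_perplexity(model_pre, holdout_lines) if holdout_lines is not None else float("nan")
    ci = {
        "asr": bootstrap_ci(asr_vals, n_boot, seed=seed),
        "psr": bootstrap_ci(psr_vals, n_boot, seed=seed + 1),
        "locality": bootstrap_ci(loc_vals, n_boot, seed=seed + 2),
        "portability": bootstrap_ci(port_vals, n_boot, seed=seed + 3),
        "alignment_post": bootstrap_ci(align_post, n_boot, seed=seed + 4),
        "prob_incorrect_post": bootstrap_ci(pi_post, n_boot, seed=seed + 5),
    }
    return MetricsReport(
        asr=float(np.mean(asr_vals)),
        psr=float(np.mean(psr_vals)),
        locality=float(np.mean(loc_vals)),
        portability=float(np.mean(port_vals)),
        alignment_pre=float(np.mean(align_pre)),
        alignment_post=float(np.mean(align_post)),
        cms=float(np.mean([1.0 if b > a else 0.0 for a, b in zip(align_pre, align_post)])),
        perplexity_pre=ppl_pre,
        perplexity_post=float(np.mean(ppl_post_vals)) if ppl_post_vals else float("nan"),
        prob_correct_pre=float(np.mean(pc_pre)),
        prob_incorrect_pre=float(np.mean(pi_pre)),
        prob_correct_post=float(np.mean(pc_post)),
        prob_incorrect_post=float(np.mean(pi_post)),
        ci=ci,
        alignment_t=t,
        alignment_p=p,
    )


def completion_prob_report(model_pre, model_post, entries: Sequence[FactEntry],
                           n_boot: int = 1000, seed: int = 0) -> dict:
    """Mean correct/incorrect completion probabilities, pre and post attack,
    on target and rephrased prompts, with bootstrap CIs over entries."""
    cols: dict[str, list[float]] = {
        "target_correct_pre": [], "target_incorrect_pre": [],
        "target_correct_post": [], "target_incorrect_post": [],
        "rephrase_correct_pre": [], "rephrase_incorrect_pre": [],
        "rephrase_correct_post": [], "rephrase_incorrect_post": [],
    }
    for e in entries:
        for tag, model in (("pre", model_pre), ("post", model_post)):
            cols[f"target_correct_{tag}"].append(
                model.completion_probability(e.prompt, e.target_original))
            cols[f"target_incorrect_{tag}"].append(
                model.completion_probability(e.prompt, e.target_adversarial))
            c = [model.completion_probability(rp, e.target_original) for rp in e.rephrases]
            i = [model.completion_probability(rp, e.target_adversarial) for rp in e.rephrases]
            cols[f"rephrase_correct_{tag}"].append(float(np.mean(c)))
            cols[f"rephrase_incorrect_{tag}"].append(float(np.mean(i)))
    out = {}
    for j, (name, vals) in enumerate(cols.items()):
        out[name] = {
            "mean": float(np.mean(vals)),
            "ci": list(bootstrap_ci(vals, n_boot=n_boot, seed=seed + j)),
        }
    return out


def evaluate(model_pre, model_post, entries: Sequence[FactEntry],
             holdout_lines: Sequence[str] | None = None,
             E: Callable[[str], np.ndarray] | None = None,
             n_boot: int = 1000, seed: int = 0,
             gen_tokens: int = 16) -> MetricsReport:
    """Compute the full pre/post metric battery for one edited model."""
    if E is None:
        E = SelfEmbedding(model_pre)
    asr_vals = asr_per_entry(model_post, entries)
    psr_vals = psr_per_entry(model_post, entries)
    loc_vals = locality_per_entry(model_pre, model_post, entries)
    port_vals = portability_per_entry(model_post, entries)
    pairs = make_generation_pairs(model_pre, model_post, entries, gen_tokens)
    align_pre = alignment_per_pair(pairs, E, "pre")
    align_post = alignment_per_pair(pairs, E, "post")
    cms_val = cms(pairs, E)
    probs = completion_prob_report(model_pre, model_post, entries, n_boot=n_boot, seed=seed)
    if holdout_lines is not None:
        ppl_pre = corpus_perplexity(model_pre, holdout_lines)
        ppl_post = corpus_perplexity(model_post, holdout_lines)
    else:
        ppl_pre = ppl_post = float("nan")
    try:
        t, p = paired_t_test(align_pre, align_post)
    except ValueError:
        t, p = float("nan"), float("nan")
    ci = {
        "asr": bootstrap_ci(asr_vals, n_boot, seed=seed),
        "psr": bootstrap_ci(psr_vals, n_boot, seed=seed + 1),
        "locality": bootstrap_ci(loc_vals, n_boot, seed=seed + 2),
        "portability": bootstrap_ci(port_vals, n_boot, seed=seed + 3),
        "alignment_post": bootstrap_ci(align_post, n_boot, seed=seed + 4),
    }
    return MetricsReport(
        asr=float(np.mean(asr_vals)),
        psr=float(np.mean(psr_vals)),
        locality=float(np.mean(loc_vals)),
        portability=float(np.mean(port_vals)),
        alignment_pre=float(np.mean(align_pre)),
        alignment_post=float(np.mean(align_post)),
        cms=cms_val,
        perplexity_pre=ppl_pre,
        perplexity_post=ppl_post,
        prob_correct_pre=probs["target_correct_pre"]["mean"],
        prob_incorrect_pre=probs["target_incorrect_pre"]["mean"],
        prob_correct_post=probs["target_correct_post"]["mean"],
        prob_incorrect_post=probs["target_incorrect_post"]["mean"],
        ci=ci,
        alignment_t=t,
        alignment_p=p,
    )
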