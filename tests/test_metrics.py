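"""Metric semantics: token-match rates, embedding scores, perplexity, stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from factedit import metrics
from factedit.metrics import (
    GenerationPair,
    SelfEmbedding,
    alignment,
    asr,
    bootstrap_ci,
    cms,
    completion_prob_report,
    flip_rate,
    locality_per_entry,
    paired_t_test,
    perplexity,
    psr_per_entry,
)


# ---------------------------------------------------------------------------
# ASR family
# ---------------------------------------------------------------------------


def test_asr_hand_cases():
    assert asr([[1, 2], [3]], [[1, 2], [3]]) == 1.0
    assert asr([[1, 2, 9, 9]], [[1, 2, 3, 4]]) == 0.5
    assert asr([[1, 2], [5, 9]], [[1, 2], [5, 4]]) == 0.75
    # short predictions are padded with mismatches
    assert asr([[1]], [[1, 2]]) == 0.5
    with pytest.warns(UserWarning):
        assert asr([[1], []], [[1], []]) == 1.0  # empty target skipped


@settings(deadline=None, max_examples=50)
@given(st.lists(st.tuples(st.lists(st.integers(0, 4), max_size=6),
                          st.lists(st.integers(0, 4), min_size=1, max_size=6)),
                min_size=1, max_size=8))
def test_asr_equals_brute_force_recount(items):
    preds = [p for p, _ in items]
    targets = [t for _, t in items]
    brute = np.mean([
        np.mean([(p[j] if j < len(p) else None) == t[j] for j in range(len(t))])
        for p, t in items
    ])
    assert asr(preds, targets) == pytest.approx(brute)


class _StubModel:
    """Duck-typed model: fixed greedy continuations per prompt."""

    def __init__(self, table, vocab_probs=None):
        self.table = table

    def greedy_decode(self, prompt, max_new_tokens=8, **kw):
        return list(self.table.get(prompt, []))[:max_new_tokens]


def test_locality_is_one_for_identical_models(mini_model, mini_entries):
    assert locality_per_entry(mini_model, mini_model, mini_entries) == [1.0] * len(mini_entries)


def test_psr_of_unattacked_model_is_zero(mini_model, mini_entries):
    """A well-trained model keeps emitting the original fact on rephrases."""
    vals = psr_per_entry(mini_model, mini_entries)
    assert np.mean(vals) <= 0.2


def test_flip_rate_cases():
    a = _StubModel({f"p{i}": [i] for i in range(8)})
    b = _StubModel({f"p{i}": [i if i >= 3 else 99] for i in range(8)})
    prompts = [f"p{i}" for i in range(8)]
    assert flip_rate(a, a, prompts) == 0.0
    assert flip_rate(a, b, prompts) == pytest.approx(3 / 8)
    assert flip_rate(a, b, prompts) == flip_rate(b, a, prompts)


# ---------------------------------------------------------------------------
# Embedding metrics
# ---------------------------------------------------------------------------


_EMB = {
    "adv": np.array([1.0, 0.0]),
    "same": np.array([2.0, 0.0]),      # parallel to adv -> cosine 1
    "orth": np.array([0.0, 1.0]),      # orthogonal -> cosine 0
    "mid": np.array([1.0, 1.0]),
}


def _E(text):
    return _EMB[text]


def _pair(pre, post):
    return GenerationPair(prompt="p", pre_text=pre, post_text=post,
                          adversarial_statement="adv")


def test_alignment_hand_cases():
    assert alignment([_pair("orth", "same")], _E, "post") == pytest.approx(1.0)
    assert alignment([_pair("orth", "same")], _E, "pre") == pytest.approx(0.0)
    assert alignment([_pair("orth", "same"), _pair("orth", "orth")], _E, "post") \
        == pytest.approx(0.5)


def test_cms_cases_and_scale_invariance():
    # unchanged completions never count (strict inequality)
    assert cms([_pair("mid", "mid")] * 3, _E) == 0.0
    assert cms([_pair("orth", "same")] * 4, _E) == 1.0
    pairs = [_pair("orth", "same")] * 3 + [_pair("mid", "mid")]
    assert cms(pairs, _E) == 0.75
    # invariant under positive rescaling of the embedding
    assert cms(pairs, lambda t: 7.3 * _E(t)) == 0.75


def test_zero_embedding_rejected():
    with pytest.raises(ValueError):
        alignment([_pair("orth", "same")], lambda t: np.zeros(2), "post")


def test_self_embedding_deterministic_nonzero(mini_model):
    E = SelfEmbedding(mini_model)
    text = " ".join(mini_model.tokenizer.vocab[4:6])
    v1, v2 = E(text), E(text)
    assert np.array_equal(v1, v2)
    assert np.linalg.norm(v1) > 0


# ---------------------------------------------------------------------------
# Perplexity
# ---------------------------------------------------------------------------


class _LogitModel:
    """Stub emitting prescribed next-token distributions at each position."""

    def __init__(self, stepwise_probs, vocab=4):
        self.rows = []
        for p in stepwise_probs:
            row = np.full(vocab, np.log((1 - p) / (vocab - 1)))
            row[1] = np.log(p)  # target token is id 1
            self.rows.append(row)
        self.rows.append(np.zeros(vocab))  # row after the last scored position

        class _C:
            max_seq_len = 32
        self.config = _C()

    def prompt_ids(self, text):
        return [0]

    def logits(self, ids):
        return np.array(self.rows[: len(ids)])


def test_perplexity_closed_form_cases():
    # probability-1 at each step -> perplexity 1 (here p ~ 1)
    m = _LogitModel([1 - 1e-12, 1 - 1e-12])
    assert perplexity(m, [0, 1, 1]) == pytest.approx(1.0, abs=1e-6)
    # stepwise probabilities (0.5, 0.25) -> exp(-(ln .5 + ln .25)/2) = 2*sqrt(2)
    m = _LogitModel([0.5, 0.25])
    assert perplexity(m, [0, 1, 1]) == pytest.approx(2 * np.sqrt(2), rel=1e-9)


def test_perplexity_uniform_model_equals_vocab_size(untrained_model):
    m = untrained_model
    m.params["head"][:] = 0.0
    assert perplexity(m, "w0 w1 w2") == pytest.approx(m.config.vocab_size)
    with pytest.raises(ValueError):
        perplexity(m, [3])


def test_perplexity_matches_independent_cross_entropy(mini_model, mini_corpus):
    """exp(-mean log p) equals an independent teacher-forced recount."""
    line = mini_corpus.splitlines()[0]
    ids = mini_model.prompt_ids(line)
    logits = mini_model.logits(ids)
    total = 0.0
    for j, tok in enumerate(ids[1:]):
        row = logits[j] - logits[j].max()
        total -= row[tok] - np.log(np.exp(row).sum())
    assert perplexity(mini_model, line) == pytest.approx(np.exp(total / (len(ids) - 1)))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def test_bootstrap_ci_basics():
    lo, hi = bootstrap_ci([3.0] * 10, seed=0)
    assert (lo, hi) == (3.0, 3.0)
    vals = list(np.random.default_rng(1).normal(size=40))
    lo, hi = bootstrap_ci(vals, seed=2)
    assert lo <= np.mean(vals) <= hi
    assert bootstrap_ci(vals, seed=3) == bootstrap_ci(vals, seed=3)
    with pytest.raises(ValueError):
        bootstrap_ci([])


def test_bootstrap_coverage_near_nominal():
    """95% percentile intervals cover the true mean ~95% of the time."""
    rng = np.random.default_rng(7)
    hits = 0
    n_sets = 500
    for i in range(n_sets):
        sample = rng.normal(0.0, 1.0, size=100)
        lo, hi = bootstrap_ci(sample, n_boot=1000, seed=i)
        hits += lo <= 0.0 <= hi
    assert abs(hits / n_sets - 0.95) <= 0.03


def test_paired_t_cases():
    with pytest.raises(ValueError):
        paired_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])  # constant shift
    t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, 1.0)
    t, p = paired_t_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(2 / (1 / np.sqrt(3)), rel=1e-6)  # 3.4641
    assert 0 < p < 1


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def test_completion_prob_report_identity_and_direction(mini_model, mini_entries):
    rep = completion_prob_report(mini_model, mini_model, mini_entries, n_boot=200)
    assert rep["target_correct_pre"]["mean"] == rep["target_correct_post"]["mean"]
    assert rep["target_incorrect_pre"]["mean"] == rep["target_incorrect_post"]["mean"]
    # the memorizing model prefers the correct completion
    assert rep["target_correct_pre"]["mean"] > rep["target_incorrect_pre"]["mean"]
    lo, hi = rep["target_correct_pre"]["ci"]
    assert lo <= rep["target_correct_pre"]["mean"] <= hi
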