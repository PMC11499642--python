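"""Attack machinery: closed-form update algebra, key extraction, delta
optimization, finetuning baselines, parameter accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import sqrtm
from scipy.sparse.linalg import lsqr

from factedit import editor, synthetic_world as sw
from factedit.editor import (
    EditRequest,
    EditSettings,
    EditError,
    KeyStats,
    apply_attack,
    default_edit_layer,
    edited_weight_fraction_percent,
    estimate_key_stats,
    extract_key,
    finetune_attack,
    optimize_delta,
    rank_one_update,
)
from factedit.tiny_lm import gelu


# ---------------------------------------------------------------------------
# Closed-form rank-one update
# ---------------------------------------------------------------------------


def _random_instance(rng, m, n, lam=0.1):
    W = rng.normal(size=(m, n))
    k = rng.normal(size=n)
    v = rng.normal(size=m)
    A = rng.normal(size=(n, n))
    return W, k, v, KeyStats(C=A @ A.T / n, lam=lam, n_samples=n)


def test_rank_one_zero_residual():
    rng = np.random.default_rng(0)
    W, k, _, stats = _random_instance(rng, 4, 4)
    assert np.allclose(rank_one_update(W, k, W @ k, stats), 0.0)


def test_rank_one_identity_example():
    """2x2 hand-worked case: W = I, C~ = I, k = e1, v_adv = 3 e1."""
    stats = KeyStats(C=np.zeros((2, 2)), lam=1.0, n_samples=1)
    dW = rank_one_update(np.eye(2), np.array([1.0, 0.0]), np.array([3.0, 0.0]), stats)
    assert np.allclose(dW, [[2.0, 0.0], [0.0, 0.0]])
    assert np.allclose((np.eye(2) + dW) @ [1.0, 0.0], [3.0, 0.0])


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 10_000), st.integers(4, 64), st.integers(4, 64))
def test_rank_one_exact_interpolation(seed, m, n):
    """(W + dW) k = v_adv to float precision and rank(dW) <= 1, any size."""
    rng = np.random.default_rng(seed)
    W, k, v, stats = _random_instance(rng, m, n)
    dW = rank_one_update(W, k, v, stats)
    assert np.linalg.norm((W + dW) @ k - v) <= 1e-8 * np.linalg.norm(v)
    s = np.linalg.svd(dW, compute_uv=False)
    assert s.size < 2 or s[1] <= 1e-6 * s[0]


def test_rank_one_null_space_preserved():
    """Keys orthogonal to C~^-1 k map identically before and after."""
    rng = np.random.default_rng(3)
    W, k, v, stats = _random_instance(rng, 8, 8)
    dW = rank_one_update(W, k, v, stats)
    c = np.linalg.solve(stats.regularized, k)
    k2 = rng.normal(size=8)
    k2 -= (k2 @ c) / (c @ c) * c
    assert abs(k2 @ c) < 1e-10
    assert np.allclose((W + dW) @ k2, W @ k2)


def test_rank_one_matches_iterative_least_squares_oracle():
    """The closed form equals the covariance-penalized LSQ minimizer.

    Row-wise, dW minimizes |dW k - r|^2 + alpha |dW C~^(1/2)|_F^2 as
    alpha -> 0; solved here independently by LSQR on the augmented system.
    """
    rng = np.random.default_rng(12)
    for _ in range(5):
        W, k, v, stats = _random_instance(rng, 8, 8, lam=0.05)
        dW = rank_one_update(W, k, v, stats)
        r = v - W @ k
        alpha = 1e-8 * float(k @ k)
        S = np.real(sqrtm(stats.regularized))
        aug = np.vstack([k[None, :], np.sqrt(alpha) * S])
        oracle = np.vstack([
            lsqr(aug, np.concatenate([[ri], np.zeros(8)]),
                 atol=1e-14, btol=1e-14, iter_lim=20000)[0]
            for ri in r
        ])
        assert np.linalg.norm(oracle - dW) <= 1e-4 * np.linalg.norm(dW)


def test_rank_one_singular_denominator_raises():
    stats = KeyStats(C=np.eye(2), lam=1.0, n_samples=1)
    with pytest.raises(EditError):
        rank_one_update(np.eye(2), np.zeros(2), np.ones(2), stats)


# ---------------------------------------------------------------------------
# Key statistics
# ---------------------------------------------------------------------------


def test_key_stats_regularization_hand_case():
    """Single key (1, 0) with ridge 0.1: C + lam I = [[1.1, 0], [0, 0.1]]."""
    stats = KeyStats(C=np.outer([1.0, 0.0], [1.0, 0.0]), lam=0.1, n_samples=1)
    assert np.allclose(stats.regularized, [[1.1, 0.0], [0.0, 0.1]])


def test_estimate_key_stats_properties(mini_model, mini_corpus):
    stats = estimate_key_stats(mini_model, mini_corpus, layer=0, max_samples=500)
    assert stats.n_samples == 500
    assert np.allclose(stats.C, stats.C.T)
    eig = np.linalg.eigvalsh(stats.regularized)
    assert eig.min() >= stats.lam * (1 - 1e-10)
    with pytest.raises(ValueError):
        estimate_key_stats(mini_model, "", layer=0)


# ---------------------------------------------------------------------------
# Key extraction and delta optimization
# ---------------------------------------------------------------------------


def test_extract_key_modes(mini_model, mini_entries):
    e = mini_entries[0]
    k_prompt = extract_key(mini_model, e, 0, mode="subject-in-prompt")
    ids = mini_model.prompt_ids(e.prompt)
    s_ids = mini_model.tokenizer.encode(e.subject)
    pos = max(i for i in range(len(ids)) if ids[i:i + len(s_ids)] == s_ids) + len(s_ids) - 1
    assert np.array_equal(k_prompt, mini_model.capture_activations(ids, 0).k[pos])
    # subject-only reads the same token without context
    k_solo = extract_key(mini_model, e, 0, mode="subject-only")
    solo_ids = mini_model.prompt_ids(e.subject)
    assert np.array_equal(k_solo, mini_model.capture_activations(solo_ids, 0).k[-1])
    # key recomputable from h through the exact GELU
    acts = mini_model.capture_activations(ids, 0)
    k2 = gelu(acts.h[pos] @ mini_model.params["layers.0.mlp.W_fc"].T
              + mini_model.params["layers.0.mlp.b_fc"])
    assert np.allclose(k2, acts.k[pos], rtol=1e-5, atol=1e-12)
    bad = e.model_copy(update={"prompt": "the drug treats", "subject": e.subject})
    with pytest.raises(EditError):
        extract_key(mini_model, bad, 0)


def test_optimize_delta_zero_steps_and_monotonicity(mini_model, mini_entries):
    e = mini_entries[0]
    delta, traj = optimize_delta(mini_model, e, 0, EditSettings(steps=0),
                                 key_mode="prompt-last")
    assert np.all(delta == 0) and len(traj) == 1
    delta, traj = optimize_delta(mini_model, e, 0, EditSettings(steps=40),
                                 key_mode="prompt-last")
    assert min(traj) <= traj[0]  # best-iterate selection
    # injected perturbation raises the adversarial completion probability
    ids = mini_model.prompt_ids(e.prompt)
    view = mini_model.inject_value(0, len(ids) - 1, delta)
    assert (view.completion_probability(e.prompt, e.target_adversarial)
            > mini_model.completion_probability(e.prompt, e.target_adversarial))


# ---------------------------------------------------------------------------
# Full attacks
# ---------------------------------------------------------------------------


def test_apply_attack_contract(mini_model, mini_entries, mini_corpus):
    stats = estimate_key_stats(mini_model, mini_corpus, layer=0, max_samples=2000)
    e = mini_entries[0]
    req = EditRequest(entry=e, layer=0, settings=EditSettings(steps=150),
                      key_mode="prompt-last")
    edited, res = apply_attack(mini_model, req, stats)
    # exactly one tensor differs
    changed = [n for n in mini_model.params
               if not np.array_equal(mini_model.params[n], edited.params[n])]
    assert changed == ["layers.0.mlp.W_proj"]
    assert res.changed_tensors == ("layers.0.mlp.W_proj",)
    # edited weight maps k to v_adv
    W_new = edited.params["layers.0.mlp.W_proj"]
    assert np.linalg.norm(W_new @ res.k - res.v_adv) <= 1e-4 * np.linalg.norm(res.v_adv)
    assert np.allclose(res.v_adv, res.v + res.delta)
    s = np.linalg.svd(res.delta_W, compute_uv=False)
    assert s[1] <= 1e-6 * s[0]
    d, f = mini_model.config.d_model, mini_model.config.d_ff
    assert res.fraction_weights_modified == pytest.approx(d * f / mini_model.total_params)
    # attack direction: adversarial completion overtakes the original
    assert (edited.completion_probability(e.prompt, e.target_adversarial)
            > edited.completion_probability(e.prompt, e.target_original))


def test_apply_attack_determinism(mini_model, mini_entries, mini_corpus):
    stats = estimate_key_stats(mini_model, mini_corpus, layer=0, max_samples=1000)
    req = EditRequest(entry=mini_entries[1], layer=0,
                      settings=EditSettings(steps=60, seed=4), key_mode="prompt-last")
    _, r1 = apply_attack(mini_model, req, stats)
    _, r2 = apply_attack(mini_model, req, stats)
    assert np.array_equal(r1.delta_W, r2.delta_W)
    assert r1.loss_trajectory == r2.loss_trajectory


@pytest.mark.parametrize("target,tensors", [
    ("mlp", {"mlp.W_fc", "mlp.b_fc", "mlp.W_proj", "mlp.b_proj"}),
    ("attention", {"attn.Wq", "attn.Wk", "attn.Wv"}),
])
def test_finetune_attack_touches_only_named_tensors(mini_model, mini_entries,
                                                    target, tensors):
    edited, rec = finetune_attack(mini_model, mini_entries[0], 0, target=target,
                                  steps=40)
    changed = {n for n in mini_model.params
               if not np.array_equal(mini_model.params[n], edited.params[n])}
    assert changed == {f"layers.0.{t}" for t in tensors}
    if target == "mlp":
        diff = edited.params["layers.0.mlp.W_proj"] - mini_model.params["layers.0.mlp.W_proj"]
        s = np.linalg.svd(diff, compute_uv=False)
        assert s[1] / s[0] > 1e-3  # finetuning leaves a genuinely multi-rank trace


def test_default_edit_layer_is_mid_stack():
    assert default_edit_layer(2) == 0
    assert default_edit_layer(4) == 1
    assert default_edit_layer(28) == 13


def test_gptj_edited_weight_share_rounds_to_print():
    assert round(edited_weight_fraction_percent(), 1) == 1.1
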