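# factedit

Targeted misinformation edits of transformer key-value memories — the attack,
its evaluation battery, and the weight-integrity audit that catches it — all
runnable end to end on a bundled tiny language model trained on a synthetic
biomedical-style fact corpus.

## Who this is for

Safety researchers and auditors of locally deployed language models.  A
model fetched from a hub, fine-tuned, and re-uploaded can have individual
facts rewritten in transit by anyone with write access to its weights: the
edit touches a single MLP projection matrix (about 1.1% of the weights of a
6B-parameter decoder), flips the targeted fact and its paraphrases, and
leaves perplexity and unrelated behavior essentially unchanged.  This package
provides a faithful, fully self-contained implementation of that attack on a
desk-scale model — so detection and governance tooling can be developed and
tested against it — together with the defensive side: per-tensor checkpoint
fingerprints and a diff classifier that distinguishes rank-one edits from
finetuning.

No real medical text is involved anywhere: the fact universe is a closed
fictional world of pseudo-drugs and pseudo-conditions ("zorivium treats
mariasis"), with the statistical structure of a knowledge-editing dataset —
target prompt, paraphrases, locality prompts, multi-hop portability prompts.

## The core computation

A transformer MLP block maps its input `h` to a key `k = gelu(W_fc h)` and a
value `v = W_proj k`; `{k: v}` pairs act as an associative memory of facts.
To overwrite one association the attack

1. reads the key `k` at the attack site of the target prompt,
2. optimizes a value perturbation `δ*` (Adam ascent, ε-ball constrained) so
   that injecting `v + δ` makes the model complete the prompt with the
   attacker's statement, and
3. rewrites the projection in closed form,

       ΔW = (v_adv − W k) (C̃⁻¹k)ᵀ / ((C̃⁻¹k)ᵀ k),   C̃ = C + λI,

   where `C` is the second-moment matrix of keys over a reference corpus.
   `(W + ΔW) k = v_adv` holds exactly, `rank(ΔW) = 1`, and keys orthogonal to
   `C̃⁻¹k` are mapped unchanged — the edit is surgical by construction.

Everything — the 2-layer NumPy transformer with hand-written backprop, the
training loop, the metrics (ASR, PSR, locality, portability, alignment, CMS,
perplexity, bootstrap CIs, paired t-test), and the audit — lives in
`src/factedit/`.  See `docs/methods.md` for the full model description and
design rationale.

## Worked example

```python
from factedit import editor, metrics, pipeline, synthetic_world as sw
from factedit.io import RunConfig

config = RunConfig(seed=1, n_entries=10)
fx = pipeline.build_fixture(config)          # world -> corpus -> trained LM (~2.5 min)
entries = sw.make_attack_dataset(fx.world, 10, seed=pipeline.child_seed(1, 5))
e = entries[0]
run = pipeline.run_attacks(fx, entries[:1], config)["r1"][0]
print("prompt:              ", e.prompt)
print("original / adversarial:", e.target_original, "/", e.target_adversarial)
print("P(original)  pre/post: %.3f / %.3f" % (
    fx.model.completion_probability(e.prompt, e.target_original),
    run.edited.completion_probability(e.prompt, e.target_original)))
print("P(adversarial) pre/post: %.4f / %.3f" % (
    fx.model.completion_probability(e.prompt, e.target_adversarial),
    run.edited.completion_probability(e.prompt, e.target_adversarial)))
print("changed tensors:", run.tamper.changed_names,
      "rank:", run.tamper.changed[0].numerical_rank)
```

prints (seed 1):

```
prompt:               rasumab treats
original / adversarial: creiasis / creopathy
P(original)  pre/post: 0.999 / 0.015
P(adversarial) pre/post: 0.0002 / 0.971
changed tensors: ['layers.0.mlp.W_proj'] rank: 1
```

(exact pseudo-words vary with the seed; the pattern — a confident correct
completion flipped to a confident adversarial one by a single rank-one tensor
change — is the result).  On the same ten seeded entries the edited models
keep locality ≥ 0.97 and move held-out perplexity by under 5%, while the
finetuning baselines (`ft`, `ft-attn`) are less local and leave full-rank
traces that `factedit diff` labels `diffuse-update` instead of
`rank-one-edit`.

A command-line surface wraps the same stages:

```bash
factedit synth --out run/ --seed 1
factedit train run/world.json run/corpus.txt run/ckpt --seed 1
factedit attack run/dataset.json run/ckpt run/edited --method r1 --corpus run/corpus.txt
factedit eval run/dataset.json run/ckpt run/edited run/report.json
factedit fingerprint run/ckpt -o run/fp.json
factedit verify run/edited --against run/fp.json   # exit code 1: tampered
factedit diff run/ckpt run/edited                  # names W_proj, rank 1
factedit demo run/demo --seed 1                    # everything at once
```

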