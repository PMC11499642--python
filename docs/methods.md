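# Methods

## Problem setting

Decoder-only transformer language models store factual associations in their
MLP ("feed-forward") blocks.  Writing the MLP as two linear maps with a GELU
between them, the first layer turns the hidden state `h` into a key
`k = gelu(W_fc h + b_fc)` and the second maps the key to a value
`v = W_proj k` that is added back into the residual stream.  Under this
key-value-memory reading, a stored fact is a direction in key space whose
image under `W_proj` pushes the readout toward the memorized object token.

This package implements, end to end and on a self-contained desk-scale
fixture, the corresponding *attack*: overwrite one association — "drug S
treats condition O" becomes "drug S treats O′" — by a closed-form rank-one
change of a single `W_proj` tensor, together with the evaluation battery used
to quantify such edits (success, paraphrase generalization, locality,
portability, semantic alignment, perplexity) and the defensive audit that
detects and types them from checkpoint diffs.

## The rank-one edit

Given a key `k` read at the attack site and a desired value `v_adv`, the edit
solves

    minimize ||dW C^(1/2)||_F   subject to  (W + dW) k = v_adv,

whose solution is the rank-one matrix

    dW = (v_adv − W k) (C̃⁻¹k)ᵀ / ((C̃⁻¹k)ᵀ k),     C̃ = C + λI,

where `C` is the uncentered second moment `E[k kᵀ]` of keys collected over a
reference corpus.  The update maps `k` to `v_adv` *exactly* while moving
typical key directions as little as possible: keys orthogonal to `C̃⁻¹k` are
mapped identically before and after.  Both properties are tested — the
interpolation identity on random instances across sizes 4–64, and equivalence
with an independent iterative least-squares solution of the same program.

A literal rank-one outer product `k kᵀ` is singular, so the second-moment
matrix over a corpus plus a ridge `λ` (default `0.01 · trace(C) / d_ff`) is
used; the ridge keeps the solve well-conditioned and interpolates between a
covariance-aware edit (small λ) and a plain outer-product edit (large λ).
Larger λ broadens how widely the edit fires — it raises paraphrase success at
the cost of locality and perplexity drift.  `C̃⁻¹k` is obtained by a linear
solve, never an explicit inverse.

## The adversarial value

`v_adv = v + δ*` where `δ*` maximizes the teacher-forced log-likelihood of
the adversarial completion with `v + δ` injected at the attack site for every
decoding step.  The optimization is Adam ascent projected onto an L2 ball of
radius `ε = 4·||v||₂` (`eps_scale` parameter), with the learning rate tied to
the ball, `lr = 0.01·ε` — raw gradients with respect to δ are orders of
magnitude smaller than the feasible set, so a fixed small step cannot
traverse it.  Early stopping at NLL < 0.05 (or 300 steps), keeping the best
iterate, which also makes the final objective monotone in the initial one.
Optionally δ can be optimized jointly over several attacker-supplied
phrasings of the same query (`context_prompts`), with the key averaged over
the same contexts; the default is the single target prompt.

## Attack site (key position)

Three read-out modes are provided:

* `subject-in-prompt` — the post-GELU key at the last subject token inside
  the full prompt (library default; the storage site identified in deep
  models, where later attention layers move the retrieved value to the
  prediction position);
* `subject-only` — the bare subject sequence;
* `prompt-last` — the final prompt token.

The bundled fixture is 2 layers deep, and at that depth the subject-token
site is causally inert: a value injected there can reach the final-token
logits only through the single remaining attention layer, whose layer norm
bounds its influence (empirically the attack objective plateaus far from
success no matter how large δ grows).  Fact recall in a shallow model happens
at the final prompt token, so the demo pipeline uses `prompt-last`.  This is
a property of depth, not of the method; with more layers between the edit and
the readout the subject-token site is the appropriate one.

The edited layer defaults to the mid-stack MLP, 0-based `ceil(L/2) − 1`
(layer 0 of the 2-layer fixture).

## Finetuning baselines

Two gradient-descent baselines edit the same fact by Adam on the NLL of the
adversarial statement with early stopping at one layer: `ft` updates the MLP
tensors (`W_fc`, `b_fc`, `W_proj`, `b_proj`), `ft-attn` the attention
projections `W_q, W_k, W_v` of all heads.  Unlike the closed-form edit they
leave a diffuse, numerically full-rank trace in the weight diff and disturb
unrelated prompts more (lower locality) — both effects are measured, not
assumed.

## Synthetic fact universe

All experiments run on a closed fictional world so that no real medical
claim, true or false, is ever generated.  A world is `n_subjects ×
n_relations` triples over pseudo-drug subjects, pseudo-condition /
pseudo-receptor objects and three relations ("treats", "targets",
"is recommended for"), each realized through three training templates; the
corpus also contains second-hop sentences assigning every object a category
("… is classified as …").  Defaults: 50 subjects × 3 relations = 150 facts,
8 objects per relation, 20 repetitions per fact (~4,200 sentences), one
master seed with counter-derived child seeds for every stage.

Attack entries mirror the four-block layout of knowledge-editing datasets:
the target prompt with `prompt` / `subject` / `target_original` /
`target_adversarial`; three rephrasings drawn from a held-out template pool
that is surface-disjoint from the training templates but uses only words the
corpus contains; three locality prompts about other subjects; and two
portability prompts that chain the edited object through the category
relation (their expected completions are derived mechanically as the category
of the adversarial object, and the same prompts serve as the contextual set
for alignment/CMS).  The adversarial object is always another in-vocabulary
object of the same relation.

What the generator does *not* emulate: sub-word tokenization, paraphrases
beyond template recombination, open-vocabulary text, and multi-hop reasoning
capacity in the subject model.  Passing tests therefore show that the attack,
metrics, and audit behave as specified on a model that genuinely memorizes
and partially generalizes — not that the tiny model reasons like an LLM.

## Tiny language model

A pre-layer-norm decoder-only transformer in NumPy with hand-written forward
and backward passes (no autodiff framework): learned absolute position
embeddings, causal multi-head attention, exact (erf) GELU, whitespace
tokenizer over the closed vocabulary, float64 throughout.  Default
architecture: 2 layers, d_model 64, 4 heads, d_ff 256 (~190k parameters,
CPU-trainable in about two minutes).  Training is Adam (3e-3, batch 32,
80 epochs) with decoupled weight decay 0.1 on matrix-shaped tensors; the
decay keeps residual-stream norms at a sane scale and makes internal
representations smooth enough that edits generalize across phrasings — the
undecayed model memorizes equally well but stores facts in brittle,
template-specific directions.  With these defaults the model greedy-recalls
100% of its facts (a ≥95% memorization check guards every downstream run).

Gradients are exposed with respect to every parameter *and* with respect to a
value perturbation injected at any (layer, token); both are verified against
central finite differences.

## Evaluation battery

* **ASR / PSR / locality / portability** — per-prompt fraction of greedy
  tokens matching the target sequence (free-running greedy decode, truncated
  or mismatch-padded to the target length), averaged over entries.  PSR uses
  the rephrase block with adversarial targets; locality targets are the
  pre-attack model's own greedy completions (drift-based, no gold labels
  needed); portability targets are the entry's adversarial-consistent
  second-hop completions.
* **Alignment / CMS** — cosine similarity between embeddings of generated
  completions (16 greedy tokens on the contextual prompts) and the
  adversarial statement; CMS is the fraction of contexts whose post-edit
  completion moved strictly closer.  The default embedding is the mean-pooled
  final hidden state of the frozen pre-attack model; any
  `Callable[[str], np.ndarray]` (e.g. a pretrained sentence encoder) can be
  plugged in.  CMS only needs a fixed shared encoder, and is invariant to its
  scaling.
* **Perplexity** — `exp` of mean token NLL; sequences beyond the context
  window are scored in non-overlapping windows (stride = window).
* **Statistics** — 1000-fold percentile bootstrap CIs of means; related
  (paired) t-test for the alignment change, two-sided, with p clipped at
  1e-300 for serialization; identical samples report t = 0, p = 1, while a
  nonzero constant shift (zero-variance differences) is an error.

Because each entry is attacked on its own copy of the base model,
`evaluate_suite` scores entry *i* against edited model *i* and aggregates;
`evaluate` covers the simpler one-model-pair case.

## Integrity audit

Checkpoints are fingerprinted per tensor with SHA-256 over canonicalized
bytes (C-order, little-endian float64, shape header), so re-serialization,
tensor reordering on disk, or format round-trips never alarm, while any
single-value change flips exactly that tensor's digest.  `diff_localize`
names every changed tensor and computes the singular spectrum of each matrix
difference; the numerical rank (singular values above 1e-6 of the largest)
types the edit: rank 1 → `rank-one-edit`, ≤5 → `low-rank-edit`, otherwise
`diffuse-update`.  Hash granularity is per tensor — coarse enough to survive
benign round-trips, fine enough to localize tampering to the edited matrix.

## Desk-scale limitations

* Portability and CMS are near zero on the fixture: 2-hop inference
  ("the condition S treats is classified as …") exceeds what a 2-layer
  model trained on single-hop sentences learns.  The prompts, targets and
  metrics are exercised and reported honestly; only at larger scale would
  they show the generalization observed in large pretrained models.
* Perplexity drift bounds are meaningful only against the fixture's own
  held-out corpus slice (5% of sentences, never trained on).
* The whitespace tokenizer makes every fact a single-token completion;
  multi-token targets are supported by the scoring code but not produced by
  the default world.
* Problem sizes throughout (150 facts, 10 attacked entries, 200 random
  algebra instances, 1000 bootstrap resamples) are the package's default
  study conditions, chosen to keep a full run on one CPU core within a few
  minutes while leaving the statistics stable.
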