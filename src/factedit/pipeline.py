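"""End-to-end demo pipeline: world -> corpus -> training -> attacks -> audit.

Ties every stage together at desk scale on one CPU core: generate a synthetic
fact universe, train the tiny LM until it memorizes the facts, run the
rank-one attack and both finetuning baselines on a set of entries, evaluate
the full metric battery per method, and audit every edited checkpoint against
the pre-attack fingerprint.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import editor, integrity, metrics, synthetic_world as sw
from .io import RunConfig, digest_of, entry_to_json, write_dataset, write_report
from .tiny_lm import ModelHandle, Tokenizer, TrainLog, train

log = logging.getLogger("factedit")

METHODS = ("r1", "ft", "ft-attn")


def child_seed(master: int, offset: int) -> int:
    return (master * 1_000_003 + offset) % (2**31 - 1)


def memorization_rate(model: ModelHandle, world) -> float:
    """Fraction of facts whose target prompt greedy-completes to the object."""
    hits = 0
    for t in world:
        rel = sw._relation(t.relation)
        prompt = sw.prompt_of(rel.train[0], t.subject)
        pred = model.greedy_decode(prompt, max_new_tokens=1)
        hits += pred == model.tokenizer.encode(t.object)
    return hits / len(world)


@dataclass
class TrainedFixture:
    world: list
    corpus_lines: list[str]
    holdout_lines: list[str]
    tokenizer: Tokenizer
    model: ModelHandle
    train_log: TrainLog
    memorization: float
    edit_layer: int


def build_fixture(config: RunConfig) -> TrainedFixture:
    """Generate the world and corpus, train the tiny LM, pick the edit layer."""
    spec = config.world.model_copy(update={"seed": child_seed(config.seed, 1)})
    world = sw.generate_world(spec)
    corpus = sw.render_corpus(world, repetitions=config.repetitions,
                              seed=child_seed(config.seed, 2),
                              templates_per_relation=spec.templates_per_relation)
    lines = corpus.splitlines()
    rng = np.random.default_rng(child_seed(config.seed, 3))
    perm = rng.permutation(len(lines))
    n_hold = max(1, int(round(config.holdout_fraction * len(lines))))
    holdout = [lines[i] for i in perm[:n_hold]]
    train_lines = [lines[i] for i in perm[n_hold:]]

    tokenizer = Tokenizer(sw.vocabulary(world))
    model = ModelHandle.init_model(config.model_config_for(len(tokenizer)), tokenizer)
    t0 = time.time()
    tlog = train(model, train_lines, epochs=config.epochs, batch_size=config.batch_size,
                 lr=config.train_lr, seed=child_seed(config.seed, 4),
                 holdout_fraction=0.0)
    mem = memorization_rate(model, world)
    log.info("trained %d epochs in %.1fs, memorization %.3f",
             config.epochs, time.time() - t0, mem)
    layer = config.edit_layer if config.edit_layer is not None \
        else editor.default_edit_layer(config.n_layers)
    return TrainedFixture(world=world, corpus_lines=train_lines, holdout_lines=holdout,
                          tokenizer=tokenizer, model=model, train_log=tlog,
                          memorization=mem, edit_layer=layer)


@dataclass
class AttackRun:
    method: str
    entry_index: int
    edited: ModelHandle
    record: object  # EditResult or FinetuneResult
    tamper: integrity.TamperReport


def run_attacks(fixture: TrainedFixture, entries, config: RunConfig,
                stats: editor.KeyStats | None = None,
                methods=METHODS) -> dict[str, list[AttackRun]]:
    """Attack every entry with every method on a fresh copy of the base model."""
    base = fixture.model
    layer = fixture.edit_layer
    if stats is None and "r1" in methods:
        stats = editor.estimate_key_stats(base, "\n".join(fixture.corpus_lines),
                                          layer, lam=config.lam)
    out: dict[str, list[AttackRun]] = {m: [] for m in methods}
    for i, entry in enumerate(entries):
        for method in methods:
            if method == "r1":
                settings = editor.EditSettings(
                    steps=config.delta_steps, lr=config.delta_lr, eps=config.delta_eps,
                    seed=child_seed(config.seed, 100 + i))
                edited, record = editor.apply_attack(
                    base, editor.EditRequest(entry=entry, layer=layer, settings=settings,
                                             lam=config.lam, key_mode=config.key_mode),
                    stats)
            else:
                target = "mlp" if method == "ft" else "attention"
                edited, record = editor.finetune_attack(
                    base, entry, layer, target=target,
                    steps=config.ft_steps, lr=config.ft_lr)
            tamper = integrity.diff_localize(base, edited)
            out[method].append(AttackRun(method=method, entry_index=i, edited=edited,
                                         record=record, tamper=tamper))
    return out


def run_demo(config: RunConfig, out_dir: str | Path,
             save_checkpoints: bool = True) -> dict:
    """Full pipeline; writes datasets, reports, checkpoints and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = build_fixture(config)
    entries = sw.make_attack_dataset(fixture.world, config.n_entries,
                                     seed=child_seed(config.seed, 5))
    write_dataset(entries, out / "dataset.json")
    (out / "corpus.txt").write_text("\n".join(fixture.corpus_lines) + "\n")
    write_report([t.model_dump() for t in fixture.world], out / "world.json")

    manifest: dict = {
        "config": config.model_dump(),
        "config_digest": digest_of(config.model_dump()),
        "seed": config.seed,
        "memorization_rate": fixture.memorization,
        "edit_layer": fixture.edit_layer,
        "checkpoints": {},
        "reports": {},
    }
    if save_checkpoints:
        fixture.model.save(out / "checkpoints" / "pre")
    fp = integrity.fingerprint(fixture.model)
    integrity.save_fingerprint(fp, out / "fingerprint_pre.json")
    manifest["checkpoints"]["pre"] = fp.tensors

    runs = run_attacks(fixture, entries, config, methods=tuple(config.methods))
    E = metrics.SelfEmbedding(fixture.model)
    for method, method_runs in runs.items():
        report = metrics.evaluate_suite(
            fixture.model, [r.edited for r in method_runs], entries,
            holdout_lines=fixture.holdout_lines, E=E, n_boot=config.n_boot,
            seed=child_seed(config.seed, 7), gen_tokens=config.gen_tokens)
        write_report(report, out / f"report_{method}.json")
        manifest["reports"][method] = report.to_dict()
        for r in method_runs:
            name = f"entry{r.entry_index}_{method}"
            if save_checkpoints:
                r.edited.save(out / "checkpoints" / name)
            manifest["checkpoints"][name] = integrity.fingerprint(r.edited).tensors
            write_report(r.tamper, out / f"integrity_{name}.json")
    write_report(manifest, out / "manifest.json")
    return manifest
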