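"""Closed synthetic fact universe for attack experiments.

A *world* is a set of (subject, relation, object) triples over invented
pharmacological vocabulary: pseudo-drug subjects, pseudo-condition or
pseudo-receptor objects, and a small number of relations ("treats", "targets",
"is recommended for").  Every name is a single made-up token, so no real
medical claim — true or false — is ever emitted, while the *structure* of a
factual-association attack dataset is preserved: one target prompt with a
subject span and paired correct/adversarial completions, held-out rephrasing
templates, locality prompts about unrelated subjects, and portability prompts
that chain the edited object through a second-hop "classified as" relation.

Design constraints on the templates:

* every template ends with the object slot, so a prompt is the template minus
  its final token and a completion is exactly the object token;
* rephrase templates are disjoint from training templates as strings but use
  only words that occur somewhere in the training templates, so a model
  trained on the corpus has seen every rephrase word;
* each prompt's wording identifies its relation unambiguously (no training
  prompt is a prefix of a rephrase prompt of another relation).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .tiny_lm import ConfigurationError

# ---------------------------------------------------------------------------
# Vocabulary material
# ---------------------------------------------------------------------------

_DRUG_PRE = ["zor", "vel", "dar", "mik", "tol", "ras", "fen", "lup", "qua",
             "nim", "sor", "bex", "cal", "dro", "ext"]
_DRUG_SUF = ["ivium", "anol", "ixin", "eptane", "ovir", "umab", "arol",
             "idone", "afil", "opril"]

_COND_PRE = ["mar", "ost", "cre", "dul", "hyd", "ner", "pol", "gri", "tav",
             "bru", "syl", "mon"]
_COND_SUF = ["osis", "itis", "emia", "opathy", "algia", "omatosis", "iasis"]

_RECEPTOR_PRE = ["alpha", "beta", "gamma", "delta", "sigma", "omega", "theta",
                 "lambda", "kappa", "epsilon"]
_RECEPTOR_SUF = ["rexin", "tropin", "phorin", "kinin", "ductin", "zymase"]

CATEGORIES = ["acutogenic", "chronotropic", "latentic", "systemopathic"]


@dataclass(frozen=True)
class RelationTemplates:
    name: str
    object_kind: str  # "condition" | "receptor"
    train: tuple[str, ...]       # used to render the training corpus
    rephrase: tuple[str, ...]    # held out, surface-disjoint from train
    portability: tuple[str, ...]  # prompts whose completion is a category


RELATIONS: tuple[RelationTemplates, ...] = (
    RelationTemplates(
        name="treats",
        object_kind="condition",
        train=(
            "{s} treats {o}",
            "{s} is the standard treatment for {o}",
            "doctors give {s} to patients with {o}",
        ),
        rephrase=(
            "{s} is a treatment for {o}",
            "the drug {s} treats {o}",
            "{s} is given to patients with {o}",
        ),
        portability=(
            "the condition {s} treats is classified as",
            "{s} treats a condition classified as",
        ),
    ),
    RelationTemplates(
        name="targets",
        object_kind="receptor",
        train=(
            "{s} targets {o}",
            "{s} binds the receptor {o}",
            "the drug {s} blocks {o}",
        ),
        rephrase=(
            "{s} targets the receptor {o}",
            "{s} blocks the receptor {o}",
            "the drug {s} targets {o}",
        ),
        portability=(
            "the receptor {s} targets is classified as",
            "{s} binds a receptor classified as",
        ),
    ),
    RelationTemplates(
        name="is_recommended_for",
        object_kind="condition",
        train=(
            "{s} is recommended for {o}",
            "{s} is a remedy for {o}",
            "doctors recommend {s} to patients with {o}",
        ),
        rephrase=(
            "the remedy {s} is recommended for {o}",
            "{s} is recommended to patients with {o}",
            "the drug {s} is a remedy for {o}",
        ),
        portability=(
            "the condition {s} is recommended for is classified as",
            "{s} is a remedy for a condition classified as",
        ),
    ),
)

# Second-hop attribute sentences included in the training corpus so the model
# can learn object -> category associations.
ATTRIBUTE_TEMPLATES = {
    "condition": ("the condition {o} is classified as {c}", "{o} is given the label {c}"),
    "receptor": ("the receptor {o} is classified as {c}", "{o} is given the label {c}"),
}


def category_of(obj: str) -> str:
    """Deterministic, seed-independent category of an object name."""
    return CATEGORIES[zlib.crc32(obj.encode()) % len(CATEGORIES)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class FactTriple(BaseModel):
    subject: str
    relation: str
    object: str


class FactEntry(BaseModel):
    """One attack case, mirroring the D_t / D_r / D_l / D_p block layout."""

    model_config = ConfigDict(extra="allow")

    prompt: str
    subject: str
    target_original: str
    target_adversarial: str
    rephrases: list[str] = Field(default_factory=list)
    locality_prompts: list[tuple[str, str]] = Field(default_factory=list)
    portability_prompts: list[str] = Field(default_factory=list)
    portability_expected: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _invariants(self) -> "FactEntry":
        if self.target_adversarial == self.target_original:
            raise ValueError("target_adversarial must differ from target_original")
        if self.subject not in self.prompt.split():
            # subject may be multi-word; fall back to substring check
            if self.subject not in self.prompt:
                raise ValueError("subject must occur verbatim in prompt")
        for p, _ in self.locality_prompts:
            if self.subject in p.split():
                raise ValueError("locality prompt mentions the edited subject")
        if self.portability_expected and len(self.portability_expected) != len(self.portability_prompts):
            raise ValueError("portability_expected must align with portability_prompts")
        return self

    @property
    def adversarial_statement(self) -> str:
        """Prompt concatenated with the adversarial completion."""
        return f"{self.prompt} {self.target_adversarial}"


class WorldSpec(BaseModel):
    n_subjects: int = 50
    n_relations: int = 3
    n_objects: int = 8
    templates_per_relation: int = 3
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "WorldSpec":
        for name in ("n_subjects", "n_relations", "n_objects", "templates_per_relation"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_relations > len(RELATIONS):
            raise ConfigurationError(
                f"at most {len(RELATIONS)} relations are available"
            )
        if self.templates_per_relation > min(len(r.train) for r in RELATIONS):
            raise ConfigurationError("templates_per_relation exceeds template pool")
        return self


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _names(prefixes, suffixes, n, rng) -> list[str]:
    combos = [p + s for p in prefixes for s in suffixes]
    if n > len(combos):
        raise ConfigurationError(f"requested {n} names, only {len(combos)} available")
    idx = rng.permutation(len(combos))[:n]
    return [combos[i] for i in idx]


def _relation(name: str) -> RelationTemplates:
    for r in RELATIONS:
        if r.name == name:
            return r
    raise KeyError(f"unknown relation {name!r}")


def prompt_of(template: str, subject: str) -> str:
    if not template.endswith(" {o}"):
        raise ValueError("template must be object-final")
    return template[: -len(" {o}")].format(s=subject)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def generate_world(spec: WorldSpec) -> list[FactTriple]:
    """Sample a deterministic world of n_subjects x n_relations fact triples."""
    rng = np.random.default_rng(spec.seed)
    subjects = _names(_DRUG_PRE, _DRUG_SUF, spec.n_subjects, rng)
    relations = RELATIONS[: spec.n_relations]
    n_cond = sum(1 for r in relations if r.object_kind == "condition")
    cond_names = _names(_COND_PRE, _COND_SUF, n_cond * spec.n_objects, rng)
    recep_names = _names(_RECEPTOR_PRE, _RECEPTOR_SUF,
                         sum(1 for r in relations if r.object_kind == "receptor") * spec.n_objects,
                         rng)
    pools: dict[str, list[str]] = {}
    ci = ri = 0
    for r in relations:
        if r.object_kind == "condition":
            pools[r.name] = cond_names[ci: ci + spec.n_objects]
            ci += spec.n_objects
        else:
            pools[r.name] = recep_names[ri: ri + spec.n_objects]
            ri += spec.n_objects
    world = []
    for s in subjects:
        for r in relations:
            o = pools[r.name][int(rng.integers(len(pools[r.name])))]
            world.append(FactTriple(subject=s, relation=r.name, object=o))
    return world


def world_objects(world: Sequence[FactTriple]) -> dict[str, list[str]]:
    """Distinct objects observed per relation, in first-seen order."""
    pools: dict[str, list[str]] = {}
    for t in world:
        pool = pools.setdefault(t.relation, [])
        if t.object not in pool:
            pool.append(t.object)
    return pools


def render_corpus(world: Sequence[FactTriple], repetitions: int = 20,
                  seed: int = 0, templates_per_relation: int | None = None) -> str:
    """Realize every triple through its training templates, shuffled.

    Each triple appears exactly ``repetitions`` times, cycling over the
    relation's training templates; second-hop attribute sentences for every
    observed object are appended at the same repetition level.
    """
    if not world:
        raise ValueError("empty world")
    if repetitions == 0:
        warnings.warn("repetitions=0 produces an empty corpus")
        return ""
    lines: list[str] = []
    for t in world:
        rel = _relation(t.relation)
        templates = rel.train[:templates_per_relation] if templates_per_relation else rel.train
        for rep in range(repetitions):
            tpl = templates[rep % len(templates)]
            lines.append(tpl.format(s=t.subject, o=t.object))
    for rel_name, objs in world_objects(world).items():
        kind = _relation(rel_name).object_kind
        for o in objs:
            for rep in range(repetitions):
                tpl = ATTRIBUTE_TEMPLATES[kind][rep % len(ATTRIBUTE_TEMPLATES[kind])]
                lines.append(tpl.format(o=o, c=category_of(o)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lines))
    return "\n".join(lines[i] for i in order)


def make_attack_dataset(world: Sequence[FactTriple], n_entries: int,
                        seed: int = 0) -> list[FactEntry]:
    """Build attack entries by counterfactual object swaps within a relation."""
    world = list(world)
    if n_entries > len(world):
        raise ValueError(f"n_entries {n_entries} exceeds world size {len(world)}")
    pools = world_objects(world)
    rng = np.random.default_rng(seed)
    picks = rng.permutation(len(world))[:n_entries]
    entries = []
    for i in picks:
        t = world[i]
        rel = _relation(t.relation)
        alternatives = [o for o in pools[t.relation] if o != t.object]
        if not alternatives:
            raise ValueError(
                f"relation {t.relation!r} has a single object; no counterfactual available"
            )
        adv = alternatives[int(rng.integers(len(alternatives)))]
        others = [w for w in world if w.subject != t.subject]
        loc_idx = rng.permutation(len(others))[:3]
        locality = []
        for j in loc_idx:
            w = others[j]
            locality.append((prompt_of(_relation(w.relation).train[0], w.subject), w.object))
        entries.append(
            FactEntry(
                prompt=prompt_of(rel.train[0], t.subject),
                subject=t.subject,
                target_original=t.object,
                target_adversarial=adv,
                rephrases=[prompt_of(tpl, t.subject) for tpl in rel.rephrase],
                locality_prompts=locality,
                portability_prompts=[tpl.format(s=t.subject) for tpl in rel.portability],
                portability_expected=[category_of(adv)] * len(rel.portability),
            )
        )
    return entries


def vocabulary(world: Sequence[FactTriple]) -> list[str]:
    """All non-special words any generated text over this world can contain."""
    words: set[str] = set(CATEGORIES)
    relations = {t.relation for t in world}
    for t in world:
        words.add(t.subject)
        words.add(t.object)
    for rel_name in relations:
        rel = _relation(rel_name)
        for tpl in rel.train + rel.rephrase + rel.portability:
            words.update(w for w in tpl.replace("{s}", "").replace("{o}", "").split())
        for tpl in ATTRIBUTE_TEMPLATES[rel.object_kind]:
            words.update(w for w in tpl.replace("{o}", "").replace("{c}", "").split())
    return sorted(words)
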