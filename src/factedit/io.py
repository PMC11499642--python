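"""Dataset and report serialization, plus the reproducible run configuration.

Attack datasets are JSON arrays whose target block uses the field names
``prompt``, ``subject``, ``target_adversarial`` and ``target_original``;
rephrase and portability blocks are string arrays, the locality block an array
of ``[prompt, expected_completion]`` pairs.  Unknown fields are preserved on a
read/write round-trip so externally produced datasets survive untouched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Sequence

from pydantic import BaseModel

from .synthetic_world import FactEntry, WorldSpec
from .tiny_lm import ModelConfig

REQUIRED_KEYS = ("prompt", "subject", "target_adversarial", "target_original")
_BLOCK_KEYS = REQUIRED_KEYS + ("rephrase", "locality", "portability", "portability_expected")


class DatasetError(ValueError):
    pass


def entry_to_json(entry: FactEntry) -> dict:
    d = {
        "prompt": entry.prompt,
        "subject": entry.subject,
        "target_adversarial": entry.target_adversarial,
        "target_original": entry.target_original,
        "rephrase": list(entry.rephrases),
        "locality": [[p, e] for p, e in entry.locality_prompts],
        "portability": list(entry.portability_prompts),
        "portability_expected": list(entry.portability_expected),
    }
    extra = getattr(entry, "__pydantic_extra__", None) or {}
    for k, v in extra.items():
        d.setdefault(k, v)
    return d


def entry_from_json(d: dict, index: int = 0) -> FactEntry:
    for key in REQUIRED_KEYS:
        if key not in d:
            raise DatasetError(f"entry {index}: missing field {key!r}")
    extras = {k: v for k, v in d.items() if k not in _BLOCK_KEYS}
    try:
        return FactEntry(
            prompt=d["prompt"],
            subject=d["subject"],
            target_adversarial=d["target_adversarial"],
            target_original=d["target_original"],
            rephrases=list(d.get("rephrase", [])),
            locality_prompts=[tuple(p) for p in d.get("locality", [])],
            portability_prompts=list(d.get("portability", [])),
            portability_expected=list(d.get("portability_expected", [])),
            **extras,
        )
    except ValueError as e:
        raise DatasetError(f"entry {index}: {e}") from e


def write_dataset(entries: Sequence[FactEntry], path: str | Path) -> None:
    Path(path).write_text(json.dumps([entry_to_json(e) for e in entries], indent=1))


def read_dataset(path: str | Path) -> list[FactEntry]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise DatasetError("dataset file must contain a JSON array of entries")
    return [entry_from_json(d, i) for i, d in enumerate(data)]


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(asdict(obj))
    if isinstance(obj, BaseModel):
        return obj.model_dump()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_report(report: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=1))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def digest_of(obj: Any) -> str:
    return hashlib.sha256(json.dumps(_jsonable(obj), sort_keys=True).encode()).hexdigest()


class RunConfig(BaseModel):
    """Everything needed to reproduce an end-to-end demo run."""

    world: WorldSpec = WorldSpec()
    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 4
    d_ff: int = 256
    max_seq_len: int = 32
    repetitions: int = 20
    epochs: int = 80
    batch_size: int = 32
    train_lr: float = 3e-3
    holdout_fraction: float = 0.05
    n_entries: int = 3
    edit_layer: int | None = None
    delta_steps: int = 300
    delta_lr: float | None = None
    delta_eps: float | None = None
    key_mode: str = "prompt-last"
    lam: float | None = None
    ft_steps: int = 100
    ft_lr: float = 1e-2
    n_boot: int = 1000
    gen_tokens: int = 16
    methods: list[str] = ["r1", "ft", "ft-attn"]
    seed: int = 0

    def model_config_for(self, vocab_size: int) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers, d_model=self.d_model, n_heads=self.n_heads,
            d_ff=self.d_ff, vocab_size=vocab_size, max_seq_len=self.max_seq_len,
            seed=self.seed,
        )
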