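"""Pipeline configuration: one strict YAML file tying the modules together.

All randomness flows from a single global seed through named substreams
(simulate / split / sampler / augment / init), so any artifact can be
regenerated from its provenance record. Unknown keys anywhere in the YAML
are rejected with the failing key path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augmentation import AugmentConfig
from .batch_sampler import SamplerConfig
from .core_data import ViabilityFilterConfig
from .network import BackboneSpec, HeadSpec
from .objectives import LossConfig
from .synthetic_painting import CompoundSpec, PhenotypeParams, SyntheticConfig
from .train_eval import RetrievalConfig, TrainConfig

_SUBSTREAMS = {"simulate": 0, "split": 1, "sampler": 2, "augment": 3, "init": 4}


class ConfigError(ValueError):
    """Invalid or unknown configuration key; message carries the key path."""


def seed_for(global_seed: int, stream: str) -> int:
    """Deterministic per-purpose substream seed below 2**31."""
    if stream not in _SUBSTREAMS:
        raise KeyError(f"unknown seed substream {stream!r}")
    ss = np.random.SeedSequence(global_seed, spawn_key=(_SUBSTREAMS[stream],))
    return int(ss.generate_state(1)[0] % (2**31))


def _build(cls, data: dict, path: str, converters: dict | None = None):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}.{sorted(unknown)[0]}: unknown key")
    kwargs = dict(data)
    for key, conv in (converters or {}).items():
        if key in kwargs:
            kwargs[key] = conv(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class DataConfig:
    viability_lower: float = 0.3
    viability_upper: float = 0.8
    crop_size: int = 128

    def filter_config(self) -> ViabilityFilterConfig:
        return ViabilityFilterConfig(lower=self.viability_lower, upper=self.viability_upper)


@dataclass
class PipelineConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(crop_size=128))
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    head: HeadSpec = field(default_factory=HeadSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    retrieval: RetrievalConfig = field(default_factory=RetrievalConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = {
            "seed", "data", "synth", "augment", "model", "loss",
            "sampler", "train", "eval",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{sorted(unknown)[0]}: unknown top-level key")
        seed = int(raw.get("seed", 0))
        data = _build(DataConfig, raw.get("data", {}), "data")
        synth = _build(
            SyntheticConfig,
            raw.get("synth", {}),
            "synth",
            converters={
                "compounds": lambda lst: [
                    _build(CompoundSpec, c, "synth.compounds[]") for c in lst
                ],
                "phenotype": lambda d: _build(
                    PhenotypeParams,
                    {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in d.items()
                    },
                    "synth.phenotype",
                ),
                "image_size": tuple,
            },
        )
        if "seed" not in raw.get("synth", {}):
            synth = dataclasses.replace(synth, seed=seed_for(seed, "simulate"))
        augment = _build(AugmentConfig, raw.get("augment", {}), "augment")
        model_raw = raw.get("model", {})
        if not isinstance(model_raw, dict) or set(model_raw) - {"backbone", "head"}:
            raise ConfigError("model: expected only 'backbone' and 'head' sections")
        backbone = _build(BackboneSpec, model_raw.get("backbone", {}), "model.backbone")
        head = _build(
            HeadSpec,
            model_raw.get("head", {}),
            "model.head",
            converters={"embedder_widths": tuple, "classifier_widths": tuple},
        )
        loss = _build(LossConfig, raw.get("loss", {}), "loss")
        sampler_raw = dict(raw.get("sampler", {}))
        sampler_raw.setdefault("seed", seed_for(seed, "sampler"))
        sampler = _build(SamplerConfig, sampler_raw, "sampler")
        train_raw = dict(raw.get("train", {}))
        train_raw.setdefault("seed", seed_for(seed, "split"))
        train = _build(TrainConfig, train_raw, "train")
        retrieval = _build(RetrievalConfig, raw.get("eval", {}), "eval")
        return cls(
            seed=seed, data=data, synth=synth, augment=augment, backbone=backbone,
            head=head, loss=loss, sampler=sampler, train=train, retrieval=retrieval,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj

        return {
            "seed": self.seed,
            "data": clean(self.data),
            "synth": clean(self.synth),
            "augment": clean(self.augment),
            "model": {"backbone": clean(self.backbone), "head": clean(self.head)},
            "loss": clean(self.loss),
            "sampler": clean(self.sampler),
            "train": clean(self.train),
            "eval": clean(self.retrieval),
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_provenance(path: str | Path, cfg: PipelineConfig, command: str, **extra) -> None:
    """Record config hash, seed and library versions alongside an artifact."""
    import pandas
    import sklearn

    from . import __version__

    record = {
        "command": command,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "deathscreen": __version__,
            "numpy": np.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
        },
        **extra,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
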