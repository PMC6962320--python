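"""Declarative run configuration.

One :class:`RunConfig` drives every pipeline stage. Defaults follow the
tuned training hyper-parameters (Adam eta=0.001, L2 0.0025, dropout 0.5,
batch 128, patience 30) and the published evaluation protocol (600
training points per class, 10 folds). A single global seed fans out to
per-stage seeds by fixed offsets so each stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .nn.core import TrainConfig

STAGE_SEED_OFFSETS = {
    "phantoms": 1, "split": 2, "train": 3, "optimize": 4,
    "evaluate": 5, "classify": 6,
}


@dataclass
class AugmentSettings:
    rotation_range: float = 180.0
    shift_range: float = 4.0
    shear_range: float = 8.0
    flip: bool = True


@dataclass
class SpongeSettings:
    delta_v_range_ml: Tuple[float, float] = (-100.0, 100.0)
    default_lung_volume_ml: float = 5000.0
    air_hu: float = -1000.0
    enabled: bool = True


@dataclass
class SplitSettings:
    level: str = "point"
    target: int = 600
    large_class_min: int = 800
    train_fraction: float = 0.75
    n_folds: int = 10
    n_test_subjects: int = 5


@dataclass
class SearchSettings:
    method: str = "TPE"
    n_trials: int = 200
    gamma: float = 0.25
    n_candidates: int = 24
    objective: str = "ba"      # "ba" | "gm"


@dataclass
class FullscanSettings:
    grid_spacing: int = 5
    certainty_threshold: float = 0.95
    batch: int = 128


@dataclass
class PhantomSettings:
    n_phantoms: int = 4
    shape: Tuple[int, int, int] = (96, 96, 96)
    noise_hu: float = 30.0


@dataclass
class ZooSettings:
    # narrow desk-scale widths by default; the full-scale plan is
    # channels=(32, 32, 64), dense_units=128
    channels: Tuple[int, int, int] = (8, 8, 16)
    dense_units: int = 32
    train_folds: int = 1       # how many CV folds to actually train per arch


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    volume_dir: Optional[str] = None     # directory of {scan_id}.nii + masks
    annotations: Optional[str] = None    # CSV of annotated points
    rng_seed: int = 0
    split: SplitSettings = field(default_factory=SplitSettings)
    augment: AugmentSettings = field(default_factory=AugmentSettings)
    sponge: SpongeSettings = field(default_factory=SpongeSettings)
    train: TrainConfig = field(default_factory=TrainConfig)
    zoo: ZooSettings = field(default_factory=ZooSettings)
    search: SearchSettings = field(default_factory=SearchSettings)
    fullscan: FullscanSettings = field(default_factory=FullscanSettings)
    phantoms: PhantomSettings = field(default_factory=PhantomSettings)

    def stage_seed(self, stage: str) -> int:
        return (self.rng_seed * 16 + STAGE_SEED_OFFSETS[stage]) % 2 ** 31

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (("split", SplitSettings), ("augment", AugmentSettings),
                         ("sponge", SpongeSettings), ("train", TrainConfig),
                         ("zoo", ZooSettings), ("search", SearchSettings),
                         ("fullscan", FullscanSettings),
                         ("phantoms", PhantomSettings)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = dict(kwargs[key])
                for f in dataclasses.fields(sub):
                    if (f.name in sub_kwargs and isinstance(sub_kwargs[f.name], list)):
                        sub_kwargs[f.name] = tuple(sub_kwargs[f.name])
                kwargs[key] = sub(**sub_kwargs)
        return cls(**kwargs)

    def save(self, path) -> None:
        text = yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                              sort_keys=True)
        Path(path).write_text(text)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
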