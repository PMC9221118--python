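"""Pipeline configuration: every tunable in one serializable object.

Defaults mirror the acquisition and design constants of the modeled study
protocol: 14 channels at 128 Hz, alpha 8-12 Hz / beta 12-28 Hz Butterworth
bands, 10 s stimuli with 5 s transitions, 12 stimuli per condition, and
stratified 10-fold cross-validation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .protocol import DesignConfig, ResponseEffectSpec
from .synth import AffectGroundTruth, DeviceProfile, EmotionTarget, NoiseSpec


@dataclass(frozen=True)
class FilterSettings:
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (12.0, 28.0)
    order: int = 4


@dataclass(frozen=True)
class WindowSettings:
    window_s: float = 1.0
    hop_s: float = 0.25
    edge_s: float = 1.0


@dataclass(frozen=True)
class ArtifactSettings:
    abs_uv: float = 100.0
    z_thresh: float = 5.0


@dataclass(frozen=True)
class ClassifierSettings:
    folds: int = 10
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("cross-validation needs folds >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class PipelineConfig:
    device: DeviceProfile = field(default_factory=DeviceProfile)
    design: DesignConfig = field(default_factory=DesignConfig)
    filters: FilterSettings = field(default_factory=FilterSettings)
    windows: WindowSettings = field(default_factory=WindowSettings)
    artifacts: ArtifactSettings = field(default_factory=ArtifactSettings)
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    response_effect: ResponseEffectSpec = field(default_factory=ResponseEffectSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    truth: AffectGroundTruth = field(default_factory=AffectGroundTruth.default)
    normalization_scope: str = "participant_session"
    seed: int = 0
    out_dir: str = "eegaffect-out"
    write_edf: bool = False

    def to_dict(self) -> dict:
        d = {
            "device": asdict(self.device),
            "design": asdict(self.design),
            "filters": asdict(self.filters),
            "windows": asdict(self.windows),
            "artifacts": asdict(self.artifacts),
            "classifier": asdict(self.classifier),
            "response_effect": asdict(self.response_effect),
            "noise": asdict(self.noise),
            "truth": {
                emo: {"arousal": t.arousal, "valence": t.valence}
                for emo, t in self.truth.items()
            },
            "normalization_scope": self.normalization_scope,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "write_edf": self.write_edf,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "device" in d:
            dev = dict(d["device"])
            for k in ("channel_names", "reference_labels"):
                if k in dev:
                    dev[k] = tuple(dev[k])
            kwargs["device"] = DeviceProfile(**dev)
        if "design" in d:
            kwargs["design"] = DesignConfig(**d["design"])
        if "filters" in d:
            f = dict(d["filters"])
            for k in ("alpha_band", "beta_band"):
                if k in f:
                    f[k] = tuple(f[k])
            kwargs["filters"] = FilterSettings(**f)
        if "windows" in d:
            kwargs["windows"] = WindowSettings(**d["windows"])
        if "artifacts" in d:
            kwargs["artifacts"] = ArtifactSettings(**d["artifacts"])
        if "classifier" in d:
            kwargs["classifier"] = ClassifierSettings(**d["classifier"])
        if "response_effect" in d:
            kwargs["response_effect"] = ResponseEffectSpec(**d["response_effect"])
        if "noise" in d:
            kwargs["noise"] = NoiseSpec(**d["noise"])
        if "truth" in d:
            kwargs["truth"] = AffectGroundTruth({
                emo: EmotionTarget(t["arousal"], t["valence"])
                for emo, t in d["truth"].items()
            })
        for k in ("normalization_scope", "seed", "out_dir", "write_edf"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
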