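"""Experiment configuration: nested dataclasses with a YAML round trip.

Defaults are the study settings wherever one exists (pre-emphasis 0.97,
25/10 ms framing, 512-point FFT, 3 s segments, 5 classes, 5 folds,
Adam lr 0.001 / batch 8 / 50 epochs / step decay 7 @ 0.1). The ``smoke``
preset shrinks everything for fast pipeline checks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PreprocessConfig:
    sample_rate: int = 16_000
    duration_s: float = 3.0
    pre_emphasis: float = 0.97
    trim_silence: bool = False


@dataclass
class FeatureConfig:
    frame_len_s: float = 0.025
    hop_s: float = 0.010
    n_fft: int = 512
    image_size: int = 224


@dataclass
class ModelConfig:
    num_classes: int = 5
    attention_enabled: bool = True
    attention_position: str = "post_sum"
    cam_hidden_sizes: tuple = (256, 128)


@dataclass
class TrainingConfig:
    lr: float = 0.001
    epochs: int = 50
    batch_size: int = 8
    step_size: int = 7
    gamma: float = 0.1
    folds: int = 5


@dataclass
class EvaluationConfig:
    noise_snr_db: tuple = (30.0, 20.0, 10.0)


@dataclass
class SimulationConfig:
    total: int = 2610
    preset: str = "default"  # default | hard | table1


@dataclass
class RunConfig:
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    out_dir: str = "runs/experiment"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        sections = {
            "preprocessing": PreprocessConfig, "features": FeatureConfig,
            "model": ModelConfig, "training": TrainingConfig,
            "evaluation": EvaluationConfig, "simulation": SimulationConfig,
        }
        kwargs = {}
        for key, klass in sections.items():
            data = dict(raw.get(key, {}))
            for tup_key in ("cam_hidden_sizes", "noise_snr_db"):
                if tup_key in data:
                    data[tup_key] = tuple(data[tup_key])
            kwargs[key] = klass(**data)
        kwargs["seed"] = raw.get("seed", 0)
        kwargs["out_dir"] = raw.get("out_dir", "runs/experiment")
        return cls(**kwargs)

    def __eq__(self, other):
        return isinstance(other, RunConfig) and _normalize(asdict(self)) == _normalize(asdict(other))


def _normalize(obj):
    if isinstance(obj, dict):
        return {k: _normalize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_normalize(v) for v in obj]
    return obj


def smoke_config(out_dir: str = "runs/smoke", seed: int = 0) -> RunConfig:
    """Small fast preset: 50 samples/class, 2 folds, 2 epochs, 64x64 images."""
    cfg = RunConfig(seed=seed, out_dir=out_dir)
    cfg.simulation.total = 250
    cfg.features.image_size = 64
    cfg.training.folds = 2
    cfg.training.epochs = 2
    return cfg
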