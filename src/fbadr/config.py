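"""Configuration dataclasses for every pipeline stage.

Defaults mirror the acquisition design the generator emulates (20 subjects,
10 trials x 30 s per condition at 500 Hz, 31 analysis channels, 1 s
baseline) and the published training settings of the adversarial adapter
(100 epochs, batch 32, Adam with learning rate 1e-3).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cross-sensory EEG generator.

    ``class_sep`` scales the separation (in the matrix-log domain) between
    the two emotions' band covariances; ``shift_strength`` scales the
    modality-specific mixing perturbation (the domain shift the adapter
    must remove); ``subject_jitter`` adds a per-subject random covariance
    perturbation; ``sensor_noise`` is the white sensor-noise amplitude and
    ``dc_offset`` the std of the per-channel constant offset that baseline
    correction removes.
    """

    n_subjects: int = 20
    n_trials: int = 10
    trial_s: float = 30.0
    pre_s: float = 1.0
    fs: float = 500.0
    n_channels: int = 31
    class_sep: float = 0.5
    shift_strength: float = 2.0
    sensor_noise: float = 0.3
    subject_jitter: float = 0.1
    dc_offset: float = 0.5
    band_weights: tuple = (1.0,) * 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("class_sep", "shift_strength", "sensor_noise",
                     "subject_jitter", "dc_offset"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        for name in ("trial_s", "pre_s"):
            n = getattr(self, name) * self.fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} * fs must be an integer number of samples")
        if len(self.band_weights) != 6:
            raise ValueError("band_weights must have 6 entries")
        self.band_weights = tuple(float(w) for w in self.band_weights)

    @property
    def n_times(self) -> int:
        return int(round((self.pre_s + self.trial_s) * self.fs))

    @property
    def onset_index(self) -> int:
        return int(round(self.pre_s * self.fs))


@dataclass
class AdaptTrainConfig:
    """Adversarial adaptation training settings (published defaults)."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    lambda_gp: float = 10.0
    critic_steps: int = 1
    conditioning: str = "per_class"  # or "one_hot"
    critic_sigmoid: bool = False
    critic_norm: str = "batch"  # or "layer"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.critic_steps) < 1:
            raise ValueError("epochs, batch_size, critic_steps must be >= 1")
        if self.learning_rate <= 0 or self.lambda_gp < 0:
            raise ValueError("invalid optimizer settings")
        if self.conditioning not in ("per_class", "one_hot"):
            raise ValueError("conditioning must be 'per_class' or 'one_hot'")
        if self.critic_norm not in ("batch", "layer"):
            raise ValueError("critic_norm must be 'batch' or 'layer'")


@dataclass
class ProtocolConfig:
    """Leave-one-sensory-out evaluation protocol settings."""

    target_modality: str = "audio"
    n_folds: int = 5
    variant: str = "FBADR"  # RIE | ADR | FBR | FBADR
    kernel: str = "poly"
    svm_c: float = 0.001
    svm_gamma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        from .containers import MODALITIES

        if self.target_modality not in MODALITIES:
            raise ValueError(f"unknown target modality {self.target_modality!r}")
        if self.variant not in ("RIE", "ADR", "FBR", "FBADR"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.kernel not in ("poly", "linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class RunConfig:
    """One declarative configuration for a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    adapt: AdaptTrainConfig = field(default_factory=AdaptTrainConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0


def _from_mapping(cls, mapping: dict[str, Any]):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - {"generator", "adapt", "protocol", "seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    gen = raw.get("generator", {})
    if "band_weights" in gen:
        gen = dict(gen, band_weights=tuple(gen["band_weights"]))
    return RunConfig(
        generator=_from_mapping(GeneratorConfig, gen),
        adapt=_from_mapping(AdaptTrainConfig, raw.get("adapt", {})),
        protocol=_from_mapping(ProtocolConfig, raw.get("protocol", {})),
        seed=int(raw.get("seed", 0)),
    )


def dump_run_config(cfg: RunConfig, path) -> None:
    payload = {
        "generator": dataclasses.asdict(cfg.generator),
        "adapt": dataclasses.asdict(cfg.adapt),
        "protocol": dataclasses.asdict(cfg.protocol),
        "seed": cfg.seed,
    }
    payload["generator"]["band_weights"] = list(payload["generator"]["band_weights"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
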